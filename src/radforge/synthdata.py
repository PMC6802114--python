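"""Synthetic diploid RAD-Seq experiment with full ground truth.

The generator emulates the laboratory design the pipeline targets: a diploid
population drawn from diverged source pools, EcoRI (GAATTC) restriction sites,
~600 bp sheared library fragments, paired 2x100 or 2x300 reads with 3' adapter
read-through whenever a molecule is shorter than the read length, uniform
per-base sequencing error, planted microsatellites of di- to hexa-nucleotide
motifs, and planted SNPs at a controllable per-site density.  Every planted
feature is recorded in a :class:`TruthSet` so downstream stages can be scored
exactly.

Model notes
-----------
* Restriction sites are planted at roughly regular spacing along a random
  backbone (accidental occurrences are destroyed first), and each site anchors
  one RAD locus whose reads start at the AATTC remnant.
* Shearing is not modelled physically: each sequenced molecule independently
  draws its length from Normal(fragment_mean, fragment_sd) truncated to
  [read_length/2, 2*fragment_mean], which reproduces the read-through geometry.
* A SNP is planted at a site with probability ``per_site_theta``.  Its
  population alt-allele frequency p0 is uniform on (0,1); with more than one
  pool, each pool draws its own frequency from Beta(c*p0, c*(1-p0)) so pools
  are differentiated.  With a single pool the expected per-site nucleotide
  diversity is per_site_theta * E[2 p(1-p)] = per_site_theta / 3.
* Microsatellite alleles vary per haplotype within the requested unit-count
  range; the reference carries the maximum so the locus is always detectable.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import mutate, random_dna, revcomp
from .errors import PlacementError
from .readprep import ReadPair

#: Illumina TruSeq read-through sequence seen at the 3' end of short inserts.
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 50_000
    n_individuals: int = 12
    n_pools: int = 2
    per_site_theta: float = 0.003
    #: list of (motif, (min_units, max_units), count) to plant
    ssr_plant_spec: list = field(default_factory=list)
    enzyme_site: str = "GAATTC"
    fragment_mean: int = 600
    fragment_sd: float = 100.0
    read_length: int = 100
    error_rate: float = 0.005
    adapter_seq: str = TRUSEQ_ADAPTER
    coverage: float = 10.0
    #: approximate distance between planted restriction sites (one RAD locus each)
    locus_spacing: int = 1500
    #: Beta concentration controlling pool differentiation (larger = less drift)
    pool_concentration: float = 3.0
    #: optional sample -> inline barcode map; when set, forward reads carry barcodes
    barcode_map: Optional[dict] = None

    def __post_init__(self) -> None:
        for name in ("per_site_theta", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fragment_mean <= 0 or self.read_length <= 0:
            raise ValueError("fragment_mean and read_length must be positive")
        if not set(self.enzyme_site) <= set("ACGT"):
            raise ValueError("enzyme_site must be plain DNA")
        if self.n_pools < 1 or self.n_individuals < 1:
            raise ValueError("need at least one pool and one individual")

    @property
    def samples(self) -> list[str]:
        return [f"ind{i + 1:02d}" for i in range(self.n_individuals)]

    @property
    def enzyme_remnant(self) -> str:
        """Sticky-end remnant left at read starts (AATTC for EcoRI G^AATTC)."""
        return self.enzyme_site[1:]

    @property
    def expected_pi(self) -> float:
        """Expected per-site nucleotide diversity of the generating process.

        Exact for a single pool (alt frequency uniform on (0,1) gives
        E[2 p (1-p)] = 1/3); with diverged pools the within-sample expectation
        additionally depends on pool assignment and concentration, so use a
        single pool for calibration experiments.
        """
        if self.n_pools != 1:
            raise ValueError("expected_pi is exact only for n_pools=1")
        return self.per_site_theta / 3.0


@dataclass
class RadLocus:
    locus_id: str
    site_pos0: int  # 0-based position of the G of GAATTC on the reference
    zone_len: int  # reference span, from the remnant start, scored for variants

    @property
    def start0(self) -> int:
        """0-based reference position of the first read base (AATTC...)."""
        return self.site_pos0 + 1


@dataclass
class PlantedSnp:
    pos0: int  # 0-based reference coordinate
    ref: str
    alt: str
    pool_freqs: np.ndarray  # alt-allele frequency per pool
    genotypes: np.ndarray  # (n_individuals, 2) of 0=ref / 1=alt
    locus_id: Optional[str] = None
    locus_pos: Optional[int] = None  # 1-based position on the locus contig


@dataclass
class PlantedSsr:
    start0: int
    motif: str
    ref_units: int
    units: np.ndarray  # (n_individuals, 2) unit counts per haplotype
    locus_id: Optional[str] = None
    locus_pos: Optional[int] = None

    @property
    def ref_len(self) -> int:
        return len(self.motif) * self.ref_units

    @property
    def end0(self) -> int:  # exclusive
        return self.start0 + self.ref_len


@dataclass
class FragmentRecord:
    read_id: str
    sample: str
    locus_id: str
    hap: int
    frag_len: int
    readthrough: int  # adapter bases present in each read (0 when frag >= read len)


@dataclass
class TruthSet:
    config: SimulationConfig
    genome: str
    samples: list[str]
    loci: list[RadLocus]
    snps: list[PlantedSnp]
    ssrs: list[PlantedSsr]
    #: haplotype sequences, indexed [individual][hap 0/1]
    haplotypes: list[tuple[str, str]]
    #: coordinate-shift breakpoints per (individual, hap): list of (ref_pos, shift)
    _offsets: list[tuple[list, list]]
    fragments: list[FragmentRecord] = field(default_factory=list)

    def hap_pos(self, ind: int, hap: int, ref_pos: int) -> int:
        """Map a reference coordinate onto a haplotype (SSR indels shift it)."""
        bps = self._offsets[ind][hap]
        i = bisect.bisect_right([b[0] for b in bps], ref_pos) - 1
        return ref_pos + bps[i][1]

    def locus_fragment(self, locus: RadLocus, ind: int, hap: int, length: int) -> str:
        """True haplotype sequence of a locus, from the remnant, for scoring."""
        start = self.hap_pos(ind, hap, locus.start0)
        return self.haplotypes[ind][hap][start : start + length]

    def locus_reference(self, locus: RadLocus, length: int) -> str:
        return self.genome[locus.start0 : locus.start0 + length]


def _destroy_matches(genome: list, pattern: str, rng: np.random.Generator) -> None:
    """Mutate the middle base of every occurrence of pattern (in place)."""
    s = "".join(genome)
    start = 0
    while True:
        i = s.find(pattern, start)
        if i == -1:
            break
        mid = i + len(pattern) // 2
        old = genome[mid]
        genome[mid] = "ACGT"[(("ACGT".index(old)) + 1 + rng.integers(0, 3)) % 4]
        s = "".join(genome)
        start = i + 1


def simulate_genome(config: SimulationConfig) -> TruthSet:
    """Build the reference, plant restriction sites, SSRs and SNPs, and phase
    diploid haplotypes for every individual."""
    rng = np.random.default_rng([config.seed, 101])
    site_len = len(config.enzyme_site)
    tail_margin = 2 * config.fragment_mean + 50
    head_margin = 50 + max(1, config.locus_spacing // 10)
    usable = config.genome_length - head_margin - tail_margin
    n_loci = usable // config.locus_spacing + 1 if usable >= 0 else 0
    if n_loci < 1:
        raise PlacementError(
            f"genome of {config.genome_length} bp too short for one RAD locus "
            f"(needs ~{100 + tail_margin + site_len} bp)"
        )

    genome = list(random_dna(rng, config.genome_length))
    _destroy_matches(genome, config.enzyme_site, rng)

    jitter_span = max(1, config.locus_spacing // 10)
    site_positions = []
    for i in range(n_loci):
        pos = 50 + jitter_span + i * config.locus_spacing + int(
            rng.integers(-jitter_span, jitter_span + 1)
        )
        site_positions.append(pos)
        genome[pos : pos + site_len] = list(config.enzyme_site)
    zone_len = min(config.locus_spacing - site_len - 20, 2 * config.fragment_mean)
    loci = [
        RadLocus(locus_id=f"locus{i + 1:04d}", site_pos0=p, zone_len=zone_len)
        for i, p in enumerate(site_positions)
    ]

    site_blocked = set()
    for p in site_positions:
        site_blocked.update(range(p, p + site_len))

    # --- SSR planting -------------------------------------------------------
    ssrs: list[PlantedSsr] = []
    occupied: list[tuple[int, int]] = []  # closed-open intervals incl. guard bases

    def overlaps(a: int, b: int) -> bool:
        if any(p in site_blocked for p in (a, b - 1)):
            return True
        return any(a < e and s < b for s, e in occupied)

    for motif, unit_range, count in config.ssr_plant_spec:
        lo, hi = unit_range
        m = len(motif)
        if not (2 <= m <= 6):
            raise PlacementError(f"SSR motif {motif!r} must be 2-6 bp")
        for _ in range(count):
            placed = False
            for _attempt in range(400):
                locus = loci[int(rng.integers(0, len(loci)))]
                max_off = zone_len - hi * m - m - 10
                if max_off <= 30:
                    break
                off = int(rng.integers(30, max_off))
                a = locus.start0 + off
                b = a + hi * m
                if overlaps(a - m, b + m) or any(
                    p in site_blocked for p in range(a - m, b + m)
                ):
                    continue
                genome[a:b] = list(motif * hi)
                # break accidental extensions of the repeat into the flanks
                if "".join(genome[a - m : a]) == motif:
                    genome[a - 1] = next(
                        c for c in "ACGT" if c != motif[-1] and c != genome[a - 1]
                    )
                if "".join(genome[b : b + m]) == motif:
                    genome[b] = next(
                        c for c in "ACGT" if c != motif[0] and c != genome[b]
                    )
                region = "".join(genome[max(0, a - site_len) : b + site_len])
                if config.enzyme_site in region:
                    continue  # planting created a spurious cut site; retry
                units = rng.integers(lo, hi + 1, size=(config.n_individuals, 2))
                ssrs.append(
                    PlantedSsr(
                        start0=a,
                        motif=motif,
                        ref_units=hi,
                        units=units,
                        locus_id=locus.locus_id,
                        locus_pos=a - locus.start0 + 1,
                    )
                )
                occupied.append((a - m, b + m))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place SSR {motif!r} x{hi}: genome too short or crowded"
                )

    genome_str = "".join(genome)

    # --- SNP planting -------------------------------------------------------
    excluded = np.zeros(config.genome_length, dtype=bool)
    for p in site_blocked:
        excluded[p] = True
    for s in ssrs:
        excluded[s.start0 : s.end0] = True
    snp_mask = (rng.random(config.genome_length) < config.per_site_theta) & ~excluded
    pools = np.arange(config.n_individuals) % config.n_pools
    snps: list[PlantedSnp] = []
    locus_starts = [l.start0 for l in loci]
    for pos0 in np.flatnonzero(snp_mask):
        pos0 = int(pos0)
        ref = genome_str[pos0]
        alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        p0 = float(np.clip(rng.uniform(), 1e-6, 1 - 1e-6))
        if config.n_pools == 1:
            freqs = np.array([p0])
        else:
            c = config.pool_concentration
            freqs = rng.beta(c * p0, c * (1 - p0), size=config.n_pools)
        geno = (
            rng.random((config.n_individuals, 2)) < freqs[pools][:, None]
        ).astype(np.int8)
        li = bisect.bisect_right(locus_starts, pos0) - 1
        locus_id = locus_pos = None
        if li >= 0:
            locus = loci[li]
            off = pos0 - locus.start0
            if 0 <= off < locus.zone_len:
                locus_id = locus.locus_id
                locus_pos = off + 1
        snps.append(
            PlantedSnp(
                pos0=pos0,
                ref=ref,
                alt=alt,
                pool_freqs=freqs,
                genotypes=geno,
                locus_id=locus_id,
                locus_pos=locus_pos,
            )
        )

    # --- haplotype realisation ---------------------------------------------
    haplotypes: list[tuple[str, str]] = []
    offsets: list[tuple[list, list]] = []
    for ind in range(config.n_individuals):
        pair_seqs = []
        pair_offsets = []
        for hap in (0, 1):
            events: list[tuple[int, str, object]] = [
                (s.pos0, "snp", s) for s in snps if s.genotypes[ind, hap] == 1
            ] + [(r.start0, "ssr", r) for r in ssrs]
            events.sort(key=lambda e: e[0])
            parts = []
            cur = 0
            shift = 0
            bps = [(0, 0)]
            for pos, kind, obj in events:
                parts.append(genome_str[cur:pos])
                if kind == "snp":
                    parts.append(obj.alt)
                    cur = pos + 1
                else:
                    u = int(obj.units[ind, hap])
                    parts.append(obj.motif * u)
                    cur = pos + obj.ref_len
                    shift += len(obj.motif) * u - obj.ref_len
                    bps.append((cur, shift))
            parts.append(genome_str[cur:])
            pair_seqs.append("".join(parts))
            pair_offsets.append(bps)
        haplotypes.append(tuple(pair_seqs))
        offsets.append(tuple(pair_offsets))

    return TruthSet(
        config=config,
        genome=genome_str,
        samples=config.samples,
        loci=loci,
        snps=snps,
        ssrs=ssrs,
        haplotypes=haplotypes,
        _offsets=offsets,
    )


def _draw_fragment(rng: np.random.Generator, config: SimulationConfig) -> int:
    lo = max(config.read_length // 2, 30)
    hi = 2 * config.fragment_mean
    for _ in range(200):
        f = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        if lo <= f <= hi:
            return f
    return int(np.clip(config.fragment_mean, lo, hi))


def simulate_reads(truth: TruthSet, config: SimulationConfig) -> list[ReadPair]:
    """Emit paired reads from the haplotypes, with adapter read-through and error.

    Mean per-locus depth per individual is ~``coverage`` (Poisson(coverage/2)
    molecules per haplotype).  When the drawn molecule is shorter than the read
    length, both reads run into the adapter starting at position fragment_length
    (before errors).  True molecule lengths per read pair are recorded in
    ``truth.fragments``.
    """
    rng = np.random.default_rng([config.seed, 202])
    L = config.read_length
    pad = "G" * L  # past-adapter filler for very short molecules
    qual = "I" * L
    pairs: list[ReadPair] = []
    truth.fragments = []
    serial = 0
    for ind, sample in enumerate(truth.samples):
        barcode = (config.barcode_map or {}).get(sample, "")
        for locus in truth.loci:
            for hap in (0, 1):
                for _ in range(rng.poisson(config.coverage / 2.0)):
                    frag_len = _draw_fragment(rng, config)
                    start = truth.hap_pos(ind, hap, locus.start0)
                    frag = truth.haplotypes[ind][hap][start : start + frag_len]
                    if len(frag) < frag_len:
                        continue  # locus too close to the genome end
                    fwd = (frag + config.adapter_seq + pad)[:L]
                    rev = (revcomp(frag) + config.adapter_seq + pad)[:L]
                    fwd = mutate(rng, fwd, config.error_rate)
                    rev = mutate(rng, rev, config.error_rate)
                    if barcode:
                        fwd = barcode + fwd
                    read_id = f"r{serial:07d}"
                    serial += 1
                    pairs.append(
                        ReadPair(
                            read_id=read_id,
                            forward_seq=fwd,
                            reverse_seq=rev,
                            forward_qual="I" * len(fwd),
                            reverse_qual=qual,
                            sample_id="" if barcode else sample,
                            barcode=barcode,
                        )
                    )
                    truth.fragments.append(
                        FragmentRecord(
                            read_id=read_id,
                            sample=sample,
                            locus_id=locus.locus_id,
                            hap=hap,
                            frag_len=frag_len,
                            readthrough=max(0, L - frag_len),
                        )
                    )
    return pairs


def simulate_depth_table(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Per-site, per-individual depths over every locus zone position.

    Depths are Poisson(coverage) draws; this stands in for the mapping-based
    depth accounting of a read-alignment stage and covers variant and invariant
    sites alike, which is what the invariant-site denominator of total
    nucleotide diversity needs.
    """
    rng = np.random.default_rng([config.seed, 303])
    frames = []
    n = config.n_individuals
    for locus in truth.loci:
        depths = rng.poisson(config.coverage, size=(locus.zone_len, n))
        frames.append(
            pd.DataFrame(
                {
                    "contig": locus.locus_id,
                    "pos": np.repeat(np.arange(1, locus.zone_len + 1), n),
                    "sample": np.tile(np.array(truth.samples), locus.zone_len),
                    "depth": depths.reshape(-1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_variant_sites(
    truth: TruthSet, depth_table: Optional[pd.DataFrame] = None
):
    """Planted SNPs as in-memory ``diversity.VariantSite`` records.

    Equivalent to writing the truth VCF and reading it back; handy for
    calibration experiments that never touch disk.  Depths match the ones the
    companion depth table reports.
    """
    from .diversity import VariantSite

    config = truth.config
    if depth_table is None:
        depth_table = simulate_depth_table(truth, config)
    lookup = {}
    for locus in truth.loci:
        sub = depth_table[depth_table["contig"] == locus.locus_id]
        lookup[locus.locus_id] = sub.pivot_table(
            index="pos", columns="sample", values="depth", aggfunc="first"
        )
    sites = []
    for snp in truth.snps:
        if snp.locus_id is None:
            continue
        mat = lookup[snp.locus_id]
        depths = np.array(
            [int(mat.loc[snp.locus_pos, s]) for s in truth.samples]
        )
        sites.append(
            VariantSite(
                contig=snp.locus_id,
                pos=snp.locus_pos,
                ref=snp.ref,
                alts=[snp.alt],
                genotypes=snp.genotypes.astype(int).copy(),
                depths=depths,
                qual=999.0,
            )
        )
    sites.sort(key=lambda s: (s.contig, s.pos))
    return sites, depth_table


def emit_truth_vcf(
    truth: TruthSet, depth_table: Optional[pd.DataFrame] = None
) -> tuple[str, pd.DataFrame]:
    """Render the planted SNPs as VCFv4.2 text plus the companion depth table.

    Only SNPs that fall inside a locus zone are emitted (those are the sites a
    mapping stage could have called); coordinates are contig-local and 1-based.
    Per-sample DP fields are taken from the depth table so the VCF and the
    invariant-site accounting are mutually consistent.
    """
    config = truth.config
    if depth_table is None:
        depth_table = simulate_depth_table(truth, config)
    # depth lookup indexed by (contig, pos, sample)
    depth_lookup = {}
    for locus in truth.loci:
        sub = depth_table[depth_table["contig"] == locus.locus_id]
        mat = sub.pivot_table(
            index="pos", columns="sample", values="depth", aggfunc="first"
        )
        depth_lookup[locus.locus_id] = mat

    header = [
        "##fileformat=VCFv4.2",
        "##source=radforge-synthdata",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for locus in truth.loci:
        header.append(f"##contig=<ID={locus.locus_id},length={locus.zone_len}>")
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(truth.samples)
    )
    records = []
    emitted = [s for s in truth.snps if s.locus_id is not None]
    emitted.sort(key=lambda s: (s.locus_id, s.locus_pos))
    for snp in emitted:
        mat = depth_lookup[snp.locus_id]
        cols = [
            "{}/{}:{}".format(
                snp.genotypes[i, 0],
                snp.genotypes[i, 1],
                int(mat.loc[snp.locus_pos, sample]),
            )
            for i, sample in enumerate(truth.samples)
        ]
        records.append(
            "\t".join(
                [
                    snp.locus_id,
                    str(snp.locus_pos),
                    ".",
                    snp.ref,
                    snp.alt,
                    "999",
                    "PASS",
                    ".",
                    "GT:DP",
                ]
                + cols
            )
        )
    return "\n".join(header + records) + "\n", depth_table
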