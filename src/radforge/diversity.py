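"""Variant filtering, SNP dataset construction and nucleotide diversity.

Three nested SNP datasets are built from a called VCF:

1. genotype calls outside the per-sample depth window [5, 200) are masked;
   sites are kept when variant quality >= 300, minor allele frequency > 0.05
   (after masking) and the genotype is present in >= 10 individuals;
2. a configurable list of low-yield individuals is removed, then sites must be
   present in >= 80% of the remaining individuals and lie between 11 and 80 bp
   (1-based, inclusive) on the forward contig — the window where forward-read
   coverage is uniform;
3. one SNP per forward contig (first by position, or random with a seed).

Per-site nucleotide diversity uses the unbiased pairwise estimator
pi = 1 - sum_a c_a (c_a - 1) / (n (n - 1)) over called allele counts c_a
(for a biallelic site with counts k and n-k this is k (n-k) / C(n, 2)).
Total diversity divides the summed per-site values by the number of *callable*
sites — variant or invariant — that meet a minimum depth in a minimum fraction
of individuals, and its confidence interval comes from a percentile bootstrap
across sites (invariant sites resampled as zeros).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

MISSING = -1


@dataclass
class VariantSite:
    contig: str
    pos: int  # 1-based on the forward contig
    ref: str
    alts: list[str]
    genotypes: np.ndarray  # (n_individuals, 2) allele codes, -1 = missing
    depths: np.ndarray  # (n_individuals,)
    qual: float

    @property
    def n_called(self) -> int:
        """Individuals with a fully called genotype."""
        return int(((self.genotypes != MISSING).all(axis=1)).sum())

    @property
    def allele_counts(self) -> np.ndarray:
        called = self.genotypes[self.genotypes != MISSING]
        if called.size == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(called, minlength=len(self.alts) + 1)

    @property
    def maf(self) -> float:
        counts = self.allele_counts
        total = counts.sum()
        if total == 0:
            return 0.0
        freqs = np.sort(counts / total)[::-1]
        if len(freqs) < 2:
            return 0.0
        # frequency of the second most common allele (0 when monomorphic)
        return float(freqs[1])

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass(frozen=True)
class FilterParams:
    min_qual: float = 300.0
    min_sample_depth: int = 5
    max_sample_depth: int = 200  # exclusive
    min_maf: float = 0.05  # strict >
    min_individuals: int = 10


@dataclass
class PiEstimate:
    pi_total: float
    ci_low: float
    ci_high: float
    n_sites_total: int
    n_variant_sites: int
    n_bootstrap: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# VCF input


def read_vcf(path: str) -> tuple[list[str], list[VariantSite]]:
    """Load a VCF (plain or bgzipped) into VariantSite records via cyvcf2.

    Records without parseable genotypes are skipped and counted in the logger;
    the count is returned via the module-level attribute of the list for
    simplicity of the CLI report.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    skipped = 0
    for v in vcf:
        try:
            gts = np.array([g[:2] for g in v.genotypes], dtype=int)
            gts[gts < 0] = MISSING
            try:
                dp = v.format("DP")
                depths = (
                    np.array(dp).reshape(-1).astype(float)
                    if dp is not None
                    else np.zeros(len(samples))
                )
                depths[~np.isfinite(depths)] = 0
                depths = depths.astype(int)
            except Exception:
                depths = np.zeros(len(samples), dtype=int)
            sites.append(
                VariantSite(
                    contig=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=list(v.ALT),
                    genotypes=gts,
                    depths=depths,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                )
            )
        except Exception:
            skipped += 1
    sites_skipped[0] = skipped
    return samples, sites


#: count of records skipped by the most recent read_vcf call (CLI reporting)
sites_skipped = [0]


# ---------------------------------------------------------------------------
# dataset filters


def filter_variants(
    sites: Sequence[VariantSite], params: FilterParams = FilterParams()
) -> list[VariantSite]:
    """Dataset 1: depth-mask genotypes, then apply quality/MAF/presence rules.

    Returns deep copies: genotype calls whose per-sample depth falls outside
    [min_sample_depth, max_sample_depth) are set missing before the MAF and
    presence rules are evaluated.
    """
    out = []
    for site in sites:
        s = copy.deepcopy(site)
        bad = (s.depths < params.min_sample_depth) | (
            s.depths >= params.max_sample_depth
        )
        s.genotypes[bad, :] = MISSING
        if s.qual < params.min_qual:
            continue
        if not s.maf > params.min_maf:
            continue
        if s.n_called < params.min_individuals:
            continue
        out.append(s)
    return out


def make_dataset2(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    drop_individuals: Sequence[str] = (),
    min_presence: float = 0.8,
    pos_window: tuple[int, int] = (11, 80),
) -> tuple[list[str], list[VariantSite]]:
    """Dataset 2: drop listed individuals, then keep sites present in >=80% of
    the rest and positioned 11..80 bp (inclusive) on the forward contig."""
    unknown = set(drop_individuals) - set(samples)
    if unknown:
        raise ConfigurationError(f"unknown individual(s): {sorted(unknown)}")
    keep_idx = [i for i, s in enumerate(samples) if s not in set(drop_individuals)]
    kept_samples = [samples[i] for i in keep_idx]
    lo, hi = pos_window
    out = []
    for site in sites:
        s = copy.deepcopy(site)
        s.genotypes = s.genotypes[keep_idx]
        s.depths = s.depths[keep_idx]
        if not lo <= s.pos <= hi:
            continue
        if s.n_called < min_presence * len(kept_samples):
            continue
        out.append(s)
    return kept_samples, out


def make_dataset3(
    sites: Sequence[VariantSite],
    mode: str = "first",
    seed: Optional[int] = None,
) -> list[VariantSite]:
    """Dataset 3: exactly one SNP per forward contig."""
    by_contig: dict[str, list[VariantSite]] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s)
    out = []
    rng = np.random.default_rng(seed) if mode == "random" else None
    for contig in sorted(by_contig):
        group = sorted(by_contig[contig], key=lambda s: s.pos)
        if mode == "first":
            out.append(group[0])
        elif mode == "random":
            out.append(group[int(rng.integers(0, len(group)))])
        else:
            raise ConfigurationError(f"unknown dataset-3 mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity


def site_pi(site: VariantSite) -> float:
    """Unbiased per-site nucleotide diversity from called allele counts."""
    counts = site.allele_counts
    n = int(counts.sum())
    if n < 2:
        raise InputError("site_pi needs at least two called alleles")
    return float(1.0 - (counts * (counts - 1)).sum() / (n * (n - 1)))


def callable_mask(
    depth_table: pd.DataFrame, min_depth: int = 5, min_presence: float = 0.8
) -> pd.DataFrame:
    """Per-site callability from the long-format depth table.

    Returns a frame with columns contig, pos, callable; a site is callable when
    depth >= min_depth in at least min_presence of all individuals in the table.
    """
    n_samples = depth_table["sample"].nunique()
    ok = (
        depth_table.assign(ok=depth_table["depth"] >= min_depth)
        .groupby(["contig", "pos"], sort=True)["ok"]
        .sum()
        .reset_index()
    )
    ok["callable"] = ok["ok"] >= min_presence * n_samples
    return ok[["contig", "pos", "callable"]]


def total_pi(
    sites: Sequence[VariantSite],
    depth_table: pd.DataFrame,
    min_depth: int = 5,
    min_presence: float = 0.8,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> PiEstimate:
    """Total nucleotide diversity over all callable sites, with bootstrap CI.

    The denominator counts every site in the depth table — variant or invariant
    — with depth >= ``min_depth`` in >= ``min_presence`` of individuals.  The
    numerator sums per-site pi over the variant sites at callable positions
    (with genotypes depth-masked the same way).  The CI is a percentile
    bootstrap across sites: the full site list is resampled, invariant sites
    contributing zeros.
    """
    mask = callable_mask(depth_table, min_depth, min_presence)
    callable_set = {
        (c, p) for c, p, ok in mask.itertuples(index=False) if ok
    }
    denominator = len(callable_set)
    if denominator == 0:
        raise InputError("no callable sites: denominator is zero")

    values = []
    for site in sites:
        if (site.contig, site.pos) not in callable_set:
            continue
        s = copy.deepcopy(site)
        s.genotypes[s.depths < min_depth, :] = MISSING
        try:
            values.append(site_pi(s))
        except InputError:
            continue  # fewer than two called alleles: counted in denominator only
    values = np.asarray(values, dtype=float)
    v = values.size
    pi_total = float(values.sum() / denominator)

    if v == 0 or n_bootstrap <= 0:
        lo = hi = pi_total if n_bootstrap > 0 else pi_total
        return PiEstimate(pi_total, lo, hi, denominator, v, n_bootstrap)

    rng = np.random.default_rng(seed)
    # resampling D sites uniformly; only draws that land on variant sites move
    # the mean, so draw the per-variant multiplicities directly
    probs = np.full(v + 1, 1.0 / denominator)
    probs[-1] = 1.0 - v / denominator
    counts = rng.multinomial(denominator, probs, size=n_bootstrap)[:, :v]
    boot = counts @ values / denominator
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PiEstimate(
        pi_total=pi_total,
        ci_low=float(lo),
        ci_high=float(hi),
        n_sites_total=denominator,
        n_variant_sites=v,
        n_bootstrap=n_bootstrap,
    )


def per_site_pi_table(sites: Sequence[VariantSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        try:
            rows.append((s.contig, s.pos, site_pi(s)))
        except InputError:
            continue
    return pd.DataFrame(rows, columns=["contig", "pos", "pi"])
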