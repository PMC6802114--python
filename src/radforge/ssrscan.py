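"""Perfect microsatellite (SSR) detection, motif classification and genotyping.

The scanner reports every maximal uninterrupted tandem run of a primitive
2-6 bp motif meeting the unit-count minima (5 units for dinucleotides, 4 for
tri- through hexa-). Motifs are grouped into canonical classes — the
lexicographically smallest string over all cyclic rotations of the motif and of
its reverse complement — so e.g. GT, CA and TG all report as class AC.

A simplified spanning-read allele caller genotypes each locus: a read is
informative when it fully spans the repeat with a minimum number of exactly
matching flank bases on each side, and the allele is the spanned repeat length
in bp.  The locus quality is a support-based score (not comparable to any
external genotyper's scale).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode, revcomp

DEFAULT_MIN_UNITS = {2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SsrParams:
    min_units: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_UNITS)
    )
    min_alleles_polymorphic: int = 2
    min_alleles_primer: int = 3
    min_flank: int = 200
    min_quality: float = 300.0


@dataclass
class SsrLocus:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str  # canonical class representative
    found_motif: str  # motif as it appears in the sequence
    unit_count: int
    left_flank: int
    right_flank: int
    #: (allele length in bp, supporting read count) pairs, filled by genotyping
    alleles: list[tuple[int, int]] = field(default_factory=list)
    quality: float = 0.0
    #: sample -> (allele1, allele2) in bp
    genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class representative: minimum over all cyclic rotations of the
    motif and of its reverse complement."""
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def motif_classes(length: int) -> set[str]:
    """All canonical classes of primitive motifs of the given length."""
    from itertools import product

    out = set()
    for combo in product("ACGT", repeat=length):
        motif = "".join(combo)
        if is_primitive(motif):
            out.add(canonical_motif(motif))
    return out


def scan_perfect(
    sequence: str, params: SsrParams = SsrParams(), contig: str = ""
) -> list[SsrLocus]:
    """All maximal perfect tandem runs of primitive 2-6 bp motifs.

    Runs are found per motif length as maximal stretches where ``s[i] ==
    s[i-m]`` (N breaks a run); only whole units are reported, so a trailing
    partial unit is excluded but guarantees that extension by one full unit is
    impossible.  The same physical run found under rotated motifs or composite
    motif lengths collapses to one locus; when runs of *different* classes
    overlap (one repeat eroding into another) the longer one wins.
    """
    n = len(sequence)
    arr = encode(sequence)
    valid = (
        (arr == ord("A"))
        | (arr == ord("C"))
        | (arr == ord("G"))
        | (arr == ord("T"))
    )
    candidates = []  # (length, start0, m, units)
    for m in range(2, 7):
        if n < 2 * m:
            continue
        eq = (arr[m:] == arr[:-m]) & valid[m:] & valid[:-m]
        # maximal True runs in eq: eq[i] covers sequence position i+m
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        min_units = params.min_units.get(m, 10**9)
        for s0, e0 in zip(starts, ends):
            a = int(s0)  # run spans sequence [a, e0 + m)
            span = int(e0) - a + m
            if not is_primitive(sequence[a : a + m]):
                continue
            # one candidate per left-maximal phase: when an adjacent locus of a
            # different period claims the run's first bases, a re-phased start
            # inside the first unit can still be a maximal perfect run
            for d in range(m):
                units = (span - d) // m
                if units < min_units:
                    break
                start = a + d
                if d and start >= m and (
                    sequence[start - m : start] == sequence[start : start + m]
                ):
                    continue  # extendable left: not maximal under this phase
                candidates.append((units * m, start, m, units))
    # longer loci win overlaps; ties resolved leftmost then shortest motif
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken: list[tuple[int, int]] = []
    loci = []
    for length, a, m, units in candidates:
        b = a + length
        if any(a < e and s < b for s, e in taken):
            continue
        taken.append((a, b))
        motif = sequence[a : a + m]
        loci.append(
            SsrLocus(
                contig=contig,
                start=a + 1,
                end=b,
                motif=canonical_motif(motif),
                found_motif=motif,
                unit_count=units,
                left_flank=a,
                right_flank=n - b,
            )
        )
    loci.sort(key=lambda l: l.start)
    return loci


def summarize_composition(loci: Sequence[SsrLocus]) -> dict[str, pd.DataFrame]:
    """Counts and fractions of loci by motif length and by canonical class."""
    if not loci:
        empty = pd.DataFrame(columns=["count", "fraction"])
        return {"by_length": empty, "by_class": empty}
    df = pd.DataFrame(
        {"motif_length": [l.motif_length for l in loci], "motif": [l.motif for l in loci]}
    )
    by_length = df.groupby("motif_length").size().to_frame("count")
    by_length["fraction"] = by_length["count"] / len(df)
    by_class = df.groupby(["motif_length", "motif"]).size().to_frame("count")
    by_class["fraction"] = by_class["count"] / len(df)
    return {"by_length": by_length, "by_class": by_class}


# ---------------------------------------------------------------------------
# spanning-read allele calling


def _is_perfect_repeat(segment: str, canonical: str) -> bool:
    m = len(canonical)
    if len(segment) < m or len(segment) % m:
        return False
    motif = segment[:m]
    if segment != motif * (len(segment) // m):
        return False
    try:
        return canonical_motif(motif) == canonical
    except ValueError:
        return False


def _read_allele(
    read: str, left_anchor: str, right_anchor: str, canonical: str, min_border: int
) -> Optional[int]:
    """Allele length measured from one read orientation, or None."""
    alleles = set()
    start = 0
    while True:
        l = read.find(left_anchor, start)
        if l == -1:
            break
        start = l + 1
        inner = l + min_border
        r = read.find(right_anchor, inner)
        while r != -1:
            segment = read[inner:r]
            if _is_perfect_repeat(segment, canonical):
                alleles.add(len(segment))
            r = read.find(right_anchor, r + 1)
    if len(alleles) == 1:
        return alleles.pop()
    return None  # absent or ambiguous


@dataclass
class AlleleCall:
    locus: SsrLocus
    genotypes: dict[str, tuple[int, int]]
    allele_table: list[tuple[int, int]]
    quality: float
    informative_reads: int


def call_ssr_alleles(
    locus: SsrLocus,
    contig_seq: str,
    reads_by_individual: Mapping[str, Sequence[str]],
    min_border: int = 5,
) -> Optional[AlleleCall]:
    """Genotype one SSR locus from reads spanning it.

    A read (in either orientation) is informative when it contains
    ``min_border`` exactly matching flank bases on each side of a perfect
    repeat of the locus class; the allele is the spanned repeat length.  Each
    individual gets up to the two best-supported allele lengths (the second
    requires support of at least 2 reads and a quarter of the first).  Returns
    None when no read is informative.
    """
    a0 = locus.start - 1
    b0 = locus.end
    if a0 < min_border or b0 + min_border > len(contig_seq):
        return None
    left_anchor = contig_seq[a0 - min_border : a0]
    right_anchor = contig_seq[b0 : b0 + min_border]
    genotypes: dict[str, tuple[int, int]] = {}
    pooled: Counter = Counter()
    total_informative = 0
    quality = 0.0
    for sample in sorted(reads_by_individual):
        support: Counter = Counter()
        for read in reads_by_individual[sample]:
            for oriented in (read, revcomp(read)):
                allele = _read_allele(
                    oriented, left_anchor, right_anchor, locus.motif, min_border
                )
                if allele is not None:
                    support[allele] += 1
                    break
        if not support:
            continue
        total_informative += sum(support.values())
        quality += 10.0 * float(np.log2(1 + sum(support.values())))
        ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
        a1, c1 = ranked[0]
        if len(ranked) > 1 and ranked[1][1] >= max(2, 0.25 * c1):
            a2 = ranked[1][0]
        else:
            a2 = a1
        genotypes[sample] = tuple(sorted((a1, a2)))
        pooled.update(support)
    if total_informative == 0:
        return None
    allele_table = sorted(pooled.items())
    locus.alleles = allele_table
    locus.quality = quality
    locus.genotypes = genotypes
    return AlleleCall(
        locus=locus,
        genotypes=genotypes,
        allele_table=allele_table,
        quality=quality,
        informative_reads=total_informative,
    )


# ---------------------------------------------------------------------------
# polymorphism summary


@dataclass
class PolymorphismStats:
    per_locus: pd.DataFrame
    kruskal_stat: float
    kruskal_p: float
    pearson_r: float
    pearson_p: float


def polymorphism_stats(loci: Sequence[SsrLocus]) -> PolymorphismStats:
    """Allele-number distribution by motif length, a Kruskal-Wallis rank test of
    allele number across motif lengths, and the Pearson correlation of allele
    number with mean allele length.  Degenerate inputs yield NaN statistics."""
    rows = [
        (
            l.contig,
            l.motif_length,
            l.n_alleles,
            float(np.mean([a for a, _ in l.alleles])) if l.alleles else np.nan,
        )
        for l in loci
        if l.alleles
    ]
    df = pd.DataFrame(
        rows, columns=["contig", "motif_length", "n_alleles", "mean_allele_len"]
    )
    kw_stat = kw_p = r = rp = float("nan")
    groups = [
        g["n_alleles"].to_numpy()
        for _, g in df.groupby("motif_length")
        if len(g) > 0
    ]
    if len(groups) >= 2 and len(df) >= 3:
        try:
            kw_stat, kw_p = stats.kruskal(*groups)
        except ValueError:
            pass  # all values identical
    if len(df) >= 3 and df["n_alleles"].nunique() > 1 and df[
        "mean_allele_len"
    ].nunique() > 1:
        r, rp = stats.pearsonr(df["n_alleles"], df["mean_allele_len"])
    return PolymorphismStats(
        per_locus=df,
        kruskal_stat=float(kw_stat),
        kruskal_p=float(kw_p),
        pearson_r=float(r),
        pearson_p=float(rp),
    )


def loci_table(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """MISA-style tabular view of scanned loci."""
    return pd.DataFrame(
        [
            (
                l.contig,
                l.start,
                l.end,
                l.motif,
                l.found_motif,
                l.unit_count,
                l.left_flank,
                l.right_flank,
                l.n_alleles,
                l.quality,
            )
            for l in loci
        ],
        columns=[
            "contig",
            "start",
            "end",
            "class",
            "motif",
            "units",
            "left_flank",
            "right_flank",
            "n_alleles",
            "quality",
        ],
    )
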