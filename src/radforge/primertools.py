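"""Primer design over SSR flanks and in-silico PCR validation.

Candidate primer pairs are enumerated exhaustively over the masked flanking
sequence under the screening constraints (length 18-24 nt with optimum 21,
product 125-250 bp containing the repeat, melting temperature 55-65 degC with
optimum 60, GC 40-60% with optimum 50%, no N anywhere in a primer) and ranked
by distance from the optima.  Tm uses the simple GC rule
``64.9 + 41 * (GC_count - 16.4) / length`` — deterministic and adequate for
relative screening, but not comparable with thermodynamic nearest-neighbour
models.

Electronic PCR then searches every contig, on both strands, for binding sites
within a per-primer budget of two mismatches and two gaps, requiring the last
three 3' bases to match exactly (mispriming at the 3' terminus does not
amplify).  The gap budget is a net indel in the priming duplex — all gaps in
one alignment lie on the same side — and the 5'-terminal base must pair, so
gaps can neither disguise extra substitutions nor dangle the primer end.  Pairs that amplify exactly one product across the whole contig set
are the final high-quality panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._seq import revcomp
from .errors import InputError
from .ssrscan import SsrLocus


def melting_temperature(primer: str) -> float:
    """GC-rule melting temperature in degrees Celsius."""
    gc = primer.count("G") + primer.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def gc_fraction(primer: str) -> float:
    return (primer.count("G") + primer.count("C")) / len(primer)


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 18
    max_length: int = 24
    opt_length: int = 21
    min_product: int = 125
    max_product: int = 250
    min_tm: float = 55.0
    max_tm: float = 65.0
    opt_tm: float = 60.0
    min_gc: float = 0.40
    max_gc: float = 0.60
    opt_gc: float = 0.50


@dataclass
class PrimerPair:
    locus_id: str
    left_seq: str
    right_seq: str  # 5'->3' on the minus strand
    left_start: int  # 1-based position of the left primer's 5' base
    right_end: int  # 1-based position of the right primer's 5' base (plus strand)
    product_size: int
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    penalty: float = 0.0


def mask_variants(contig_seq: str, positions: Sequence[int]) -> str:
    """Replace each 1-based variant position with N (length preserved)."""
    seq = list(contig_seq)
    for pos in positions:
        if not 1 <= pos <= len(seq):
            raise InputError(
                f"variant position {pos} outside contig of length {len(seq)}"
            )
        seq[pos - 1] = "N"
    return "".join(seq)


def _window_ok(primer: str, c: PrimerConstraints) -> bool:
    if "N" in primer:
        return False
    if not c.min_gc <= gc_fraction(primer) <= c.max_gc:
        return False
    return c.min_tm <= melting_temperature(primer) <= c.max_tm


def _penalty(primer: str, c: PrimerConstraints) -> float:
    return (
        abs(len(primer) - c.opt_length)
        + abs(melting_temperature(primer) - c.opt_tm)
        + 20.0 * abs(gc_fraction(primer) - c.opt_gc)
    )


def design_candidates(
    locus: SsrLocus,
    masked_contig: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    flank_search: int = 200,
    max_candidates: Optional[int] = None,
) -> list[PrimerPair]:
    """Exhaustively enumerate valid primer pairs around one SSR locus.

    Left primers end before the repeat start, right primers begin after the
    repeat end (given 5'->3' on the minus strand), both within
    ``flank_search`` bp of the repeat, and the product must contain the repeat
    with a size inside the constraint window.  Candidates are ranked by summed
    distance from the length/Tm/GC optima.
    """
    a0 = locus.start - 1  # repeat interval [a0, b0) 0-based
    b0 = locus.end
    n = len(masked_contig)
    lefts = []
    for length in range(constraints.min_length, constraints.max_length + 1):
        # window end (exclusive) must not enter the repeat
        for end in range(max(length, a0 - flank_search), a0 + 1):
            s = end - length
            if s < 0:
                continue
            primer = masked_contig[s:end]
            if _window_ok(primer, constraints):
                lefts.append((s, primer))
    rights = []
    for length in range(constraints.min_length, constraints.max_length + 1):
        for start in range(b0, min(n, b0 + flank_search) - length + 1):
            window = masked_contig[start : start + length]
            primer = revcomp(window)
            if _window_ok(primer, constraints):
                rights.append((start + length - 1, primer))  # 0-based end

    pairs = []
    for s, left in lefts:
        for e, right in rights:
            product = e - s + 1
            if not constraints.min_product <= product <= constraints.max_product:
                continue
            pairs.append(
                PrimerPair(
                    locus_id=f"{locus.contig}:{locus.start}-{locus.end}",
                    left_seq=left,
                    right_seq=right,
                    left_start=s + 1,
                    right_end=e + 1,
                    product_size=product,
                    tm_left=melting_temperature(left),
                    tm_right=melting_temperature(right),
                    gc_left=gc_fraction(left),
                    gc_right=gc_fraction(right),
                    penalty=_penalty(left, constraints) + _penalty(right, constraints),
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.left_start, p.right_end))
    return pairs[:max_candidates] if max_candidates else pairs


# ---------------------------------------------------------------------------
# electronic PCR


@dataclass(frozen=True)
class BindingSite:
    contig: str
    strand: str  # "+" | "-"
    start: int  # 1-based inclusive, plus-strand coordinates
    end: int
    mismatches: int
    gaps: int


@dataclass
class EpcrHit:
    contig: str
    forward_site: BindingSite  # plus-strand (5') binding site
    reverse_site: BindingSite  # minus-strand (3') binding site
    product_size: int


def _align_tail(primer_head: str, text: str, end0: int, max_mm: int, max_gaps: int):
    """Align the primer (minus its 3' anchor) against text ending at ``end0``.

    Returns (mismatches, gaps, text_start0), or None when no alignment
    qualifies.  The budgets apply to the *minimal* edit script: among all
    alignments, the ones with the fewest total edits (mismatches + gaps) are
    found first, and the site binds only if one of them fits both per-type
    budgets.  A primer differing from a site by three substitutions is
    therefore never rescued by a costlier gapped alignment.  Gaps are a net
    indel in the duplex (all on one side) and the 5'-terminal base must pair.
    """
    q = len(primer_head)
    if q == 0:
        return (0, 0, end0 + 1)
    rev = primer_head[::-1]
    budget = max_mm + max_gaps
    # alignments[total] -> list of (mm, g, start0)
    found: dict[int, list] = {}
    best_total = [budget + 1]

    def rec(i: int, j: int, mm: int, g: int, gap_side: str) -> None:
        if mm + g > min(budget, best_total[0]):
            return
        if i == q:
            total = mm + g
            found.setdefault(total, []).append((mm, g, end0 - j + 1))
            best_total[0] = min(best_total[0], total)
            return
        pos = end0 - j
        if pos >= 0:
            rec(i + 1, j + 1, mm + (rev[i] != text[pos]), g, gap_side)
            if gap_side != "p":  # unpaired text base
                rec(i, j + 1, mm, g + 1, "t")
        # unpaired primer base; the 5'-terminal base must pair (no dangling end)
        if gap_side != "t" and i < q - 1:
            rec(i + 1, j, mm, g + 1, "p")

    rec(0, 0, 0, 0, "")
    if not found:
        return None
    minimal = found[min(found)]
    feasible = [c for c in minimal if c[0] <= max_mm and c[1] <= max_gaps]
    return min(feasible) if feasible else None


def _find_sites(
    primer: str, contig: str, name: str, max_mm: int, max_gaps: int
) -> list[BindingSite]:
    """Plus-strand binding sites of a primer (3' end pointing right)."""
    sites = []
    anchor = primer[-3:]
    head = primer[:-3]
    start = 0
    while True:
        i = contig.find(anchor, start)
        if i == -1:
            break
        start = i + 1
        res = _align_tail(head, contig, i - 1, max_mm, max_gaps)
        if res is not None:
            mm, g, s0 = res
            sites.append(
                BindingSite(
                    contig=name,
                    strand="+",
                    start=s0 + 1,
                    end=i + 3,
                    mismatches=mm,
                    gaps=g,
                )
            )
    return sites


def find_binding_sites(
    primer: str,
    contigs: Mapping[str, str],
    max_mismatches: int = 2,
    max_gaps: int = 2,
) -> list[BindingSite]:
    """All binding sites of one primer over both strands of every contig.

    The last three 3' bases must match exactly; mismatch and gap budgets apply
    per primer.  Coordinates are 1-based on the plus strand.
    """
    out = []
    for name in sorted(contigs):
        seq = contigs[name]
        out.extend(_find_sites(primer, seq, name, max_mismatches, max_gaps))
        for site in _find_sites(
            primer, revcomp(seq), name, max_mismatches, max_gaps
        ):
            out.append(
                BindingSite(
                    contig=name,
                    strand="-",
                    start=len(seq) - site.end + 1,
                    end=len(seq) - site.start + 1,
                    mismatches=site.mismatches,
                    gaps=site.gaps,
                )
            )
    return out


def epcr(
    pair: PrimerPair,
    contigs: Mapping[str, str],
    max_mismatches: int = 2,
    max_gaps: int = 2,
    size_window: tuple[int, int] = (75, 300),
) -> list[EpcrHit]:
    """Predicted amplification products of a primer pair over a contig set.

    A product forms when one primer binds the plus strand upstream of the other
    primer bound on the minus strand (convergent orientation) and the implied
    size falls inside ``size_window``.
    """
    left_sites = find_binding_sites(pair.left_seq, contigs, max_mismatches, max_gaps)
    right_sites = find_binding_sites(pair.right_seq, contigs, max_mismatches, max_gaps)
    lo, hi = size_window
    hits = []
    for plus_pool, minus_pool in (
        (left_sites, right_sites),
        (right_sites, left_sites),
    ):
        for fs in plus_pool:
            if fs.strand != "+":
                continue
            for rs in minus_pool:
                if rs.strand != "-" or rs.contig != fs.contig:
                    continue
                size = rs.end - fs.start + 1
                if fs.start <= rs.start and lo <= size <= hi:
                    hits.append(
                        EpcrHit(
                            contig=fs.contig,
                            forward_site=fs,
                            reverse_site=rs,
                            product_size=size,
                        )
                    )
    # the same physical product can be found from both pool orderings when the
    # two primers are identical; deduplicate on coordinates
    unique = {}
    for h in hits:
        key = (h.contig, h.forward_site.start, h.reverse_site.end)
        unique.setdefault(key, h)
    return [unique[k] for k in sorted(unique)]


def select_high_quality(
    pairs_with_hits: Sequence[tuple[PrimerPair, Sequence[EpcrHit]]],
) -> list[PrimerPair]:
    """Keep primer pairs that amplify exactly one product across all contigs."""
    return [pair for pair, hits in pairs_with_hits if len(hits) == 1]
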