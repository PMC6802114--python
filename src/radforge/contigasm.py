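"""Per-tag contig assembly and forward/reverse contig merging.

Forward reads of a RAD-tag are anchored at the restriction site, so the
forward contig is a stacked per-column majority consensus.  Reverse reads come
from individually sheared molecules and tile a staggered window, so the reverse
contig is built by a small greedy overlap-layout-consensus assembler whose
overlap rules mirror the CAP3 defaults that matter (overlap >= 16 bp at >= 80%
identity).

Merging follows the printed rules: the reverse contig is reverse-complemented
and globally aligned to the forward contig by Needleman-Wunsch with match +5
(mismatch -4, linear gap -8) and free end gaps; the merge is accepted as
"overlapped" only when the spliced sequence keeps both contig ends intact, the
score exceeds 50, the identity (count of exactly matching alignment columns)
exceeds 10, and score/identity exceeds 4 (i.e. at least ~80% of the score comes
from matches).  Rejected pairs are joined with a 10-N separator instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from ._seq import revcomp


@dataclass
class Contig:
    tag_id: str
    side: str  # "forward" | "reverse"
    sequence: str
    support_fraction: float
    n_reads: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError("support_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MergeParams:
    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_penalty: float = -8.0
    min_score: float = 50.0
    min_identity: int = 10
    min_score_identity_ratio: float = 4.0
    end_anchor: int = 10
    separator: str = "N" * 10


@dataclass
class MergedContig:
    tag_id: str
    sequence: str
    mode: str  # "overlapped" | "n_joined"
    score: float = 0.0
    identity: int = 0
    fwd_support: float = 0.0
    rev_support: float = 0.0


# ---------------------------------------------------------------------------
# forward assembly: stacked consensus


def assemble_forward(reads: list[str], tag_id: str = "") -> Optional[Contig]:
    """Majority consensus over restriction-anchored forward reads.

    Reads may differ in length (adapter-trimmed molecules are shorter); each
    column is voted on by the reads that cover it and columns covered by fewer
    than two reads are dropped from the 3' end (unless only one read exists).
    Support is the fraction of reads >= 80% identical to the consensus over
    their covered span.
    """
    if not reads:
        return None
    max_len = max(len(r) for r in reads)
    min_cov = 2 if len(reads) > 1 else 1
    consensus = []
    for j in range(max_len):
        counts = Counter(r[j] for r in reads if len(r) > j)
        if sum(counts.values()) < min_cov:
            break
        best = max(sorted(counts), key=lambda b: counts[b])
        consensus.append(best)
    if not consensus:
        return None
    cons = "".join(consensus)
    supported = 0
    for r in reads:
        span = min(len(r), len(cons))
        if span == 0:
            continue
        matches = sum(a == b for a, b in zip(r[:span], cons[:span]))
        if matches >= 0.8 * span:
            supported += 1
    return Contig(
        tag_id=tag_id,
        side="forward",
        sequence=cons,
        support_fraction=supported / len(reads),
        n_reads=len(reads),
    )


# ---------------------------------------------------------------------------
# reverse assembly: greedy overlap-layout-consensus


class _Layout:
    """A growing multiple layout: per-column base votes plus member count."""

    __slots__ = ("columns", "n_reads")

    def __init__(self, seq: str):
        self.columns: list[Counter] = [Counter({b: 1}) for b in seq]
        self.n_reads = 1

    @property
    def consensus(self) -> str:
        return "".join(
            max(sorted(c), key=lambda b: c[b]) for c in self.columns
        )

    def __len__(self) -> int:
        return len(self.columns)


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float):
    """Best suffix(a)/prefix(b) overlap found via short exact seeds from b's
    start; returns (identity, overlap_len, offset_of_b_in_a) or None."""
    best = None
    seen_offsets = set()
    for seed_off in (0, 7, 14):
        seed = b[seed_off : seed_off + 12]
        if len(seed) < 12:
            break
        start = 0
        while True:
            i = a.find(seed, start)
            if i == -1:
                break
            start = i + 1
            offset = i - seed_off
            if offset < 0 or offset in seen_offsets:
                continue
            seen_offsets.add(offset)
            ov = min(len(a) - offset, len(b))
            if ov < min_overlap:
                continue
            matches = sum(
                x == y for x, y in zip(a[offset : offset + ov], b[:ov])
            )
            ident = matches / ov
            if ident >= min_identity:
                cand = (ident, ov, offset)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    return best


def _merge_layouts(a: _Layout, b: _Layout, offset: int) -> _Layout:
    merged = _Layout.__new__(_Layout)
    merged.columns = [Counter(c) for c in a.columns]
    while len(merged.columns) < offset + len(b.columns):
        merged.columns.append(Counter())
    for j, col in enumerate(b.columns):
        merged.columns[offset + j].update(col)
    merged.n_reads = a.n_reads + b.n_reads
    return merged


def assemble_reverse(
    reads: list[str],
    tag_id: str = "",
    min_overlap: int = 16,
    min_identity: float = 0.80,
) -> Optional[Contig]:
    """Greedy OLC assembly of a tag's reverse reads (kept in read orientation).

    Repeatedly merges the layout pair with the highest-identity overlap of
    length >= ``min_overlap`` and identity >= ``min_identity``; the final contig
    is the longest layout's per-column majority consensus, and support is the
    fraction of the bin's reads incorporated into it.
    """
    if not reads:
        return None
    total = len(reads)
    # collapse exact duplicates up front (they vote with their multiplicity)
    dup = Counter(reads)
    layouts = []
    for seq in sorted(dup):
        lay = _Layout.__new__(_Layout)
        lay.columns = [Counter({b: dup[seq]}) for b in seq]
        lay.n_reads = dup[seq]
        layouts.append(lay)

    def candidates(i: int, j: int):
        a, b = layouts[i].consensus, layouts[j].consensus
        out = []
        hit = _best_overlap(a, b, min_overlap, min_identity)
        if hit:
            out.append((hit[0], hit[1], i, j, hit[2]))
        hit = _best_overlap(b, a, min_overlap, min_identity)
        if hit:
            out.append((hit[0], hit[1], j, i, hit[2]))
        return out

    # precompute candidate overlaps
    pool: list[tuple] = []
    for i in range(len(layouts)):
        for j in range(i + 1, len(layouts)):
            pool.extend(candidates(i, j))

    alive = set(range(len(layouts)))
    while True:
        pool = [c for c in pool if c[2] in alive and c[3] in alive]
        if not pool:
            break
        ident, ov, i, j, offset = max(pool, key=lambda c: (c[0], c[1], -c[2], -c[3]))
        merged = _merge_layouts(layouts[i], layouts[j], offset)
        layouts.append(merged)
        k = len(layouts) - 1
        alive.discard(i)
        alive.discard(j)
        for other in sorted(alive):
            pool.extend(candidates(k, other))
        alive.add(k)

    best = max(
        (layouts[i] for i in alive), key=lambda l: (len(l), l.n_reads)
    )
    return Contig(
        tag_id=tag_id,
        side="reverse",
        sequence=best.consensus,
        support_fraction=best.n_reads / total,
        n_reads=total,
    )


# ---------------------------------------------------------------------------
# contig merging


def _aligner(params: MergeParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_penalty
    aligner.extend_gap_score = params.gap_penalty
    # free end gaps: the contigs overlap at their facing ends only
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _identity_from_alignment(aln, fwd: str, rev_rc: str) -> int:
    ident = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        ident += sum(a == b for a, b in zip(fwd[ts:te], rev_rc[qs:qe]))
    return ident


def merge_contigs(
    fwd: Contig, rev: Contig, params: MergeParams = MergeParams()
) -> MergedContig:
    """Merge a forward and a reverse contig into the final locus contig.

    See the module docstring for the acceptance rules.  In overlapped mode the
    spliced sequence keeps the forward contig up to the end of the aligned
    region and continues with the reverse-complemented reverse contig;
    mismatched overlap columns are resolved in favour of the contig with the
    higher read support.
    """
    rev_rc = revcomp(rev.sequence)
    n_joined = MergedContig(
        tag_id=fwd.tag_id,
        sequence=fwd.sequence + params.separator + rev_rc,
        mode="n_joined",
        fwd_support=fwd.support_fraction,
        rev_support=rev.support_fraction,
    )
    if len(fwd.sequence) < params.end_anchor or len(rev_rc) < params.end_anchor:
        return n_joined

    aln = _aligner(params).align(fwd.sequence, rev_rc)[0]
    score = float(aln.score)
    identity = _identity_from_alignment(aln, fwd.sequence, rev_rc)
    n_joined.score = score
    n_joined.identity = identity

    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return n_joined
    ts0, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
    qs0, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
    if fwd.support_fraction >= rev.support_fraction:
        merged_seq = fwd.sequence[:te] + rev_rc[qe:]
    else:
        merged_seq = fwd.sequence[:ts0] + rev_rc[qs0:]

    a = params.end_anchor
    accepted = (
        merged_seq[:a] == fwd.sequence[:a]
        and merged_seq[-a:] == rev_rc[-a:]
        and score > params.min_score
        and identity > params.min_identity
        and identity > 0
        and score / identity > params.min_score_identity_ratio
    )
    if not accepted:
        return n_joined
    return MergedContig(
        tag_id=fwd.tag_id,
        sequence=merged_seq,
        mode="overlapped",
        score=score,
        identity=identity,
        fwd_support=fwd.support_fraction,
        rev_support=rev.support_fraction,
    )


def merge_tag(
    fwd: Optional[Contig],
    rev: Optional[Contig],
    params: MergeParams = MergeParams(),
    min_fwd_support: float = 0.10,
    min_rev_support: float = 0.60,
) -> Optional[MergedContig]:
    """Apply the support floors (>=10% forward, >=60% reverse) and merge; tags
    failing the floors, or missing a side, are skipped."""
    if fwd is None or rev is None:
        return None
    if fwd.support_fraction < min_fwd_support or rev.support_fraction < min_rev_support:
        return None
    return merge_contigs(fwd, rev, params)


# ---------------------------------------------------------------------------
# pseudomolecule


@dataclass
class PseudoIndex:
    #: (tag_id, start0, length) in pseudomolecule order
    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def to_local(self, global_pos: int) -> Optional[tuple[str, int]]:
        """Map a 1-based pseudomolecule position to (tag_id, 1-based local)."""
        p0 = global_pos - 1
        for tag_id, start0, length in self.entries:
            if start0 <= p0 < start0 + length:
                return tag_id, p0 - start0 + 1
        return None

    def to_global(self, tag_id: str, local_pos: int) -> int:
        for tid, start0, length in self.entries:
            if tid == tag_id:
                if not 1 <= local_pos <= length:
                    raise ValueError("local position outside contig")
                return start0 + local_pos
        raise KeyError(tag_id)


def build_pseudomolecule(
    merged: list[MergedContig], spacer: str = "N" * 100
) -> tuple[str, PseudoIndex]:
    """Concatenate final contigs with 100-N spacers, in stable tag order."""
    if not merged:
        raise ValueError("need at least one contig")
    ordered = sorted(merged, key=lambda m: m.tag_id)
    index = PseudoIndex()
    parts = []
    pos = 0
    for i, contig in enumerate(ordered):
        if i:
            parts.append(spacer)
            pos += len(spacer)
        index.entries.append((contig.tag_id, pos, len(contig.sequence)))
        parts.append(contig.sequence)
        pos += len(contig.sequence)
    return "".join(parts), index
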