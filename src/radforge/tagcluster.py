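"""Stacks-style clustering of forward reads into RAD-tags.

Forward reads are anchored at the restriction site, so reads from one locus in
one individual are (nearly) identical over their first 85 bp.  Clustering is
therefore a simplified reimplementation of the usual stacks workflow: exact
piles -> depth-filtered stacks -> per-individual loci (alleles merged within a
mismatch budget) -> a cross-individual catalog by single-linkage matching,
followed by removal of depth-outlier (repetitive) tags and allocation of the
full-length read pairs to their tags.

This intentionally omits the SNP-model error correction and gapped matching of
the original stacks programs; on restriction-anchored reads the Hamming
neighbourhood is the right metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._seq import encode_matrix
from .errors import InputError
from .readprep import ReadPair


@dataclass(frozen=True)
class ClusterParams:
    trim_to: int = 85
    min_stack_depth: int = 3
    max_stack_mismatches: int = 2
    max_locus_mismatches: int = 3
    repeat_depth_factor: float = 3.0

    def __post_init__(self) -> None:
        if min(
            self.trim_to,
            self.min_stack_depth,
            self.max_stack_mismatches,
            self.max_locus_mismatches,
        ) < 0:
            raise ValueError("cluster parameters must be non-negative")


@dataclass
class IndividualLocus:
    """One clustered locus within one individual."""

    sample: str
    consensus: str
    #: pile sequence -> read ids carrying it (includes merged secondary piles)
    piles: dict[str, list[str]]

    @property
    def depth(self) -> int:
        return sum(len(v) for v in self.piles.values())

    @property
    def read_ids(self) -> list[str]:
        return [rid for ids in self.piles.values() for rid in ids]


@dataclass
class RadTag:
    tag_id: str
    consensus: str
    members: list[IndividualLocus]

    @property
    def depth_by_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.sample] = out.get(m.sample, 0) + m.depth
        return out

    @property
    def total_depth(self) -> int:
        return sum(m.depth for m in self.members)

    @property
    def read_ids(self) -> list[str]:
        return [rid for m in self.members for rid in m.read_ids]


def prepare_forward_reads(
    pairs: Iterable[ReadPair], trim_to: int = 85
) -> dict[str, str]:
    """Cut forward reads to a uniform length for clustering; reads that are
    already shorter (heavily trimmed pairs) are excluded."""
    return {
        p.read_id: p.forward_seq[:trim_to]
        for p in pairs
        if len(p.forward_seq) >= trim_to
    }


def _pairwise_hamming(seqs: list[str]) -> np.ndarray:
    mat = encode_matrix(seqs)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def _majority_consensus(weighted: list[tuple[str, int]]) -> str:
    """Per-column majority over sequences with multiplicities; ties go to the
    alphabetically smallest base (deterministic)."""
    length = len(weighted[0][0])
    mat = encode_matrix([s for s, _ in weighted])
    w = np.array([c for _, c in weighted])
    out = []
    for j in range(length):
        col = mat[:, j]
        best_base, best_count = None, -1
        for base in b"ACGTN":
            count = int(w[col == base].sum())
            if count > best_count:
                best_base, best_count = base, count
        out.append(chr(best_base))
    return "".join(out)


def _single_linkage(dist: np.ndarray, cutoff: int) -> list[list[int]]:
    n = dist.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def build_stacks(
    reads: Mapping[str, str], params: ClusterParams = ClusterParams(), sample: str = ""
) -> list[IndividualLocus]:
    """Cluster one individual's trimmed forward reads into loci.

    Exact-match piles with depth >= ``min_stack_depth`` seed stacks; seeds
    within ``max_stack_mismatches`` of each other are the alleles of one locus;
    lower-depth piles are attached to the nearest locus within the same budget
    and the rest are discarded as error singletons.
    """
    if not reads:
        return []
    lengths = {len(s) for s in reads.values()}
    if len(lengths) != 1:
        raise InputError("forward reads must share one length; trim first")

    piles: dict[str, list[str]] = {}
    for rid, seq in sorted(reads.items()):
        piles.setdefault(seq, []).append(rid)
    seed_seqs = sorted(
        [s for s, ids in piles.items() if len(ids) >= params.min_stack_depth],
        key=lambda s: (-len(piles[s]), s),
    )
    if not seed_seqs:
        return []
    dist = _pairwise_hamming(seed_seqs)
    groups = _single_linkage(dist, params.max_stack_mismatches)

    loci: list[IndividualLocus] = []
    for group in groups:
        members = {seed_seqs[i]: list(piles[seed_seqs[i]]) for i in group}
        consensus = _majority_consensus(
            [(s, len(ids)) for s, ids in members.items()]
        )
        loci.append(IndividualLocus(sample=sample, consensus=consensus, piles=members))

    secondary = sorted(
        s for s, ids in piles.items() if len(ids) < params.min_stack_depth
    )
    if secondary and loci:
        sec_mat = encode_matrix(secondary)
        con_mat = encode_matrix([l.consensus for l in loci])
        d = (sec_mat[:, None, :] != con_mat[None, :, :]).sum(axis=2)
        for i, seq in enumerate(secondary):
            j = int(np.argmin(d[i]))
            if d[i, j] <= params.max_stack_mismatches:
                loci[j].piles.setdefault(seq, []).extend(piles[seq])
    # refresh consensi after secondary merging
    for locus in loci:
        locus.consensus = _majority_consensus(
            [(s, len(ids)) for s, ids in locus.piles.items()]
        )
    return loci


def _kmedoids_split(seqs: list[str], dist: np.ndarray, k: int) -> list[list[int]]:
    """Deterministic k-medoids on a precomputed Hamming matrix (used to break
    single-linkage chains that exceed the diameter cap)."""
    n = len(seqs)
    # initial medoids: greedily pick mutually far points
    medoids = [int(np.argmax(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_to_m = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_to_m)))
    for _ in range(20):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            idx = np.flatnonzero(assign == c)
            if idx.size == 0:
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(idx, idx)].sum(axis=1)
            new_medoids.append(int(idx[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    return [list(np.flatnonzero(assign == c)) for c in range(k) if (assign == c).any()]


def build_catalog(
    stacks_by_sample: Mapping[str, list[IndividualLocus]],
    params: ClusterParams = ClusterParams(),
) -> list[RadTag]:
    """Match per-individual loci across samples into catalog RAD-tags.

    Single-linkage over locus consensi within ``max_locus_mismatches``; chains
    whose diameter exceeds twice that budget are split by k-medoids.  The tag
    consensus is a per-column majority vote over all member reads.
    """
    all_loci: list[IndividualLocus] = []
    for sample in sorted(stacks_by_sample):
        all_loci.extend(stacks_by_sample[sample])
    if not all_loci:
        return []
    consensi = [l.consensus for l in all_loci]
    dist = _pairwise_hamming(consensi)
    groups = _single_linkage(dist, params.max_locus_mismatches)

    final_groups: list[list[int]] = []
    cap = 2 * params.max_locus_mismatches
    for group in groups:
        sub = dist[np.ix_(group, group)]
        if sub.max() <= cap or len(group) <= 2:
            final_groups.append(group)
            continue
        k = 2
        while True:
            parts = _kmedoids_split([consensi[i] for i in group], sub, k)
            if all(
                sub[np.ix_(p, p)].max() <= cap for p in parts
            ) or k >= len(group):
                final_groups.extend([[group[i] for i in p] for p in parts])
                break
            k += 1

    tags = []
    for group in final_groups:
        members = [all_loci[i] for i in group]
        weighted = [
            (seq, len(ids)) for m in members for seq, ids in sorted(m.piles.items())
        ]
        tags.append(RadTag(tag_id="", consensus=_majority_consensus(weighted), members=members))
    tags.sort(key=lambda t: t.consensus)
    for i, tag in enumerate(tags):
        tag.tag_id = f"tag{i + 1:05d}"
    return tags


def drop_repetitive(
    tags: list[RadTag], params: ClusterParams = ClusterParams()
) -> tuple[list[RadTag], int]:
    """Remove depth-outlier tags (collapsed repeat families).

    A tag is "highly repetitive" when its total depth exceeds
    ``repeat_depth_factor`` times the median total depth.
    """
    if not tags:
        return [], 0
    depths = np.array([t.total_depth for t in tags], dtype=float)
    cutoff = params.repeat_depth_factor * float(np.median(depths))
    kept = [t for t, d in zip(tags, depths) if d <= cutoff]
    return kept, len(tags) - len(kept)


@dataclass
class PairAllocation:
    by_tag: dict[str, list[ReadPair]]
    missing_mates: int = 0
    unassigned_reads: int = field(default=0)


def allocate_pairs(
    tags: list[RadTag], pairs: Mapping[str, ReadPair]
) -> PairAllocation:
    """Bin full-length read pairs by the tag their forward read clustered into.

    The full (not cut-to-85) forward read and its mate go to the tag's bin;
    reads whose pair record is missing are skipped and counted.
    """
    by_tag: dict[str, list[ReadPair]] = {}
    missing = 0
    assigned = 0
    for tag in tags:
        bin_pairs = []
        for rid in tag.read_ids:
            pair = pairs.get(rid)
            if pair is None:
                missing += 1
                continue
            bin_pairs.append(pair)
            assigned += 1
        by_tag[tag.tag_id] = bin_pairs
    return PairAllocation(
        by_tag=by_tag,
        missing_mates=missing,
        unassigned_reads=max(0, len(pairs) - assigned),
    )
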