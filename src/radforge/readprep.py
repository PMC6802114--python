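"""Paired-read preparation: barcode demultiplexing and 3' adapter read-through removal.

RAD libraries sheared to ~600 bp occasionally yield molecules shorter than the
read length; both reads of such a pair run through the insert into the
sequencing adapter at their 3' end.  Because the two mates cover the *same*
short molecule from opposite ends, the insert boundary can be inferred without
knowing the adapter sequence: a probe taken from the 5' end of one mate is slid
along the reverse complement of the other mate, 3' to 5' in 1 bp steps, and the
first offset at which the Hamming distance drops to the threshold marks the end
of the insert.  Everything 3' of that boundary is adapter and is removed from
both mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from ._seq import encode, revcomp
from .errors import ConfigurationError


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with per-base Phred qualities and sample provenance."""

    read_id: str
    forward_seq: str
    reverse_seq: str
    forward_qual: str
    reverse_qual: str
    sample_id: str = ""
    barcode: str = ""

    def __post_init__(self) -> None:
        if not self.forward_seq or not self.reverse_seq:
            raise ValueError("read sequences must be non-empty")
        if len(self.forward_qual) != len(self.forward_seq) or len(
            self.reverse_qual
        ) != len(self.reverse_seq):
            raise ValueError("quality string length must match sequence length")


@dataclass(frozen=True)
class ScanParams:
    """Probe size and Hamming threshold for the read-through scan."""

    probe_size: int = 50
    max_distance: int = 5
    min_read_length: int = 30  # pairs trimmed below this are discarded

    def __post_init__(self) -> None:
        if self.probe_size <= 0:
            raise ValueError("probe_size must be positive")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")


@dataclass
class TrimResult:
    pair: Optional[ReadPair]  # None when the pair was discarded as too short
    trimmed: bool
    boundary: Optional[int]  # inferred insert length, when a boundary was found


def scan_readthrough(
    anchor_read: str, scanned_read: str, params: ScanParams = ScanParams()
) -> Optional[int]:
    """Infer the insert length from a mate pair by the 5'-probe Hamming scan.

    The probe is the first ``probe_size`` bases of ``anchor_read``.  The scanned
    mate is reverse-complemented so probe and target share orientation, and the
    probe is slid over it starting from the alignment corresponding to the
    scanned read's 3' end, in 1 bp steps.  The first offset with Hamming
    distance <= ``max_distance`` wins (i.e. the longest candidate insert).

    Returns the inferred insert length (the boundary both mates should be
    truncated to), or None when no alignment qualifies or the scanned read is
    shorter than the probe.  A boundary equal to the scanned read length means
    "no read-through detected" and is reported as None.
    """
    if len(anchor_read) < params.probe_size or len(scanned_read) < params.probe_size:
        return None
    probe = encode(anchor_read[: params.probe_size])
    target = encode(revcomp(scanned_read))
    # windows[o] = target[o : o + probe_size]; offset o=0 is the 3'-most
    # alignment in the scanned read's own orientation.
    windows = np.lib.stride_tricks.sliding_window_view(target, params.probe_size)
    mismatches = (windows != probe).sum(axis=1)
    hits = np.flatnonzero(mismatches <= params.max_distance)
    if hits.size == 0:
        return None
    boundary = len(scanned_read) - int(hits[0])
    return None if boundary >= len(scanned_read) else boundary


def trim_pair(pair: ReadPair, params: ScanParams = ScanParams()) -> TrimResult:
    """Remove 3' adapter read-through from both mates of a pair.

    The scan is applied in both directions (forward probe against the reverse
    read, and reverse probe against the forward read).  When both scans find a
    boundary they normally agree; under sequencing error the smaller boundary is
    used, which removes adapter conservatively.  Both mates are truncated to the
    boundary.  Pairs trimmed below ``params.min_read_length`` are discarded.
    """
    b_from_fwd = scan_readthrough(pair.forward_seq, pair.reverse_seq, params)
    b_from_rev = scan_readthrough(pair.reverse_seq, pair.forward_seq, params)
    candidates = [b for b in (b_from_fwd, b_from_rev) if b is not None]
    if not candidates:
        return TrimResult(pair=pair, trimmed=False, boundary=None)
    boundary = min(candidates)
    if boundary >= len(pair.forward_seq) and boundary >= len(pair.reverse_seq):
        return TrimResult(pair=pair, trimmed=False, boundary=None)
    if boundary < params.min_read_length:
        return TrimResult(pair=None, trimmed=True, boundary=boundary)
    new = replace(
        pair,
        forward_seq=pair.forward_seq[:boundary],
        forward_qual=pair.forward_qual[:boundary],
        reverse_seq=pair.reverse_seq[:boundary],
        reverse_qual=pair.reverse_qual[:boundary],
    )
    trimmed = (len(new.forward_seq) < len(pair.forward_seq)) or (
        len(new.reverse_seq) < len(pair.reverse_seq)
    )
    return TrimResult(pair=new, trimmed=trimmed, boundary=boundary)


def trim_pairs(
    pairs: Iterable[ReadPair], params: ScanParams = ScanParams()
) -> Iterator[TrimResult]:
    for pair in pairs:
        yield trim_pair(pair, params)


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadPair]]
    rejected: int = 0
    report: dict[str, int] = field(default_factory=dict)  # sample -> kept count


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_map,
    enzyme_remnant: str = "AATTC",
) -> DemuxResult:
    """Assign read pairs to samples by exact inline barcode + enzyme remnant.

    ``barcode_map`` maps barcode -> sample id (a dict, or an iterable of
    (barcode, sample) rows as read from a barcode sheet).  A pair is assigned
    iff its forward read starts with an exact barcode immediately followed by
    the exact enzyme remnant; there is no mismatch rescue.  The barcode (only)
    is removed from the forward read, so assigned output starts with the
    remnant.
    """
    if not isinstance(barcode_map, dict):
        rows = list(barcode_map)
        seen: set[str] = set()
        for bc, _sample in rows:
            if bc in seen:
                raise ConfigurationError(f"duplicate barcode {bc!r}")
            seen.add(bc)
        barcode_map = dict(rows)
    # longest barcode first so a shorter barcode that is a prefix of a longer
    # one cannot steal its reads
    ordered = sorted(barcode_map, key=len, reverse=True)
    out: dict[str, list[ReadPair]] = {s: [] for s in barcode_map.values()}
    rejected = 0
    for pair in pairs:
        assigned = False
        for bc in ordered:
            if pair.forward_seq.startswith(bc + enzyme_remnant):
                sample = barcode_map[bc]
                n = len(bc)
                out[sample].append(
                    replace(
                        pair,
                        forward_seq=pair.forward_seq[n:],
                        forward_qual=pair.forward_qual[n:],
                        sample_id=sample,
                        barcode=bc,
                    )
                )
                assigned = True
                break
        if not assigned:
            rejected += 1
    return DemuxResult(
        by_sample=out,
        rejected=rejected,
        report={s: len(v) for s, v in out.items()},
    )
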