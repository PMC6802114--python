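"""Standard-format I/O: FASTA, gzipped FASTQ (Phred+33), VCF text, TSV tables.

Gzip members are written with a zeroed mtime so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .readprep import ReadPair


class _DeterministicGzip:
    """Gzip writer with zeroed mtime and empty FNAME, closing both layers."""

    def __init__(self, path: Path):
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(
            filename="", fileobj=self._raw, mtime=0, mode="wb"
        )

    def write(self, data: bytes) -> int:
        return self._gz.write(data)

    def close(self) -> None:
        self._gz.close()
        self._raw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _open_out(path: Path):
    if str(path).endswith(".gz"):
        return _DeterministicGzip(path)
    return open(path, "wb")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str, path2: str) -> int:
    """Write mates to two FASTQ files (gzipped when the name ends in .gz)."""
    n = 0
    with _open_out(Path(path1)) as f1, _open_out(Path(path2)) as f2:
        for p in pairs:
            f1.write(
                f"@{p.read_id}/1\n{p.forward_seq}\n+\n{p.forward_qual}\n".encode()
            )
            f2.write(
                f"@{p.read_id}/2\n{p.reverse_seq}\n+\n{p.reverse_qual}\n".encode()
            )
            n += 1
    return n


def _open_in(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(path1: str, path2: str, sample_id: str = "") -> list[ReadPair]:
    pairs = []
    with _open_in(path1) as f1, _open_in(path2) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            rid = rec1.id.rsplit("/", 1)[0]
            pairs.append(
                ReadPair(
                    read_id=rid,
                    forward_seq=str(rec1.seq),
                    reverse_seq=str(rec2.seq),
                    forward_qual="".join(
                        chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                    ),
                    reverse_qual="".join(
                        chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                    ),
                    sample_id=sample_id,
                )
            )
    return pairs


def write_fasta(records: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_depth_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"contig", "pos", "sample", "depth"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df
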