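"""Paired-end read cleanup for bisulfite amplicon libraries.

Reproduces the conventional pre-alignment contract for two-color-chemistry
instruments: 3' quality trimming that treats G calls as unreliable
(dark-cycle artifact), removal of the standard sequencing adapter
(``AGATCGGAAGAGC``) by semi-global suffix/prefix matching, and a paired
length filter keeping only pairs whose mates are both strictly longer
than 20 bp after trimming.

Order of operations per mate: quality trim, then adapter trim — the
order the standard trimming tools apply.
"""
from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_NEXTSEQ_CUTOFF = 30
DEFAULT_MIN_LEN = 20
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1

__all__ = [
    "ReadPair",
    "TrimReport",
    "trim_adapter",
    "quality_trim_nextseq",
    "trim_pair",
    "filter_pairs",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "trim_files",
    "DEFAULT_ADAPTER",
]


@dataclass(frozen=True)
class ReadPair:
    """One read pair; qualities are Phred scores, one per base."""

    id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


def quality_trim_nextseq(
    seq: str, qual: Iterable[int], cutoff: int = DEFAULT_NEXTSEQ_CUTOFF
) -> tuple[str, tuple[int, ...]]:
    """Two-color 3' quality trimming.

    Running-sum trimming from the 3' end: each base contributes
    ``cutoff - q_effective`` where ``q_effective`` is the base quality,
    except G bases, whose quality is treated as ``cutoff - 1`` — on
    two-color chemistry a G is the no-signal call, so a high-quality G
    tail is indistinguishable from signal dropout. The read is cut at
    the position maximizing the partial sum; a nonpositive maximum means
    no trimming.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    qual = tuple(qual)
    n = len(seq)
    s = 0
    best = 0
    cut = n
    for i in range(n - 1, -1, -1):
        q = cutoff - 1 if seq[i] == "G" else qual[i]
        s += cutoff - q
        if s < 0:
            break
        if s > best:
            best = s
            cut = i
    return seq[:cut], qual[:cut]


def _adapter_trim_index(
    seq: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int:
    """Index at which the adapter match starts, or len(seq) if none.

    A match is the adapter's prefix aligned at position i reaching the
    read's 3' end (or the full adapter internally), with mismatch
    fraction <= max_error_rate and overlap >= min_overlap. The earliest
    (longest-removal) match wins.
    """
    n, m = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        k = min(m, n - i)
        mismatches = sum(1 for a, b in zip(seq[i : i + k], adapter[:k]) if a != b)
        if mismatches <= max_error_rate * k:
            return i
    return n


def trim_adapter(
    pair: ReadPair,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> ReadPair:
    """Remove 3' adapter read-through from both mates (qualities in lockstep)."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    i1 = _adapter_trim_index(pair.seq1, adapter, min_overlap, max_error_rate)
    i2 = _adapter_trim_index(pair.seq2, adapter, min_overlap, max_error_rate)
    return replace(
        pair,
        seq1=pair.seq1[:i1],
        qual1=pair.qual1[:i1],
        seq2=pair.seq2[:i2],
        qual2=pair.qual2[:i2],
    )


def trim_pair(
    pair: ReadPair,
    adapter: str = DEFAULT_ADAPTER,
    nextseq_cutoff: int = DEFAULT_NEXTSEQ_CUTOFF,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> ReadPair:
    """Full per-pair cleanup: quality trim then adapter trim, each mate.

    Repeated until stable — adapter removal can expose a fresh
    low-quality 3' end, so a single quality-then-adapter pass is not a
    fixed point in general. Trimming only ever shortens, so the loop
    terminates; on typical reads one pass suffices.
    """
    while True:
        s1, q1 = quality_trim_nextseq(pair.seq1, pair.qual1, nextseq_cutoff)
        s2, q2 = quality_trim_nextseq(pair.seq2, pair.qual2, nextseq_cutoff)
        trimmed = replace(pair, seq1=s1, qual1=q1, seq2=s2, qual2=q2)
        trimmed = trim_adapter(trimmed, adapter, min_overlap, max_error_rate)
        if trimmed == pair:
            return trimmed
        pair = trimmed


@dataclass
class TrimReport:
    input_pairs: int = 0
    kept_pairs: int = 0
    dropped_short_pairs: int = 0
    trimmed_bases: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def filter_pairs(
    pairs: Iterable[ReadPair], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[ReadPair], TrimReport]:
    """Keep pairs whose mates are BOTH strictly longer than ``min_len``."""
    kept: list[ReadPair] = []
    report = TrimReport()
    for pair in pairs:
        report.input_pairs += 1
        if len(pair.seq1) > min_len and len(pair.seq2) > min_len:
            kept.append(pair)
            report.kept_pairs += 1
        else:
            report.dropped_short_pairs += 1
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (.gz supported)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path_r1, "r") as fh1, _open_text(path_r2, "r") as fh2:
        it2 = FastqGeneralIterator(fh2)
        for title1, seq1, q1 in FastqGeneralIterator(fh1):
            try:
                title2, seq2, q2 = next(it2)
            except StopIteration:
                raise ValueError(f"{path_r2}: fewer records than {path_r1}") from None
            rid = title1.split()[0].removesuffix("/1")
            rid2 = title2.split()[0].removesuffix("/2")
            if rid != rid2:
                raise ValueError(f"mate id mismatch: {rid!r} vs {rid2!r}")
            yield ReadPair(
                id=rid,
                seq1=seq1,
                seq2=seq2,
                qual1=tuple(ord(c) - 33 for c in q1),
                qual2=tuple(ord(c) - 33 for c in q2),
            )


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1, path_r2) -> int:
    """Write pairs to two parallel FASTQ files; returns the pair count."""
    n = 0
    with _open_text(path_r1, "w") as fh1, _open_text(path_r2, "w") as fh2:
        for pair in pairs:
            q1 = "".join(chr(q + 33) for q in pair.qual1)
            q2 = "".join(chr(q + 33) for q in pair.qual2)
            fh1.write(f"@{pair.id}\n{pair.seq1}\n+\n{q1}\n")
            fh2.write(f"@{pair.id}\n{pair.seq2}\n+\n{q2}\n")
            n += 1
    return n


def trim_files(
    in1,
    in2,
    out1,
    out2,
    adapter: str = DEFAULT_ADAPTER,
    nextseq_cutoff: int = DEFAULT_NEXTSEQ_CUTOFF,
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> TrimReport:
    """File-level trimming pipeline; returns the JSON-serializable report."""
    report = TrimReport()
    kept: list[ReadPair] = []
    for pair in read_fastq_pairs(in1, in2):
        report.input_pairs += 1
        before = len(pair.seq1) + len(pair.seq2)
        trimmed = trim_pair(pair, adapter, nextseq_cutoff, min_overlap, max_error_rate)
        report.trimmed_bases += before - len(trimmed.seq1) - len(trimmed.seq2)
        if len(trimmed.seq1) > min_len and len(trimmed.seq2) > min_len:
            kept.append(trimmed)
            report.kept_pairs += 1
        else:
            report.dropped_short_pairs += 1
    write_fastq_pairs(kept, out1, out2)
    return report
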