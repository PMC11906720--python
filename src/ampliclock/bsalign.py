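"""Bisulfite-aware assignment of read pairs to amplicons and per-read
methylation calls.

Bisulfite conversion destroys complementarity, so reads are compared in
converted space: against the original-top (OT) strand both read and
reference are C->T collapsed; against the original-bottom (OB) strand
both are G->A collapsed. Alignment is ungapped sliding-window scoring
(+1 match / -1 mismatch) over every offset of every amplicon — amplicons
are fixed-length PCR products and the simulator emits substitutions
only, so gaps buy nothing here (a documented limitation for real data
with indels).

A pair is assigned to the best-scoring (region, strand); any tie in best
score across regions, or a best score below ``min_score``, leaves it
UNASSIGNED — the conservative reading of "uniquely mapped". CpGs under
a primer footprint are excluded from calling: a degenerate primer base
carries no methylation signal.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import ReadPair
from .regions import TargetRegion, revcomp

__all__ = [
    "RegionAssignment",
    "PerReadCalls",
    "METH",
    "UNMETH",
    "NOCALL",
    "convert_space",
    "assign_region",
    "call_methylation",
    "process_pairs",
    "write_calls",
    "write_sam",
]

METH, UNMETH, NOCALL = "METH", "UNMETH", "NOCALL"

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


def convert_space(seq: str, mode: str) -> str:
    """Collapse a sequence into bisulfite-converted space.

    ``CT`` replaces every C with T (original-top comparison); ``GA``
    replaces every G with A (original-bottom comparison).
    """
    if mode == "CT":
        return seq.translate(_CT)
    if mode == "GA":
        return seq.translate(_GA)
    raise ValueError(f"mode must be 'CT' or 'GA', got {mode!r}")


@dataclass(frozen=True)
class RegionAssignment:
    """Where a pair maps: amplicon, bisulfite strand, mate offsets."""

    read_id: str
    gene_name: str | None
    strand: str | None  # "OT" / "OB"
    offset: int | None  # read 1 start within the amplicon
    offset2: int | None  # forward-space start of mate 2
    score: float
    unique: bool
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.unique and self.gene_name is not None


@dataclass(frozen=True)
class PerReadCalls:
    """Methylation states observed by one pair at region CpG positions."""

    read_id: str
    gene_name: str
    calls: tuple[tuple[int, str], ...]  # (genomic position, state)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@lru_cache(maxsize=8)
def _converted_refs(regions: tuple[TargetRegion, ...]):
    out = []
    for r in regions:
        if r.ref_seq is None:
            raise ValueError(f"{r.gene_name}: reference sequence required")
        out.append(
            (
                r,
                _encode(convert_space(r.ref_seq, "CT")),
                _encode(convert_space(r.ref_seq, "GA")),
            )
        )
    return out


def _best_placement(read: np.ndarray, ref: np.ndarray) -> tuple[float, int]:
    """Best ungapped score and its lowest offset (+1 match / -1 mismatch).

    When the read overhangs the amplicon 3' end, only the overlap is
    scored.
    """
    lr, lref = len(read), len(ref)
    if lr == 0:
        return float("-inf"), 0
    if lr <= lref:
        windows = sliding_window_view(ref, lr)
        matches = (windows == read).sum(axis=1)
        scores = 2 * matches - lr
        off = int(np.argmax(scores))
        return float(scores[off]), off
    matches = int((read[:lref] == ref).sum())
    return float(2 * matches - lref), 0


def assign_region(
    pair: ReadPair,
    regions: Sequence[TargetRegion],
    min_score: float | None = None,
) -> RegionAssignment:
    """Assign a trimmed pair to an amplicon and bisulfite strand.

    Both mates are scored in converted space against both strands of
    every amplicon (mate 2 is reverse-complemented into forward space
    first); the pair score at a (region, strand) is the sum of the
    mates' best placements. ``min_score`` defaults to 0.6x the total
    trimmed read length.
    """
    if len(pair.seq1) == 0 or len(pair.seq2) == 0:
        return RegionAssignment(
            pair.id, None, None, None, None, float("-inf"), False,
            reason="zero-length mate",
        )
    if min_score is None:
        min_score = 0.6 * (len(pair.seq1) + len(pair.seq2))

    r1 = pair.seq1
    r2f = revcomp(pair.seq2)
    reads = {
        "CT": (_encode(convert_space(r1, "CT")), _encode(convert_space(r2f, "CT"))),
        "GA": (_encode(convert_space(r1, "GA")), _encode(convert_space(r2f, "GA"))),
    }

    best = None  # (score, region, strand, off1, off2)
    region_best: dict[str, float] = {}
    for region, ref_ct, ref_ga in _converted_refs(tuple(regions)):
        for strand, ref in (("OT", ref_ct), ("OB", ref_ga)):
            a1, a2 = reads["CT" if strand == "OT" else "GA"]
            s1, o1 = _best_placement(a1, ref)
            s2, o2 = _best_placement(a2, ref)
            total = s1 + s2
            prev = region_best.get(region.gene_name, float("-inf"))
            region_best[region.gene_name] = max(prev, total)
            if best is None or total > best[0]:
                best = (total, region, strand, o1, o2)

    score, region, strand, o1, o2 = best
    ties = sum(1 for v in region_best.values() if v == score)
    if ties > 1:
        return RegionAssignment(
            pair.id, None, None, None, None, score, False, reason="ambiguous"
        )
    if score < min_score:
        return RegionAssignment(
            pair.id, None, None, None, None, score, False, reason="below min_score"
        )
    return RegionAssignment(
        pair.id, region.gene_name, strand, o1, o2, score, True
    )


def call_methylation(
    pair: ReadPair, assignment: RegionAssignment, region: TargetRegion
) -> PerReadCalls:
    """Read out CpG methylation states for a uniquely assigned pair.

    On the OT strand the CpG cytosine reads C (methylated) or T
    (unmethylated); on OB the guanine one base downstream reads G or A.
    Positions covered by both mates are called once from mate 1 (overlap
    deduplication: one molecule, one count). Primer-footprint CpGs are
    skipped.
    """
    if not assignment.assigned:
        raise ValueError(f"{pair.id}: pair is not uniquely assigned")
    if assignment.gene_name != region.gene_name:
        raise ValueError(
            f"{pair.id}: assignment is to {assignment.gene_name}, "
            f"not {region.gene_name}"
        )
    r2f = revcomp(pair.seq2)
    o1, o2 = assignment.offset, assignment.offset2
    span1 = range(o1, o1 + len(pair.seq1))
    span2 = range(o2, o2 + len(r2f))
    ot = assignment.strand == "OT"
    calls = []
    for c in region.callable_cpg_offsets:
        p = c if ot else c + 1
        if p in span1:
            base = pair.seq1[p - o1]
        elif p in span2:
            base = r2f[p - o2]
        else:
            continue
        if ot:
            state = METH if base == "C" else UNMETH if base == "T" else NOCALL
        else:
            state = METH if base == "G" else UNMETH if base == "A" else NOCALL
        calls.append((region.position_of(c), state))
    return PerReadCalls(pair.id, region.gene_name, tuple(calls))


def process_pairs(
    pairs: Iterable[ReadPair],
    regions: Sequence[TargetRegion],
    min_score: float | None = None,
) -> tuple[list[RegionAssignment], list[PerReadCalls], dict[str, int]]:
    """Assign and call a stream of pairs.

    Returns assignments, calls for the uniquely assigned pairs, and the
    count of uniquely assigned pairs per gene (the per-region depth the
    coverage QC consumes).
    """
    by_gene = {r.gene_name: r for r in regions}
    assignments: list[RegionAssignment] = []
    calls: list[PerReadCalls] = []
    depth: dict[str, int] = {g: 0 for g in by_gene}
    for pair in pairs:
        a = assign_region(pair, regions, min_score)
        assignments.append(a)
        if a.assigned:
            depth[a.gene_name] += 1
            calls.append(call_methylation(pair, a, by_gene[a.gene_name]))
    return assignments, calls, depth


def write_calls(calls: Iterable[PerReadCalls], path) -> None:
    """Per-read call TSV: read id, gene, genomic position, state."""
    with open(path, "w") as fh:
        fh.write("read_id\tgene\tposition\tstate\n")
        for c in calls:
            for pos, state in c.calls:
                fh.write(f"{c.read_id}\t{c.gene_name}\t{pos}\t{state}\n")


def read_calls(path) -> list[PerReadCalls]:
    """Read a per-read call TSV back (inverse of :func:`write_calls`)."""
    grouped: dict[tuple[str, str], list[tuple[int, str]]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "gene", "position", "state"]:
            raise ValueError(f"{path}: unexpected call-file header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields")
            rid, gene, pos, state = fields
            if state not in (METH, UNMETH, NOCALL):
                raise ValueError(f"{path}: line {lineno}: bad state {state!r}")
            key = (rid, gene)
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append((int(pos), state))
    return [
        PerReadCalls(rid, gene, tuple(grouped[(rid, gene)])) for rid, gene in order
    ]


def write_sam(
    pairs: Sequence[ReadPair],
    assignments: Sequence[RegionAssignment],
    regions: Sequence[TargetRegion],
    path,
) -> None:
    """Minimal SAM of assignments in amplicon-local coordinates.

    Reference names are gene names; mate 2 is stored reverse-complemented
    (flag 0x10). Unassigned pairs are written unmapped (flag 0x4).
    """
    by_gene = {r.gene_name: r for r in regions}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for r in regions:
            fh.write(f"@SQ\tSN:{r.gene_name}\tLN:{r.length}\n")
        for pair, a in zip(pairs, assignments):
            if not a.assigned:
                for seq in (pair.seq1, pair.seq2):
                    fh.write(
                        f"{pair.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
                    )
                continue
            L = by_gene[a.gene_name].length
            for seq, off, flag in (
                (pair.seq1, a.offset, 0),
                (revcomp(pair.seq2), a.offset2, 16),
            ):
                m = min(len(seq), L - off)
                cigar = f"{m}M" + (f"{len(seq) - m}S" if len(seq) > m else "")
                fh.write(
                    f"{pair.id}\t{flag}\t{a.gene_name}\t{off + 1}\t60\t{cigar}"
                    f"\t*\t0\t0\t{seq}\t*\n"
                )
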