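"""Target amplicon panel and the bundled 25-CpG age-prediction clock.

The assay interrogates five CpG-island loci whose methylation tracks
chronological age in blood — ELOVL2, FHL2, KLF14, miR29B2C and TRIM59 —
each amplified by one bisulfite PCR primer pair. This module defines the
amplicon coordinates (GRCh38, 1-based inclusive, forward strand), the
degenerate bisulfite primers (IUPAC R/Y codes tolerating both conversion
outcomes at primer-internal CpGs), the CpG sites of the published
25-feature elastic-net clock with their regression coefficients, and the
validation logic tying the two together.

The shipped amplicon reference sequences are SYNTHETIC: random sequence
with CG dinucleotides planted at the published clock-site offsets and
primer-compatible ends, so the whole toolkit runs without a genome
download. Substitute real GRCh38 sequence via ``load_regions``'s FASTA
argument for work on real reads.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TargetRegion",
    "CpGSite",
    "ClockModel",
    "ValidationReport",
    "RegionFileError",
    "GENES",
    "ADAPTER_TAIL_FWD",
    "ADAPTER_TAIL_REV",
    "iupac_match",
    "revcomp",
    "load_regions",
    "write_regions",
    "bundled_regions",
    "bundled_clock",
    "read_model",
    "write_model",
    "validate_model_against_regions",
    "build_synthetic_reference",
]

GENES = ("ELOVL2", "FHL2", "KLF14", "miR29B2C", "TRIM59")

# Sequencing-adapter prefixes carried 5' of every locus-specific primer;
# read-through into the opposite adapter begins with AGATCGGAAGAGC.
ADAPTER_TAIL_FWD = "TACACGACGCTCTTCCGATCT"
ADAPTER_TAIL_REV = "GACGTGTGCTCTTCCGATCT"

# Locus-specific (genomic) primer parts, bisulfite-converted space.
# Y marks a former CpG cytosine on the top strand (C if methylated, T if
# not); R is its complement on the bottom-strand (reverse) primer.
PRIMERS = {
    "ELOVL2": ("YGGTYGGGYGGYGATTTGTA", "ACCCACCRAAACCCAACTAT"),
    "miR29B2C": ("GTAAATATATAYGTGGGGGAAGAAGGG", "TAATAAAACCAAATTCTAAAACATTC"),
    "TRIM59": ("TATYGGTGGTTTGGGGGAGAG", "AACRACTTCCCRAAACAACRAATCTA"),
    "KLF14": ("YGGTTTTYGGTTAAGTTATGTTTAATAGT", "CTACTACAACCCAAAAATTCC"),
    "FHL2": ("TGTTTTTYGGGTTTTGGGAGTATAG", "CACRTCCTAAAACTTCTCCAATCTCC"),
}

# Amplicon coordinates (GRCh38, 1-based inclusive). Spans chosen so every
# clock CpG sits between the primer footprints; lengths are realistic
# bisulfite amplicon sizes (110-170 bp).
REGION_COORDS = {
    "miR29B2C": ("chr1", 207823646, 207823765),
    "FHL2": ("chr2", 105399252, 105399421),
    "TRIM59": ("chr3", 160450149, 160450258),
    "ELOVL2": ("chr6", 11044600, 11044729),
    "KLF14": ("chr7", 130734358, 130734472),
}

# The published clock: (gene, site label, chrom, position of the CpG C on
# the forward strand, used by previous clocks, regression coefficient in
# years per percent methylation).
_CLOCK_ROWS = [
    ("miR29B2C", "C1", "chr1", 207823681, True, -0.031),
    ("miR29B2C", "C2", "chr1", 207823705, False, -0.0242),
    ("FHL2", "C1", "chr2", 105399282, True, 0.0354),
    ("FHL2", "C2", "chr2", 105399288, True, 0.1146),
    ("FHL2", "C3", "chr2", 105399297, False, 0.0561),
    ("FHL2", "C4", "chr2", 105399300, False, 0.039),
    ("FHL2", "C5", "chr2", 105399327, False, -0.0837),
    ("FHL2", "C6", "chr2", 105399360, False, -0.6492),
    ("FHL2", "C7", "chr2", 105399363, False, -0.2134),
    ("FHL2", "C8", "chr2", 105399388, False, 0.057),
    ("TRIM59", "C1", "chr3", 160450179, False, 0.1184),
    ("TRIM59", "C2", "chr3", 160450184, False, 0.0528),
    ("TRIM59", "C3", "chr3", 160450189, True, 0.138),
    ("TRIM59", "C4", "chr3", 160450192, False, 0.0748),
    ("TRIM59", "C5", "chr3", 160450199, True, 0.0824),
    ("ELOVL2", "C1", "chr6", 11044628, True, 0.1533),
    ("ELOVL2", "C2", "chr6", 11044634, False, 0.2957),
    ("ELOVL2", "C3", "chr6", 11044640, False, 0.0894),
    ("ELOVL2", "C4", "chr6", 11044644, False, 0.0852),
    ("ELOVL2", "C5", "chr6", 11044647, False, 0.1189),
    ("ELOVL2", "C6", "chr6", 11044655, False, 0.0631),
    ("ELOVL2", "C7", "chr6", 11044661, True, 0.2512),
    ("ELOVL2", "C8", "chr6", 11044683, False, -0.0028),
    ("ELOVL2", "C9", "chr6", 11044702, False, -0.0712),
    ("KLF14", "C1", "chr7", 130734398, False, 0.2441),
]

# Hyperparameters of the published fit, carried as model metadata.
PUBLISHED_ALPHA = 0.01
PUBLISHED_LAMBDA = 1.2

_IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
}
_COMP = str.maketrans("ACGTRYN", "TGCAYRN")


class RegionFileError(ValueError):
    """Malformed region-definition input."""


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` matches ``pattern`` position-wise, with R = A/G
    and Y = C/T. Pattern and sequence must have equal length."""
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    try:
        return all(s in _IUPAC[p] for p, s in zip(pattern, seq))
    except KeyError as exc:
        raise ValueError(f"unsupported pattern symbol {exc.args[0]!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement; R/Y ambiguity codes map to their complements."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CpGSite:
    """One clock feature: a CpG cytosine at a fixed forward-strand position."""

    gene_name: str
    site_label: str
    chrom: str
    position: int  # 1-based position of the C (GRCh38, forward strand)
    in_previous_models: bool = False

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.position}"


@dataclass(frozen=True)
class TargetRegion:
    """One amplicon locus: coordinates, primers, reference, CpG offsets.

    ``cpg_offsets`` are 0-based offsets of CpG cytosines within the
    amplicon; when ``ref_seq`` is present they are derived from it and
    every offset must sit on a CG dinucleotide. Offsets inside a primer
    footprint exist physically but carry no methylation signal (the
    degenerate primer base overwrites it), so ``callable_cpg_offsets``
    excludes them.
    """

    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    primer_fwd: str
    primer_rev: str
    adapter_tail_fwd: str = ADAPTER_TAIL_FWD
    adapter_tail_rev: str = ADAPTER_TAIL_REV
    ref_seq: str | None = None
    cpg_offsets: tuple[int, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_name}: start must be < end")
        for primer in (self.primer_fwd, self.primer_rev):
            bad = set(primer) - set("ACGTRY")
            if bad:
                raise ValueError(
                    f"{self.gene_name}: primer contains non-IUPAC symbols {bad}"
                )
        if self.ref_seq is not None:
            if len(self.ref_seq) != self.length:
                raise ValueError(
                    f"{self.gene_name}: ref_seq length {len(self.ref_seq)} != "
                    f"region length {self.length}"
                )
            scanned = _scan_cpgs(self.ref_seq)
            if not self.cpg_offsets:
                object.__setattr__(self, "cpg_offsets", scanned)
            elif tuple(self.cpg_offsets) != scanned:
                raise ValueError(
                    f"{self.gene_name}: declared CpG offsets differ from "
                    f"CG dinucleotides in ref_seq"
                )
        for off in self.cpg_offsets:
            if not 0 <= off < self.length:
                raise ValueError(
                    f"{self.gene_name}: CpG offset {off} outside region "
                    f"(length {self.length})"
                )
            if self.ref_seq is not None and self.ref_seq[off : off + 2] != "CG":
                raise ValueError(
                    f"{self.gene_name}: offset {off} is not a CG dinucleotide"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def primer_fwd_span(self) -> tuple[int, int]:
        """Half-open offset span covered by the forward primer."""
        return (0, len(self.primer_fwd))

    @property
    def primer_rev_span(self) -> tuple[int, int]:
        """Half-open offset span covered by the reverse primer (top strand)."""
        return (self.length - len(self.primer_rev), self.length)

    def in_primer(self, offset: int) -> bool:
        return offset < len(self.primer_fwd) or offset >= self.length - len(
            self.primer_rev
        )

    @property
    def callable_cpg_offsets(self) -> tuple[int, ...]:
        return tuple(o for o in self.cpg_offsets if not self.in_primer(o))

    def position_of(self, offset: int) -> int:
        return self.start + offset

    def offset_of(self, position: int) -> int:
        return position - self.start

    @property
    def cpg_positions(self) -> tuple[int, ...]:
        return tuple(self.start + o for o in self.cpg_offsets)


@dataclass
class ClockModel:
    """A linear methylation clock: age = intercept + sum(coef_j * beta_j).

    ``beta_scale`` records whether coefficients expect betas on 0-100
    (percent) or 0-1 (fraction); predictions auto-convert. ``intercept``
    may be None (the published table omits it), in which case absolute
    prediction requires calibration first.
    """

    sites: list[CpGSite]
    coefficients: list[float]
    intercept: float | None = None
    beta_scale: str = "percent_0_100"
    alpha: float | None = None
    lam: float | None = None
    provenance: str = ""

    def __post_init__(self):
        if len(self.coefficients) != len(self.sites):
            raise ValueError(
                f"{len(self.coefficients)} coefficients for {len(self.sites)} sites"
            )
        if self.beta_scale not in ("percent_0_100", "fraction_0_1"):
            raise ValueError(f"unknown beta_scale {self.beta_scale!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_keys(self) -> list[str]:
        return [s.key for s in self.sites]

    def per_gene_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.gene_name] = counts.get(s.gene_name, 0) + 1
        return counts

    def coefficient_at(self, chrom: str, position: int) -> float:
        for site, coef in zip(self.sites, self.coefficients):
            if site.chrom == chrom and site.position == position:
                return coef
        raise KeyError(f"{chrom}:{position} not in model")

    def rescaled(self, beta_scale: str) -> "ClockModel":
        """Return an equivalent model expecting betas on the other scale."""
        if beta_scale == self.beta_scale:
            return self
        factor = 100.0 if beta_scale == "fraction_0_1" else 0.01
        return replace(
            self,
            coefficients=[c * factor for c in self.coefficients],
            beta_scale=beta_scale,
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "sites": [
                {
                    "gene": s.gene_name,
                    "label": s.site_label,
                    "chrom": s.chrom,
                    "position": s.position,
                    "in_previous_models": s.in_previous_models,
                }
                for s in self.sites
            ],
            "coefficients": list(map(float, self.coefficients)),
            "intercept": None if self.intercept is None else float(self.intercept),
            "beta_scale": self.beta_scale,
            "alpha": self.alpha,
            "lambda": self.lam,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        version = d.get("schema_version")
        if version != 1:
            raise ValueError(f"unsupported clock model schema_version: {version!r}")
        sites = [
            CpGSite(
                gene_name=s["gene"],
                site_label=s["label"],
                chrom=s["chrom"],
                position=int(s["position"]),
                in_previous_models=bool(s.get("in_previous_models", False)),
            )
            for s in d["sites"]
        ]
        return cls(
            sites=sites,
            coefficients=[float(c) for c in d["coefficients"]],
            intercept=d.get("intercept"),
            beta_scale=d["beta_scale"],
            alpha=d.get("alpha"),
            lam=d.get("lambda"),
            provenance=d.get("provenance", ""),
        )


def write_model(model: ClockModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def read_model(path) -> ClockModel:
    with open(path) as fh:
        return ClockModel.from_dict(json.load(fh))


def bundled_clock() -> ClockModel:
    """The published 25-CpG clock: Table-of-record coefficients, no
    intercept (not published; calibrate before absolute prediction)."""
    sites = [
        CpGSite(gene, label, chrom, pos, prev)
        for gene, label, chrom, pos, prev, _ in _CLOCK_ROWS
    ]
    coefs = [coef for *_, coef in _CLOCK_ROWS]
    return ClockModel(
        sites=sites,
        coefficients=coefs,
        intercept=None,
        beta_scale="percent_0_100",
        alpha=PUBLISHED_ALPHA,
        lam=PUBLISHED_LAMBDA,
        provenance="bundled 25-CpG blood age clock",
    )


# ---------------------------------------------------------------------------
# Synthetic reference construction
# ---------------------------------------------------------------------------


def _scan_cpgs(seq: str) -> tuple[int, ...]:
    return tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")


def _primer_to_genomic_top(primer_fwd: str) -> str:
    """Genomic-space top strand under a forward bisulfite primer: every Y
    marks a CpG cytosine (must be followed by G); other symbols literal."""
    out = []
    for i, ch in enumerate(primer_fwd):
        if ch == "Y":
            nxt = primer_fwd[i + 1] if i + 1 < len(primer_fwd) else ""
            if nxt != "G":
                raise ValueError("degenerate Y not followed by G in primer")
            out.append("C")
        elif ch in "ACGT":
            out.append(ch)
        else:
            raise ValueError(f"unexpected symbol {ch!r} in forward primer")
    return "".join(out)


def build_synthetic_reference(seed: int = 20240601) -> dict[str, str]:
    """Construct SYNTHETIC amplicon reference sequences for the panel.

    Random filler guaranteed free of CG dinucleotides, with CG planted at
    every published clock-site offset, and 5'/3' ends whose bisulfite
    conversion matches the degenerate primers exactly. Deterministic for
    a given seed; the bundled FASTA was produced with the default seed.
    """
    rng = np.random.default_rng(seed)
    clock_by_gene: dict[str, list[int]] = {}
    for gene, _, _, pos, _, _ in _CLOCK_ROWS:
        clock_by_gene.setdefault(gene, []).append(pos)

    refs: dict[str, str] = {}
    for gene, (chrom, start, end) in REGION_COORDS.items():
        length = end - start + 1
        fwd, rev = PRIMERS[gene]
        head = _primer_to_genomic_top(fwd)
        tail = _primer_to_genomic_top(revcomp(rev))
        interior_len = length - len(head) - len(tail)
        planted = sorted(p - start for p in clock_by_gene[gene])
        if planted[0] < len(head) or planted[-1] + 1 >= length - len(tail):
            raise ValueError(f"{gene}: clock CpG inside a primer footprint")

        seq = list(head) + list(rng.choice(list("ACGT"), size=interior_len)) + list(tail)
        for off in planted:
            seq[off], seq[off + 1] = "C", "G"
        # remove accidental CGs whose bases are mutable (interior, unplanted);
        # CGs wholly inside a primer footprint are Y-derived and legitimate
        interior = range(len(head), len(head) + interior_len)
        in_footprint = lambda o: o + 1 < len(head) or o >= length - len(tail)
        allowed = set(planted) | {
            o for o in _scan_cpgs("".join(seq)) if in_footprint(o)
        }
        for _ in range(10 * length):
            dirty = [
                i
                for i in range(length - 1)
                if seq[i] == "C" and seq[i + 1] == "G" and i not in allowed
            ]
            if not dirty:
                break
            for i in dirty:
                if i + 1 in interior and i + 1 not in allowed and i not in allowed:
                    seq[i + 1] = "A"
                elif i in interior:
                    seq[i] = "T"
                else:  # pragma: no cover - by construction both ends are clean
                    raise AssertionError(f"{gene}: immutable spurious CG at {i}")
        ref = "".join(seq)
        assert set(_scan_cpgs(ref)) >= set(planted)
        extra = set(_scan_cpgs(ref)) - set(planted)
        assert all(in_footprint(o) for o in extra), (
            f"{gene}: stray interior CpG {sorted(extra)}"
        )
        refs[gene] = ref
    return refs


# ---------------------------------------------------------------------------
# Region file I/O
# ---------------------------------------------------------------------------

_REGION_COLUMNS = [
    "gene",
    "chrom",
    "start",
    "end",
    "primer_fwd",
    "primer_rev",
    "adapter_tail_fwd",
    "adapter_tail_rev",
]
_SITE_COLUMNS = ["gene", "label", "chrom", "position", "in_previous_models"]


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_regions(
    regions_tsv=None, fasta=None, cpg_tsv=None
) -> list[TargetRegion]:
    """Load the amplicon panel from a region-definition TSV plus companion
    amplicon FASTA. With no arguments, loads the bundled panel (synthetic
    reference sequence). Raises :class:`RegionFileError` naming the
    offending line on malformed input."""
    if regions_tsv is None:
        data = resources.files("ampliclock") / "data"
        regions_tsv = data / "regions.tsv"
        fasta = fasta or data / "amplicons.synthetic.fa"
        cpg_tsv = cpg_tsv or data / "cpg_sites.tsv"
    seqs = _read_fasta(fasta) if fasta is not None else {}
    regions: list[TargetRegion] = []
    with open(regions_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_REGION_COLUMNS)] != _REGION_COLUMNS:
            raise RegionFileError(
                f"{regions_tsv}: line 1: expected header {_REGION_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_REGION_COLUMNS):
                raise RegionFileError(
                    f"{regions_tsv}: line {lineno}: expected "
                    f"{len(_REGION_COLUMNS)} fields, got {len(fields)}"
                )
            gene, chrom, start, end, pf, pr, atf, atr = fields
            if gene not in GENES:
                raise RegionFileError(
                    f"{regions_tsv}: line {lineno}: unknown gene {gene!r}"
                )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise RegionFileError(
                    f"{regions_tsv}: line {lineno}: non-integer coordinates"
                ) from None
            try:
                regions.append(
                    TargetRegion(
                        gene_name=gene,
                        chrom=chrom,
                        start=start_i,
                        end=end_i,
                        primer_fwd=pf,
                        primer_rev=pr,
                        adapter_tail_fwd=atf,
                        adapter_tail_rev=atr,
                        ref_seq=seqs.get(gene),
                    )
                )
            except ValueError as exc:
                raise RegionFileError(
                    f"{regions_tsv}: line {lineno}: {exc}"
                ) from None
    if cpg_tsv is not None:
        _validate_sites_file(cpg_tsv, regions)
    return regions


def _validate_sites_file(cpg_tsv, regions: list[TargetRegion]) -> None:
    by_gene = {r.gene_name: r for r in regions}
    with open(cpg_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SITE_COLUMNS:
            raise RegionFileError(
                f"{cpg_tsv}: line 1: expected header {_SITE_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_SITE_COLUMNS):
                raise RegionFileError(
                    f"{cpg_tsv}: line {lineno}: expected "
                    f"{len(_SITE_COLUMNS)} fields, got {len(fields)}"
                )
            gene, _, chrom, position, _ = fields
            region = by_gene.get(gene)
            if region is None:
                raise RegionFileError(
                    f"{cpg_tsv}: line {lineno}: unknown gene {gene!r}"
                )
            try:
                pos = int(position)
            except ValueError:
                raise RegionFileError(
                    f"{cpg_tsv}: line {lineno}: non-integer position"
                ) from None
            off = region.offset_of(pos)
            if chrom != region.chrom or not 0 <= off < region.length:
                raise RegionFileError(
                    f"{cpg_tsv}: line {lineno}: CpG {chrom}:{pos} outside "
                    f"{gene} region"
                )
            if region.ref_seq is not None and off not in region.cpg_offsets:
                raise RegionFileError(
                    f"{cpg_tsv}: line {lineno}: {chrom}:{pos} is not a CG "
                    f"dinucleotide in the {gene} reference"
                )


def write_regions(regions: Iterable[TargetRegion], regions_tsv, fasta=None) -> None:
    """Write a region-definition TSV (and companion FASTA if requested)."""
    regions = list(regions)
    with open(regions_tsv, "w") as fh:
        fh.write("\t".join(_REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.gene_name,
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.primer_fwd,
                        r.primer_rev,
                        r.adapter_tail_fwd,
                        r.adapter_tail_rev,
                    ]
                )
                + "\n"
            )
    if fasta is not None:
        with open(fasta, "w") as fh:
            for r in regions:
                if r.ref_seq is not None:
                    fh.write(f">{r.gene_name}\n{r.ref_seq}\n")


def bundled_regions() -> list[TargetRegion]:
    """The five-locus panel with the shipped synthetic reference."""
    return load_regions()


@dataclass
class ValidationReport:
    """Mapping of clock sites onto amplicons; carries failures, never raises."""

    per_gene_counts: dict[str, int]
    orphans: list[CpGSite]
    mismatched_reference: list[CpGSite] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.orphans and not self.mismatched_reference


def validate_model_against_regions(
    model: ClockModel, regions: Sequence[TargetRegion]
) -> ValidationReport:
    """Check that every model CpG falls inside exactly one amplicon and,
    when reference sequence is available, on a CG dinucleotide."""
    counts: dict[str, int] = {}
    orphans: list[CpGSite] = []
    mismatched: list[CpGSite] = []
    for site in model.sites:
        homes = [
            r
            for r in regions
            if r.chrom == site.chrom and r.start <= site.position <= r.end
        ]
        if len(homes) != 1:
            orphans.append(site)
            continue
        region = homes[0]
        counts[region.gene_name] = counts.get(region.gene_name, 0) + 1
        if region.ref_seq is not None:
            off = region.offset_of(site.position)
            if region.ref_seq[off : off + 2] != "CG":
                mismatched.append(site)
    return ValidationReport(per_gene_counts=counts, orphans=orphans,
                            mismatched_reference=mismatched)
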