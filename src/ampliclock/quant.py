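"""Aggregate per-read methylation calls into sample x CpG beta values.

A beta value is the percent of molecules methylated at a CpG:
``100 * meth / (meth + unmeth)`` over the uniquely assigned, deduplicated
read calls (NOCALL bases are ignored). Zero coverage yields a missing
beta, never 0. Coverage QC flags each (sample, region) against the
minimum read-pair depth the assay is expected to deliver (1,000 pairs
per region by default); the default policy excludes a sample whose
regions do not all pass.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bsalign import METH, UNMETH, PerReadCalls
from .regions import ClockModel, TargetRegion

__all__ = [
    "BetaMatrix",
    "CoverageQC",
    "panel_site_keys",
    "aggregate_calls",
    "qc_coverage",
    "model_matrix",
    "write_beta_matrix",
    "read_beta_matrix",
    "write_coverage_format",
    "read_coverage_format",
]

DEFAULT_MIN_DEPTH = 1000


def panel_site_keys(regions: Sequence[TargetRegion]) -> list[str]:
    """Callable CpG columns, in panel order: region by region, 5'->3'."""
    keys = []
    for r in regions:
        keys.extend(f"{r.chrom}:{r.position_of(o)}" for o in r.callable_cpg_offsets)
    return keys


@dataclass
class BetaMatrix:
    """Samples x CpG methylation counts with per-region pair depth.

    ``meth``/``unmeth`` are aligned integer count frames (rows samples,
    columns "chrom:pos"); ``region_depth`` counts uniquely assigned read
    pairs per (sample, gene). Betas are always derived from the counts.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    region_depth: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth/unmeth frames must be aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def site_keys(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def beta(self) -> pd.DataFrame:
        """Percent methylation; NaN where a cell has zero coverage."""
        total = self.meth + self.unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.meth / total.where(total > 0)

    @classmethod
    def concat(cls, rows: Sequence["BetaMatrix"]) -> "BetaMatrix":
        depth = None
        if all(r.region_depth is not None for r in rows):
            depth = pd.concat([r.region_depth for r in rows])
        return cls(
            meth=pd.concat([r.meth for r in rows]),
            unmeth=pd.concat([r.unmeth for r in rows]),
            region_depth=depth,
        )

    def merged_counts(self, other: "BetaMatrix") -> "BetaMatrix":
        """Sum counts cell-wise (same samples/sites): stream additivity."""
        depth = None
        if self.region_depth is not None and other.region_depth is not None:
            depth = self.region_depth + other.region_depth
        return BetaMatrix(
            meth=self.meth + other.meth,
            unmeth=self.unmeth + other.unmeth,
            region_depth=depth,
        )


def aggregate_calls(
    calls: Iterable[PerReadCalls],
    sample_id: str,
    regions: Sequence[TargetRegion],
    region_depth: Mapping[str, int] | None = None,
) -> BetaMatrix:
    """Count METH/UNMETH per CpG for one sample (NOCALL ignored)."""
    keys = panel_site_keys(regions)
    chrom_by_gene = {r.gene_name: r.chrom for r in regions}
    meth = dict.fromkeys(keys, 0)
    unmeth = dict.fromkeys(keys, 0)
    for c in calls:
        chrom = chrom_by_gene[c.gene_name]
        for pos, state in c.calls:
            key = f"{chrom}:{pos}"
            if state == METH:
                meth[key] += 1
            elif state == UNMETH:
                unmeth[key] += 1
    depth_frame = None
    if region_depth is not None:
        genes = [r.gene_name for r in regions]
        depth_frame = pd.DataFrame(
            [[int(region_depth.get(g, 0)) for g in genes]],
            index=[sample_id],
            columns=genes,
        )
    return BetaMatrix(
        meth=pd.DataFrame([meth], index=[sample_id]),
        unmeth=pd.DataFrame([unmeth], index=[sample_id]),
        region_depth=depth_frame,
    )


@dataclass
class CoverageQC:
    """Per-(sample, region) depth flags and the resulting exclusions."""

    depth: pd.DataFrame
    passed: pd.DataFrame
    min_depth: int
    samples_excluded: list[str]

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.values.all())


def qc_coverage(
    matrix: BetaMatrix,
    min_depth: int = DEFAULT_MIN_DEPTH,
    policy: str = "reject_sample",
) -> CoverageQC:
    """Flag (sample, region) cells with depth >= min_depth.

    ``reject_sample`` excludes any sample with a failing region;
    ``keep_all`` reports flags without exclusions.
    """
    if matrix.region_depth is None:
        raise ValueError("matrix carries no region depths")
    if policy not in ("reject_sample", "keep_all"):
        raise ValueError(f"unknown policy {policy!r}")
    passed = matrix.region_depth >= min_depth
    excluded = []
    if policy == "reject_sample":
        excluded = [s for s in passed.index if not passed.loc[s].all()]
    return CoverageQC(
        depth=matrix.region_depth,
        passed=passed,
        min_depth=min_depth,
        samples_excluded=excluded,
    )


def model_matrix(
    matrix: BetaMatrix, model: ClockModel, on_missing: str = "error"
) -> tuple[np.ndarray, list[str]]:
    """Extract the model's CpG columns as a percent-scale design matrix.

    ``on_missing``: "error" raises naming the first sample/site with a
    missing beta; "drop" removes such samples; "impute" fills each
    missing cell with the column mean (off by default — documented as a
    deviation from the strict policy).
    """
    beta = matrix.beta
    missing_cols = [k for k in model.site_keys if k not in beta.columns]
    if missing_cols:
        raise KeyError(f"beta matrix lacks model CpG(s): {missing_cols}")
    X = beta[model.site_keys]
    if X.isna().any().any():
        if on_missing == "error":
            stacked = X.stack(future_stack=True)
            sample, site = stacked[stacked.isna()].index[0]
            raise ValueError(
                f"sample {sample}: missing beta at model CpG {site}"
            )
        if on_missing == "drop":
            X = X.dropna(axis=0)
        elif on_missing == "impute":
            X = X.fillna(X.mean())
        else:
            raise ValueError(f"unknown on_missing {on_missing!r}")
    return X.to_numpy(dtype=float), list(X.index)


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Samples x CpG beta TSV with "chrom:pos" columns (counts excluded;
    use the coverage format for lossless counts)."""
    matrix.beta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_beta_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_coverage_format(matrix: BetaMatrix, path, sample_id: str | None = None) -> None:
    """Per-CpG coverage TSV for one sample, in the established dialect:
    chrom, start, end (1-based inclusive, start == end == the C),
    percent methylation, methylated count, unmethylated count."""
    if sample_id is None:
        if len(matrix.sample_ids) != 1:
            raise ValueError("sample_id required for a multi-sample matrix")
        sample_id = matrix.sample_ids[0]
    meth = matrix.meth.loc[sample_id]
    unmeth = matrix.unmeth.loc[sample_id]
    with open(path, "w") as fh:
        for key in matrix.site_keys:
            chrom, pos = key.rsplit(":", 1)
            m, u = int(meth[key]), int(unmeth[key])
            if m + u == 0:
                continue
            beta = 100.0 * m / (m + u)
            fh.write(f"{chrom}\t{pos}\t{pos}\t{beta:.10g}\t{m}\t{u}\n")


def read_coverage_format(path, sample_id: str) -> BetaMatrix:
    """Read one sample's coverage file back into a single-row matrix.

    Raises a parse error naming the line on malformed input; the stored
    beta must agree with the counts to 1e-6.
    """
    meth: dict[str, int] = {}
    unmeth: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(fields)}"
                )
            chrom, start, end, beta_s, m_s, u_s = fields
            try:
                start_i, end_i = int(start), int(end)
                beta = float(beta_s)
                m, u = int(m_s), int(u_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: malformed numeric field"
                ) from None
            if start_i != end_i:
                raise ValueError(
                    f"{path}: line {lineno}: start != end for a CpG record"
                )
            if m + u > 0 and abs(beta - 100.0 * m / (m + u)) > 1e-6:
                raise ValueError(
                    f"{path}: line {lineno}: beta inconsistent with counts"
                )
            key = f"{chrom}:{start_i}"
            meth[key] = m
            unmeth[key] = u
    return BetaMatrix(
        meth=pd.DataFrame([meth], index=[sample_id], dtype=int),
        unmeth=pd.DataFrame([unmeth], index=[sample_id], dtype=int),
    )
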