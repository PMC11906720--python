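"""Synthetic cohorts and bisulfite amplicon read simulation.

Generates the inputs the wet assay would produce, with known ground
truth, so the whole pipeline can be exercised and checked end to end:

* age-structured cohorts that over-weight the >= 60-year stratum, the
  design used to damp epigenetic-drift noise during clock training;
* per-CpG beta values (percent methylation) from a generative linear
  clock — the clock's linear combination of the noise-free betas
  reproduces age exactly, so the true model is recoverable;
* 150 bp paired-end bisulfite reads per amplicon, with degenerate primer
  footprints, adapter read-through on short inserts, incomplete
  conversion / over-conversion, and uniform substitution sequencing
  error. Both bisulfite strands (OT/OB) are simulated with equal
  probability.

Indels, PCR bias and chimeras are not modeled; substitutions only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ReadPair
from .regions import ClockModel, CpGSite, TargetRegion, revcomp

__all__ = [
    "CohortSpec",
    "GenerativeClock",
    "ReadSimConfig",
    "sample_cohort",
    "betas_from_age",
    "cohort_beta_matrix",
    "simulate_reads",
    "write_fastq",
    "write_truth",
    "FULL_ADAPTER_FWD",
    "FULL_ADAPTER_REV",
]

# Full library adapters (index sequences included); read-through past a
# short insert continues into the reverse complement of the opposite
# adapter, which begins with AGATCGGAAGAGC.
FULL_ADAPTER_FWD = (
    "AATGATACGGCGACCACCGAGATCTACACAGCGCTAGACACTCTTTCCCTACACGACGCTCTTCCGATCT"
)
FULL_ADAPTER_REV = (
    "CAAGCAGAAGACGGCATACGAGATAACCGCGGGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
)
_READTHROUGH_R1 = revcomp(FULL_ADAPTER_REV)
_READTHROUGH_R2 = revcomp(FULL_ADAPTER_FWD)

_DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 2.0, 1.5)  # decades of [20, 80)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: decade-stratified ages with the elderly over-weighted.

    ``stratum_weights`` has one weight per decade of ``age_range``;
    defaults emulate a blood cohort aged 20-80 in which the >= 60 strata
    dominate.
    """

    n: int
    age_range: tuple[int, int] = (20, 80)
    stratum_weights: tuple[float, ...] = _DEFAULT_WEIGHTS
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.age_range
        ndec = -(-(hi - lo) // 10)
        if len(self.stratum_weights) != ndec:
            raise ValueError(
                f"need {ndec} decade weights for age range {self.age_range}, "
                f"got {len(self.stratum_weights)}"
            )
        if min(self.stratum_weights) < 0 or sum(self.stratum_weights) <= 0:
            raise ValueError("weights must be nonnegative with a positive sum")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")

    @property
    def decade_edges(self) -> list[tuple[int, int]]:
        lo, hi = self.age_range
        return [(d, min(d + 10, hi)) for d in range(lo, hi, 10)]


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table (sample_id, age, sex), seed-deterministic.

    Decades are drawn with probability proportional to the stratum
    weights; age is uniform within the decade.
    """
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.stratum_weights, dtype=float)
    p = w / w.sum()
    decades = rng.choice(len(p), size=spec.n, p=p)
    edges = np.array(spec.decade_edges, dtype=float)
    lo = edges[decades, 0]
    hi = edges[decades, 1]
    ages = lo + rng.random(spec.n) * (hi - lo)
    # reported to 2 decimals; keep rounding inside the half-open decade
    ages = np.minimum(np.round(ages, 2), hi - 0.01)
    sexes = np.where(rng.random(spec.n) < spec.sex_ratio, "F", "M")
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(spec.n)],
            "age": ages,
            "sex": sexes,
        }
    )


@dataclass
class GenerativeClock:
    """Ground-truth linear clock used to synthesize beta values.

    Each site's mean methylation is affine in age (``base + slope * age``,
    percent scale) with slopes proportional to the clock coefficients so
    the clock sum reproduces age exactly. Two variance components are
    added on top:

    * ``between_individual_sd`` — per-sample variation drawn in the null
      space of the coefficient vector. It moves individual betas
      (making all sites linearly independent, as in real cohorts where
      sites are not perfectly collinear) but cancels exactly in the
      clock's weighted sum, so the age relation stays exact.
    * ``beta_noise_sd`` — independent Gaussian measurement noise per
      CpG, which does perturb predicted age.

    Betas are clipped to [0, 100] after noise.
    """

    truth_model: ClockModel
    base: np.ndarray
    slope: np.ndarray
    beta_noise_sd: float = 3.0
    between_individual_sd: float = 3.0

    def __post_init__(self):
        if self.truth_model.intercept is None:
            raise ValueError("generative truth model requires an intercept")
        coef = np.asarray(self.truth_model.coefficients, dtype=float)
        age0 = self.truth_model.intercept + coef @ self.base
        gain = coef @ self.slope
        if abs(age0) > 1e-8 or abs(gain - 1.0) > 1e-10:
            raise ValueError("age_to_beta map inconsistent with truth model")

    @classmethod
    def from_model(
        cls,
        model: ClockModel,
        intercept: float | None = None,
        anchor_age: float = 50.0,
        anchor_beta: float = 50.0,
        beta_noise_sd: float = 3.0,
        between_individual_sd: float = 3.0,
    ) -> "GenerativeClock":
        """Build the affine age->beta map from clock coefficients.

        Slopes are ``coef / sum(coef^2)`` (so the clock sum gains exactly
        one year per year); baselines put every site at ``anchor_beta``
        percent for a subject of ``anchor_age``. If ``intercept`` is
        given, baselines are shifted along the coefficient vector to
        realize it; otherwise the intercept implied by the anchors is
        recorded in the returned truth model.
        """
        coef = np.asarray(model.coefficients, dtype=float)
        ss = float(coef @ coef)
        slope = coef / ss
        base = anchor_beta - slope * anchor_age
        if intercept is None:
            intercept = float(-(coef @ base))
        else:
            shift = (-intercept - float(coef @ base)) / ss
            base = base + shift * coef
        truth = ClockModel(
            sites=list(model.sites),
            coefficients=list(coef),
            intercept=float(intercept),
            beta_scale="percent_0_100",
            provenance="synthetic generative truth",
        )
        return cls(
            truth_model=truth,
            base=base,
            slope=slope,
            beta_noise_sd=beta_noise_sd,
            between_individual_sd=between_individual_sd,
        )

    @property
    def coef(self) -> np.ndarray:
        return np.asarray(self.truth_model.coefficients, dtype=float)


def betas_from_age(
    gen: GenerativeClock,
    age: float,
    rng: np.random.Generator | None = None,
    size: int = 1,
) -> np.ndarray:
    """Draw beta vectors (percent) for a subject of the given age.

    Returns an array of shape (size, n_sites). With ``beta_noise_sd = 0``
    the clock applied to the output reproduces ``age`` to numerical
    precision (the between-individual component lies in the coefficient
    null space and cancels).
    """
    if not 0.0 <= age <= 120.0:
        raise ValueError(f"age {age} outside plausible range [0, 120]")
    rng = np.random.default_rng(0) if rng is None else rng
    p = len(gen.base)
    mean = gen.base + gen.slope * age
    out = np.tile(mean, (size, 1))
    if gen.between_individual_sd > 0:
        z = rng.normal(0.0, gen.between_individual_sd, size=(size, p))
        coef = gen.coef
        z -= np.outer(z @ coef / (coef @ coef), coef)
        out += z
    if gen.beta_noise_sd > 0:
        out += rng.normal(0.0, gen.beta_noise_sd, size=(size, p))
    return np.clip(out, 0.0, 100.0)


def cohort_beta_matrix(
    gen: GenerativeClock, ages: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Stack one beta vector per subject: shape (n_samples, n_sites)."""
    return np.vstack([betas_from_age(gen, a, rng) for a in ages])


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters (paired 150 bp by default)."""

    read_length: int = 150
    depth_per_region: int = 2000
    seq_error_rate: float = 0.001
    conversion_failure_rate: float = 0.005
    overconversion_rate: float = 0.001
    adapter_readthrough: bool = True
    quality_model: str = "constant"  # or "decay"
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_error_rate", "conversion_failure_rate", "overconversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_per_region < 1:
            raise ValueError("depth_per_region must be >= 1")
        if self.quality_model not in ("constant", "decay"):
            raise ValueError(f"unknown quality_model {self.quality_model!r}")


_A, _C, _G, _T = (ord(b) for b in "ACGT")
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    comp = np.full(256, 0, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    return comp[mat[:, ::-1]]


def _qualities(length: int, model: str) -> tuple[int, ...]:
    if model == "constant":
        return (37,) * length
    # decaying tail: Q37 plateau then a linear fall to Q12 over the last 40
    tail = min(40, length)
    qs = [37] * (length - tail) + [
        max(12, 37 - int(25 * (i + 1) / tail)) for i in range(tail)
    ]
    return tuple(qs)


def simulate_reads(
    region: TargetRegion,
    betas: Mapping[int, float],
    cfg: ReadSimConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "S0000",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate paired reads for one amplicon at the given true betas.

    ``betas`` maps the genomic position of every region CpG (including
    primer-footprint CpGs) to its true percent methylation. Per
    molecule, CpG states are Bernoulli(beta/100); bisulfite chemistry,
    degenerate-primer resolution, optional adapter read-through and
    uniform sequencing error are applied. Returns the read pairs and a
    truth table with one row per molecule.
    """
    if region.ref_seq is None:
        raise ValueError(f"{region.gene_name}: reference sequence required")
    missing = [p for p in region.cpg_positions if p not in betas]
    if missing:
        raise ValueError(f"{region.gene_name}: no beta for CpG(s) {missing}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    n = cfg.depth_per_region
    L = region.length
    offs = np.array(region.cpg_offsets, dtype=int)
    beta_arr = np.array([betas[p] for p in region.cpg_positions], dtype=float)

    states = rng.random((n, len(offs))) < beta_arr / 100.0
    is_ob = rng.random(n) < 0.5

    ref = _encode(region.ref_seq)
    fp = np.zeros(L, dtype=bool)
    fp[: len(region.primer_fwd)] = True
    fp[L - len(region.primer_rev) :] = True

    cpg_c = np.zeros(L, dtype=bool)
    cpg_c[offs] = True
    cpg_g = np.zeros(L, dtype=bool)
    cpg_g[offs + 1] = True
    noncpg_c = (ref == _C) & ~cpg_c
    noncpg_g = (ref == _G) & ~cpg_g

    mol = np.tile(ref, (n, 1))
    ot_rows = np.where(~is_ob)[0]
    ob_rows = np.where(is_ob)[0]

    def _convert(rows, bulk_cols_in_fp, bulk_cols_out, cpg_cols, meth_b, unmeth_b, conv_b):
        """Apply bisulfite outcome for one strand family.

        bulk columns: non-CpG convertible bases (C on OT / G on OB);
        cpg columns: the read-out base of each CpG (C on OT, G on OB).
        Inside primer footprints conversion is deterministic (the primer
        oligo fixes the base); outside, failure/over-conversion apply.
        """
        if rows.size == 0:
            return
        # non-CpG convertible bases: converted, except retained on failure
        mol[np.ix_(rows, bulk_cols_in_fp)] = conv_b
        if bulk_cols_out.size:
            fail = rng.random((rows.size, bulk_cols_out.size)) < cfg.conversion_failure_rate
            sub = np.where(fail, mol[np.ix_(rows, bulk_cols_out)], conv_b)
            mol[np.ix_(rows, bulk_cols_out)] = sub
        # CpG read-out bases by methylation state
        st = states[rows]
        base = np.where(st, meth_b, unmeth_b)
        out_fp = ~fp[cpg_cols]
        if out_fp.any():
            over = rng.random(st.shape) < cfg.overconversion_rate
            fail = rng.random(st.shape) < cfg.conversion_failure_rate
            base = np.where(st & over & out_fp, unmeth_b, base)
            base = np.where(~st & fail & out_fp, meth_b, base)
        mol[np.ix_(rows, cpg_cols)] = base

    _convert(
        ot_rows,
        np.where(noncpg_c & fp)[0],
        np.where(noncpg_c & ~fp)[0],
        offs,
        np.uint8(_C),
        np.uint8(_T),
        np.uint8(_T),
    )
    _convert(
        ob_rows,
        np.where(noncpg_g & fp)[0],
        np.where(noncpg_g & ~fp)[0],
        offs + 1,
        np.uint8(_G),
        np.uint8(_A),
        np.uint8(_A),
    )

    # assemble mates: read 1 from the product's top-strand 5' end, read 2
    # from the 3' end; short inserts read through into the adapter
    rl = cfg.read_length
    r1 = mol[:, :rl]
    r2 = _revcomp_rows(mol)[:, :rl]
    if L < rl:
        pad = rl - L
        if cfg.adapter_readthrough:
            ext1 = (_READTHROUGH_R1 + "G" * pad)[:pad]
            ext2 = (_READTHROUGH_R2 + "G" * pad)[:pad]
            r1 = np.hstack([r1, np.tile(_encode(ext1), (n, 1))])
            r2 = np.hstack([r2, np.tile(_encode(ext2), (n, 1))])

    if cfg.seq_error_rate > 0:
        for arr in (r1, r2):
            err = rng.random(arr.shape) < cfg.seq_error_rate
            shift = rng.integers(1, 4, size=arr.shape)
            codes = (_CODE[arr].astype(int) + shift) % 4
            arr[err] = _BASES[codes[err]]

    q1 = _qualities(r1.shape[1], cfg.quality_model)
    q2 = _qualities(r2.shape[1], cfg.quality_model)
    pairs = []
    seqs1 = [row.tobytes().decode() for row in r1]
    seqs2 = [row.tobytes().decode() for row in r2]
    for i in range(n):
        pairs.append(
            ReadPair(
                id=f"{sample_id}:{region.gene_name}:{i:06d}",
                seq1=seqs1[i],
                seq2=seqs2[i],
                qual1=q1,
                qual2=q2,
            )
        )

    truth = pd.DataFrame(
        {
            "molecule": [p.id for p in pairs],
            "sample": sample_id,
            "gene": region.gene_name,
            "strand": np.where(is_ob, "OB", "OT"),
            "states": ["".join("1" if s else "0" for s in row) for row in states],
        }
    )
    truth.attrs["cpg_positions"] = list(region.cpg_positions)
    truth.attrs["true_betas"] = list(beta_arr)
    return pairs, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a molecule truth table as TSV with a beta header block."""
    with open(path, "w") as fh:
        positions = truth.attrs.get("cpg_positions", [])
        betas = truth.attrs.get("true_betas", [])
        for pos, beta in zip(positions, betas):
            fh.write(f"#beta\t{pos}\t{beta}\n")
        truth.to_csv(fh, sep="\t", index=False)


def write_fastq(pairs: Sequence[ReadPair], path_r1, path_r2) -> int:
    """Write simulated pairs as parallel FASTQ (Phred+33; .gz by suffix)."""
    from .preprocess import write_fastq_pairs

    return write_fastq_pairs(pairs, path_r1, path_r2)
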