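"""Normality-adaptive correlation calling of dmCpGs against covariates.

Per probe, methylation M-values are correlated with a continuous covariate
(BMI, an individual fatty acid, or a saturation-group percentage) within a
single prandial state.  Pearson's test is used when both vectors pass the
Shapiro-Wilk normality test at alpha = 0.05, Spearman's otherwise.  A probe
is called a dmCpG when the correlation is nominally significant (p < 0.05,
no genome-wide correction) AND the beta-scale effect between extreme groups
exceeds 0.10: normoweight vs obese class means for BMI, bottom vs top
covariate tertile otherwise.  Cell-composition adjustment is an ordinary
least-squares fit of M on the covariate plus leukocyte proportions; the
covariate's two-sided t-test p-value is reported alongside the unadjusted p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import (
    AssociationResult,
    BMIClass,
    MethylationDataset,
    SampleRecord,
)
from .preprocess import beta_to_m

log = logging.getLogger(__name__)

__all__ = [
    "MEASURED_FA",
    "SATURATION_GROUPS",
    "EXCLUDED_COVARIATES",
    "CovariateSpec",
    "CorrelationOutcome",
    "shapiro_normal",
    "choose_correlation",
    "covariate_values",
    "delta_beta_extremes",
    "adjust_cell_composition",
    "ols_covariate_pvalues",
    "call_dm_for_covariate",
]

#: Blood fatty acids carried by the cohort, grouped by saturation degree.
SATURATION_GROUPS: dict[str, tuple[str, ...]] = {
    "SFA": ("C14:0", "PA", "C18:0"),
    "MUFA": ("C16:1", "EA", "OA", "C20:1"),
    "PUFA": ("LA", "EDA", "DGLA", "AA", "EPA", "C22:4", "C22:5", "C22:6"),
}
MEASURED_FA: tuple[str, ...] = tuple(
    fa for group in SATURATION_GROUPS.values() for fa in group
)
#: Never permitted as covariates: glucose (all subjects normoglycemic) and
#: C18:3 (incompletely determined in the source profiles).
EXCLUDED_COVARIATES: frozenset[str] = frozenset({"glucose", "C18:3"})


@dataclass(frozen=True)
class CovariateSpec:
    """A continuous covariate to correlate methylation against."""

    name: str
    kind: str  # bmi | individual_fa | saturation_group
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.name in EXCLUDED_COVARIATES:
            raise ValueError(f"{self.name} is not a permitted covariate")
        if self.kind not in {"bmi", "individual_fa", "saturation_group"}:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "saturation_group":
            if not self.members:
                raise ValueError("saturation_group requires members")
            unknown = set(self.members) - set(MEASURED_FA)
            if unknown:
                raise ValueError(f"unknown FA in group: {sorted(unknown)}")
        if self.kind == "individual_fa" and self.name not in MEASURED_FA:
            raise ValueError(f"unknown FA {self.name!r}")

    @classmethod
    def bmi(cls) -> "CovariateSpec":
        return cls("BMI", "bmi")

    @classmethod
    def fa(cls, name: str) -> "CovariateSpec":
        return cls(name, "individual_fa")

    @classmethod
    def group(cls, name: str) -> "CovariateSpec":
        return cls(name, "saturation_group", tuple(SATURATION_GROUPS[name]))


@dataclass(frozen=True)
class CorrelationOutcome:
    method: str  # pearson | spearman
    r: float
    p: float
    n: int


def shapiro_normal(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality test; returns (W, p, is_normal)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p >= alpha)


def choose_correlation(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    gate: str = "both",
) -> CorrelationOutcome:
    """Correlate two vectors, choosing Pearson or Spearman by normality.

    Pearson is used when the Shapiro-Wilk gate passes (``both`` vectors
    normal by default; ``either``/``y_only`` gates available); otherwise
    Spearman with average ranks and the t-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must be equal-length vectors of size >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    _, _, x_norm = shapiro_normal(x, alpha)
    _, _, y_norm = shapiro_normal(y, alpha)
    if gate == "both":
        use_pearson = x_norm and y_norm
    elif gate == "either":
        use_pearson = x_norm or y_norm
    elif gate == "y_only":
        use_pearson = y_norm
    else:
        raise ValueError(f"unknown normality gate {gate!r}")
    if use_pearson:
        r, p = stats.pearsonr(x, y)
        return CorrelationOutcome("pearson", float(r), float(p), x.size)
    rho, p = stats.spearmanr(x, y)
    return CorrelationOutcome("spearman", float(rho), float(p), x.size)


def covariate_values(
    records: Sequence[SampleRecord], spec: CovariateSpec
) -> np.ndarray:
    """Extract the covariate vector for a list of samples (one state)."""
    states = {r.prandial_state for r in records}
    if len(states) > 1:
        raise ValueError("records mix prandial states")
    if spec.kind == "bmi":
        return np.array([r.bmi for r in records], dtype=float)
    if spec.kind == "individual_fa":
        return np.array([_fa_value(r, spec.name) for r in records], dtype=float)
    return np.array(
        [sum(_fa_value(r, m) for m in spec.members) for r in records], dtype=float
    )


def _fa_value(record: SampleRecord, name: str) -> float:
    if name in EXCLUDED_COVARIATES:
        raise ValueError(f"{name} is not a permitted covariate")
    try:
        return record.fa_profile[name]
    except KeyError:
        raise ValueError(
            f"unknown FA {name!r} for subject {record.subject_id}"
        ) from None


def _extreme_indices(
    records: Sequence[SampleRecord],
    spec: CovariateSpec,
    group_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(low, high) sample indices: N/Ob classes for BMI, covariate tertiles else."""
    if spec.kind == "bmi":
        low = np.array(
            [i for i, r in enumerate(records) if r.bmi_class is BMIClass.N]
        )
        high = np.array(
            [i for i, r in enumerate(records) if r.bmi_class is BMIClass.Ob]
        )
    else:
        x = covariate_values(records, spec)
        k = group_size or len(records) // 3
        order = np.argsort(x, kind="stable")
        low, high = order[:k], order[-k:]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need at least 2 samples per extreme group")
    return low, high


def delta_beta_extremes(
    beta_row: Sequence[float],
    records: Sequence[SampleRecord],
    spec: CovariateSpec,
    group_size: int | None = None,
) -> float:
    """Beta-scale effect size between covariate extreme groups.

    BMI: mean beta of obese minus normoweight samples.  FA covariates: mean
    beta of the top minus bottom covariate tertile (size floor(n/3) unless
    overridden) — for the 12-subject design the BMI tertiles coincide with
    the N and Ob classes.
    """
    beta_row = np.asarray(beta_row, dtype=float)
    low, high = _extreme_indices(records, spec, group_size)
    return float(beta_row[high].mean() - beta_row[low].mean())


def ols_covariate_pvalues(
    m_matrix: np.ndarray, covariate: np.ndarray, proportions: np.ndarray
) -> np.ndarray:
    """Cell-adjusted covariate p-values for many probes at once.

    Fits M ~ intercept + covariate + cell proportions (one cell column
    dropped for identifiability, constant columns dropped) by OLS and
    returns the two-sided t-test p-value of the covariate coefficient per
    probe row.
    """
    m_matrix = np.atleast_2d(np.asarray(m_matrix, dtype=float))
    covariate = np.asarray(covariate, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    n = covariate.size
    cells = proportions[:, :-1]  # drop one: proportions sum to 1
    keep = [j for j in range(cells.shape[1]) if np.ptp(cells[:, j]) > 0]
    X = np.column_stack([np.ones(n), covariate, cells[:, keep]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"{n} samples cannot identify {k} coefficients")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = m_matrix @ X @ xtx_inv.T  # probes x k
    resid = m_matrix - beta_hat @ X.T
    sigma2 = (resid**2).sum(axis=1) / (n - k)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    t = beta_hat[:, 1] / se
    return 2.0 * stats.t.sf(np.abs(t), df=n - k)


def adjust_cell_composition(
    m_row: Sequence[float], covariate: Sequence[float], proportions: np.ndarray
) -> float:
    """Cell-composition-adjusted p-value for one probe (see above)."""
    p = ols_covariate_pvalues(
        np.asarray(m_row, dtype=float)[None, :],
        np.asarray(covariate, dtype=float),
        np.asarray(proportions, dtype=float),
    )
    return float(p[0])


def call_dm_for_covariate(
    dataset: MethylationDataset,
    spec: CovariateSpec,
    alpha: float = 0.05,
    min_delta: float = 0.10,
    adjust_cells: bool = False,
    gate: str = "both",
    group_size: int | None = None,
) -> list[AssociationResult]:
    """Call dmCpGs for one covariate within one prandial-state dataset.

    A probe is a dmCpG when the correlation p-value used (cell-adjusted when
    ``adjust_cells``) is below ``alpha`` and |delta beta| between extreme
    groups exceeds ``min_delta``.  Direction is hyper for positive r.
    Constant probes are excluded with a logged count.
    """
    if dataset.sample_records is None:
        raise ValueError("dataset requires attached sample metadata")
    state = dataset.single_state()
    if dataset.n_samples < 6:
        raise ValueError("need at least 6 samples")
    records = dataset.sample_records
    x = covariate_values(records, spec)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {spec.name} is constant")
    m = beta_to_m(dataset.beta)
    low, high = _extreme_indices(records, spec, group_size)

    p_adj_all = None
    if adjust_cells:
        props = np.array(
            [list(r.cell_proportions.values()) for r in records], dtype=float
        )
        p_adj_all = ols_covariate_pvalues(m, x, props)

    results: list[AssociationResult] = []
    n_constant = 0
    for i, probe in enumerate(dataset.probe_ids):
        row = m[i]
        if np.ptp(row) == 0:
            n_constant += 1
            continue
        out = choose_correlation(x, row, alpha=alpha, gate=gate)
        dbeta = float(dataset.beta[i, high].mean() - dataset.beta[i, low].mean())
        p_adj = float(p_adj_all[i]) if p_adj_all is not None else None
        p_used = p_adj if adjust_cells else out.p
        results.append(
            AssociationResult(
                probe_id=probe,
                covariate=spec.name,
                prandial_state=state,
                method=out.method,
                r=out.r,
                p=out.p,
                p_cell_adjusted=p_adj,
                delta_beta=dbeta,
                direction="hyper" if out.r > 0 else "hypo",
                is_dmcpg=bool(p_used < alpha and abs(dbeta) > min_delta),
            )
        )
    if n_constant:
        log.info("excluded %d constant probes for covariate %s", n_constant, spec.name)
    return results
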