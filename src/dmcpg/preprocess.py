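"""Beta/M-value conversion and the probe filtering cascade.

All hypothesis tests operate on M-values, M = log2(beta / (1 - beta)); the
more intuitive beta scale is used for effect sizes and presentation.  The
probe filter removes, in a fixed order: SNP-affected probes, sex-chromosome
probes, probes failing detection, probes with missing values, and probes
whose methylation associates with subject age (tested with the same
normality-adaptive correlation used for the main analysis, so age effects
cannot masquerade as covariate effects in a 12-subject design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MethylationDataset

log = logging.getLogger(__name__)

__all__ = ["beta_to_m", "m_to_beta", "FilterReport", "filter_probes", "filter_cohort"]

_SEX_CHROMS = {"chrx", "chry", "x", "y"}


def beta_to_m(beta):
    """logit2 transform: M = log2(beta / (1 - beta)); requires 0 < beta < 1."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)) or not np.all(np.isfinite(beta)):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(beta / (1.0 - beta))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("M values must be finite")
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


@dataclass
class FilterReport:
    """Attrition bookkeeping for one filtering run.

    Removal reasons are assigned in the fixed order
    SNP -> sex -> detection -> missing -> age, so the counts partition the
    removed probes with no double counting.
    """

    n_input: int
    n_removed_snp: int = 0
    n_removed_sex: int = 0
    n_removed_detection: int = 0
    n_removed_missing: int = 0
    n_removed_age: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - (
            self.n_removed_snp
            + self.n_removed_sex
            + self.n_removed_detection
            + self.n_removed_missing
            + self.n_removed_age
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("input", self.n_input),
            ("removed_snp", self.n_removed_snp),
            ("removed_sex", self.n_removed_sex),
            ("removed_detection", self.n_removed_detection),
            ("removed_missing", self.n_removed_missing),
            ("removed_age", self.n_removed_age),
            ("retained", self.n_retained),
        ]
        pd.DataFrame(rows, columns=["stage", "n"]).to_csv(path, sep="\t", index=False)


def _age_associated(
    dataset: MethylationDataset, ages: np.ndarray, alpha: float
) -> set[str]:
    from .association import choose_correlation

    hits: set[str] = set()
    m = dataset.m_values()
    for i, probe in enumerate(dataset.probe_ids):
        row = m[i]
        if np.ptp(row) == 0:
            continue  # constant probe: test undefined, retain
        out = choose_correlation(ages, row)
        if out.p < alpha:
            hits.add(probe)
    return hits


def filter_probes(
    dataset: MethylationDataset,
    annotation: pd.DataFrame,
    snp_probes: set[str] | None = None,
    detection_p: pd.DataFrame | None = None,
    ages: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    detection_threshold: float = 0.01,
    detection_rule: str = "any",
    age_remove: set[str] | None = None,
) -> tuple[MethylationDataset, FilterReport]:
    """Apply the probe filtering cascade to one dataset.

    Parameters
    ----------
    annotation
        Probe manifest indexed by probe_id with a ``chrom`` column; must
        cover every probe in the dataset.
    snp_probes
        Probe IDs affected by SNPs (user-supplied compilation).
    detection_p
        Optional detection p-value table mirroring the beta matrix; a probe
        is removed when its detection p exceeds ``detection_threshold`` in
        ``any``/``all``/``mean`` of the samples (``detection_rule``).
    ages
        Per-subject ages; defaults to the attached sample records.  Probes
        whose M-values associate with age at p < ``alpha`` (normality-adaptive
        correlation) are removed.
    age_remove
        Precomputed set of age-associated probes; when given, the age test is
        not rerun (used to remove one shared union from both states).
    """
    missing_ann = [p for p in dataset.probe_ids if p not in annotation.index]
    if missing_ann:
        raise ValueError(f"annotation missing probes: {missing_ann[:5]}")

    report = FilterReport(n_input=dataset.n_probes)
    removed: set[str] = set()

    if snp_probes:
        hit = set(dataset.probe_ids) & set(snp_probes)
        report.n_removed_snp = len(hit)
        removed |= hit

    chroms = annotation.loc[dataset.probe_ids, "chrom"].astype(str).str.lower()
    sex_hit = set(chroms.index[chroms.isin(_SEX_CHROMS)]) - removed
    report.n_removed_sex = len(sex_hit)
    removed |= sex_hit

    if detection_p is not None:
        dp = detection_p.reindex(index=dataset.probe_ids, columns=dataset.sample_ids)
        exceed = dp.to_numpy(dtype=float) > detection_threshold
        if detection_rule == "any":
            flag = exceed.any(axis=1)
        elif detection_rule == "all":
            flag = exceed.all(axis=1)
        elif detection_rule == "mean":
            flag = dp.mean(axis=1).to_numpy() > detection_threshold
        else:
            raise ValueError(f"unknown detection rule {detection_rule!r}")
        det_hit = {p for p, f in zip(dataset.probe_ids, flag) if f} - removed
        report.n_removed_detection = len(det_hit)
        removed |= det_hit

    miss = np.isnan(dataset.beta).any(axis=1)
    miss_hit = {p for p, f in zip(dataset.probe_ids, miss) if f} - removed
    report.n_removed_missing = len(miss_hit)
    removed |= miss_hit

    survivors = dataset.subset_probes([p for p in dataset.probe_ids if p not in removed])
    if age_remove is None:
        if ages is None:
            if survivors.sample_records is None:
                age_remove = set()
            else:
                age_vec = np.array([r.age for r in survivors.sample_records])
                age_remove = (
                    _age_associated(survivors, age_vec, alpha)
                    if np.ptp(age_vec) > 0
                    else set()
                )
        else:
            if survivors.sample_records is None:
                raise ValueError("ages mapping requires attached sample records")
            age_vec = np.array(
                [ages[r.subject_id] for r in survivors.sample_records]
            )
            age_remove = _age_associated(survivors, age_vec, alpha)
    age_hit = age_remove & set(survivors.probe_ids)
    report.n_removed_age = len(age_hit)
    filtered = survivors.subset_probes(
        [p for p in survivors.probe_ids if p not in age_hit]
    )
    log.info(
        "filter: %d -> %d probes (snp %d, sex %d, detection %d, missing %d, age %d)",
        report.n_input, report.n_retained, report.n_removed_snp,
        report.n_removed_sex, report.n_removed_detection,
        report.n_removed_missing, report.n_removed_age,
    )
    return filtered, report


def filter_cohort(
    dataset_fs: MethylationDataset,
    dataset_ps: MethylationDataset,
    annotation: pd.DataFrame,
    snp_probes: set[str] | None = None,
    detection_p_fs: pd.DataFrame | None = None,
    detection_p_ps: pd.DataFrame | None = None,
    alpha: float = 0.05,
    **kwargs,
) -> tuple[MethylationDataset, MethylationDataset, FilterReport, FilterReport]:
    """Filter both prandial states onto one shared probe universe.

    The age test is run per state independently; the union of age-associated
    probes is removed from both, so downstream FS/PS comparisons share a
    single probe universe.  Other filters are probe-intrinsic and identical
    across states (detection tables excepted, whose union is removed too).
    """
    fs1, rep_fs = filter_probes(
        dataset_fs, annotation, snp_probes, detection_p_fs, alpha=alpha, **kwargs
    )
    ps1, rep_ps = filter_probes(
        dataset_ps, annotation, snp_probes, detection_p_ps, alpha=alpha, **kwargs
    )
    shared = set(fs1.probe_ids) & set(ps1.probe_ids)
    fs2 = fs1.subset_probes([p for p in fs1.probe_ids if p in shared])
    ps2 = ps1.subset_probes([p for p in ps1.probe_ids if p in shared])
    return fs2, ps2, rep_fs, rep_ps
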