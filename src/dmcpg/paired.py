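"""Fasting-vs-postprandial differential methylation within one BMI class.

Subject-paired M-value differences are tested with a paired t-test when the
differences pass Shapiro-Wilk normality, otherwise with the Wilcoxon
signed-rank test (exact null distribution for n <= 25, normal approximation
with continuity correction above; zero differences dropped before ranking).
A probe is a dmCpG when p < 0.05 and |mean PS beta - mean FS beta| > 0.10.

With four pairs the exact Wilcoxon branch cannot reach p < 0.05 (its
two-sided minimum is 2/16 = 0.125), so at that class size every call
necessarily comes from the t branch; a warning is emitted to make this
visible.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .io import BMIClass, MethylationDataset, PairedResult
from .preprocess import beta_to_m

log = logging.getLogger(__name__)

__all__ = ["paired_test", "call_paired_dm"]


def paired_test(
    x_fs: Sequence[float],
    x_ps: Sequence[float],
    alpha_normality: float = 0.05,
    approx: bool = False,
) -> tuple[str, float]:
    """Subject-paired two-sided test of PS vs FS values.

    Returns ``(test, p)`` with ``test`` in ``{"paired_t", "wilcoxon"}``.
    All-zero differences yield p = 1.0 by convention (logged).  ``approx``
    forces the asymptotic Wilcoxon p-value regardless of sample size.
    """
    x_fs = np.asarray(x_fs, dtype=float)
    x_ps = np.asarray(x_ps, dtype=float)
    if x_fs.shape != x_ps.shape or x_fs.size < 3:
        raise ValueError("paired vectors must be equal length >= 3")
    d = x_ps - x_fs
    if np.all(d == 0):
        log.debug("all paired differences zero; p = 1 by convention")
        return "wilcoxon", 1.0
    _, p_norm = stats.shapiro(d) if np.ptp(d) > 0 else (None, 0.0)
    if np.ptp(d) > 0 and p_norm >= alpha_normality:
        t = stats.ttest_rel(x_ps, x_fs)
        return "paired_t", float(t.pvalue)
    nz = d[d != 0]
    if nz.size < 3:
        return "wilcoxon", 1.0
    ranks_tied = np.unique(np.abs(nz)).size < nz.size
    if approx or nz.size > 25 or ranks_tied:
        res = stats.wilcoxon(nz, correction=True, method="approx")
    else:
        res = stats.wilcoxon(nz, method="exact")
    return "wilcoxon", float(res.pvalue)


def call_paired_dm(
    dataset_fs: MethylationDataset,
    dataset_ps: MethylationDataset,
    bmi_class: BMIClass | str,
    alpha: float = 0.05,
    min_delta: float = 0.10,
    approx: bool = False,
) -> list[PairedResult]:
    """Call FS-vs-PS dmCpGs within one BMI class.

    Both datasets must cover the same probe universe and the same subjects.
    Delta beta is mean PS beta minus mean FS beta; direction is hyper when
    positive (methylation gained after the meal).
    """
    bmi_class = BMIClass(bmi_class)
    if dataset_fs.probe_ids != dataset_ps.probe_ids:
        raise ValueError("FS and PS datasets must share one probe universe")
    fs = dataset_fs.restrict_class(bmi_class)
    ps = dataset_ps.restrict_class(bmi_class)
    subj_fs = [r.subject_id for r in fs.sample_records]
    subj_ps = [r.subject_id for r in ps.sample_records]
    if set(subj_fs) != set(subj_ps):
        raise ValueError(
            f"subject mismatch between states: {sorted(set(subj_fs) ^ set(subj_ps))}"
        )
    ps = ps.subset_samples([f"{s}_PS" for s in subj_fs])  # align pair order
    if fs.n_samples == 4:
        warnings.warn(
            "class size 4: the exact Wilcoxon branch cannot reach p < 0.05; "
            "paired calls can only arise from the t branch",
            stacklevel=2,
        )
    m_fs = beta_to_m(fs.beta)
    m_ps = beta_to_m(ps.beta)
    results: list[PairedResult] = []
    for i, probe in enumerate(fs.probe_ids):
        test, p = paired_test(m_fs[i], m_ps[i], approx=approx)
        dbeta = float(ps.beta[i].mean() - fs.beta[i].mean())
        results.append(
            PairedResult(
                probe_id=probe,
                bmi_class=bmi_class,
                test=test,
                p=p,
                delta_beta=dbeta,
                direction="hyper" if dbeta > 0 else "hypo",
                is_dmcpg=bool(p < alpha and abs(dbeta) > min_delta),
            )
        )
    return results
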