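"""Seeded generator of EPIC-like methylation cohorts with planted effects.

Emulates the study design every pipeline stage expects: 12 adult subjects
(4 per BMI class), each measured once fasting (FS) and once postprandially
(PS), with blood fatty-acid percentages, leukocyte proportions, a bimodal
baseline beta distribution, and a synthetic genome layout of CpG islands.

Three effect kinds can be planted, each fully recorded in a truth table so
recovery can be scored:

* ``bmi_assoc`` / ``fa_assoc`` — probe M-values depend linearly on the
  covariate; the slope and noise SD are solved numerically so the realized
  correlation and beta-scale extreme-group difference hit their targets in
  expectation.  The effect is present in both prandial states (with
  independently realized noise), so covariate-linked probes do not leak
  into the paired fasting-vs-postprandial comparison.
* ``prandial_shift`` — a beta-scale offset added postprandially, in one BMI
  class only, preferentially on island/promoter probes with low baseline
  methylation for the hypermethylating fraction.

Optionally, cell-composition confounding is injected: leukocyte proportions
drift with BMI and shift between states, and probes load on the granulocyte
fraction, so unadjusted tests inflate while cell-adjusted ones stay
calibrated.

All randomness flows through one ``numpy.random.Generator`` with a mandatory
seed; draw order is fixed (subjects, FA, cells, annotation, baselines,
noise, planted effects), so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .association import SATURATION_GROUPS, CovariateSpec, covariate_values
from .io import (
    BMIClass,
    Compartment,
    IslandSet,
    MethylationDataset,
    PrandialState,
    SampleRecord,
    write_beta_matrix,
    write_sample_sheet,
)
from .preprocess import beta_to_m, m_to_beta

__all__ = [
    "SimConfig",
    "Cohort",
    "generate_cohort",
    "generate_annotation",
    "null_config",
    "paperlike_config",
    "confounded_config",
    "PRESETS",
]

CELL_TYPES = ("Gran", "CD4T", "CD8T", "Bcell", "Mono", "NK")
_CELL_MEANS = np.array([0.60, 0.15, 0.08, 0.06, 0.08, 0.03])

#: Typical blood percentages (of total measured FA) used as draw means.
_FA_MEANS = {
    "C14:0": 1.0, "PA": 22.0, "C18:0": 12.0,
    "C16:1": 1.5, "EA": 0.3, "OA": 20.0, "C20:1": 0.3,
    "LA": 22.0, "EDA": 0.3, "DGLA": 1.5, "AA": 9.0,
    "EPA": 0.7, "C22:4": 0.3, "C22:5": 0.5, "C22:6": 2.5,
}

_COMPARTMENT_PROPS = {
    Compartment.promoter: 0.15,
    Compartment.utr5: 0.05,
    Compartment.first_exon: 0.05,
    Compartment.body: 0.35,
    Compartment.utr3: 0.05,
    Compartment.intergenic: 0.35,
}
_RELATION_PROPS = {"island": 0.30, "shore": 0.25, "shelf": 0.15, "open_sea": 0.30}

_ISLAND_SPACING = 12_000  # leaves >4 kb of open sea between shelf edges
_SHORE = 2000
_SHELF = 2000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the motivating design: 12 subjects, 4 per BMI class,
    EPIC-like bimodal baselines, planted associations with r = 0.9 and
    delta beta = 0.2, and a postprandial shift of +/-0.2 beta planted in the
    overweight class only.
    """

    seed: int
    n_subjects_per_class: int = 4
    n_probes: int = 20_000
    n_planted_bmi: int = 200
    n_planted_fa_per_group: int = 60
    n_planted_prandial: int = 150
    prandial_class: BMIClass = BMIClass.Ow
    target_r: float = 0.9
    target_delta_beta: float = 0.2
    prandial_delta_beta: float = 0.2
    direction_hyper_frac: float = 0.5
    prandial_hyper_frac: float = 0.6
    noise_sd_m: float = 0.15
    mixture_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    fa_group_rho: float = 0.5
    fa_state_rho: float = 0.9  # FS/PS subject correlation of FA composition
    fa_log_sd: float = 0.2
    cell_concentration: float = 150.0
    cell_shift_ps: float = 0.0     # PS granulocyte mean shift (confounding)
    cell_bmi_tilt: float = 0.0     # granulocyte mean per BMI unit
    cell_loading_sd: float = 0.0   # per-probe M loading on granulocyte frac

    def __post_init__(self) -> None:
        planted = (
            self.n_planted_bmi
            + self.n_planted_fa_per_group * len(SATURATION_GROUPS)
            + self.n_planted_prandial
        )
        if planted > self.n_probes:
            raise ValueError("more planted probes than probes")
        if abs(self.target_delta_beta) > 0.5 or abs(self.prandial_delta_beta) > 0.5:
            raise ValueError("|target delta beta| must be <= 0.5")


def null_config(seed: int, n_probes: int = 20_000) -> SimConfig:
    """No planted effects: every rejection is a false positive."""
    return SimConfig(
        seed=seed,
        n_probes=n_probes,
        n_planted_bmi=0,
        n_planted_fa_per_group=0,
        n_planted_prandial=0,
    )


def paperlike_config(seed: int, n_probes: int = 20_000) -> SimConfig:
    """Default planted design: covariate associations plus an Ow-only shift."""
    return SimConfig(seed=seed, n_probes=n_probes)


def confounded_config(seed: int, n_probes: int = 20_000) -> SimConfig:
    """Null effects plus strong cell-composition confounding.

    The granulocyte fraction drifts with BMI (tilt 0.015 per kg/m^2, i.e.
    roughly 0.50 to 0.80 across the cohort's BMI range) and shifts upward
    postprandially; a tight Dirichlet (concentration 400) keeps biological
    scatter well below the drift so the confounding path, not sampling
    noise, dominates the 12-subject design.  Probes load on the granulocyte
    fraction with SD 4 on the M scale.
    """
    return replace(
        null_config(seed, n_probes),
        cell_shift_ps=0.08,
        cell_bmi_tilt=0.015,
        cell_concentration=400.0,
        cell_loading_sd=4.0,
    )


PRESETS = {
    "null": null_config,
    "paperlike": paperlike_config,
    "confounded": confounded_config,
}


class Cohort(NamedTuple):
    dataset_fs: MethylationDataset
    dataset_ps: MethylationDataset
    annotation: pd.DataFrame
    islands: IslandSet
    truth: pd.DataFrame

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_beta_matrix(self.dataset_fs, outdir / "beta_FS.tsv")
        write_beta_matrix(self.dataset_ps, outdir / "beta_PS.tsv")
        write_sample_sheet(
            list(self.dataset_fs.sample_records)
            + list(self.dataset_ps.sample_records),
            outdir / "samples.csv",
        )
        self.annotation.reset_index().to_csv(outdir / "annotation.csv", index=False)
        with open(outdir / "islands.bed", "w") as fh:
            for chrom, start, end in self.islands.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def generate_annotation(
    n_probes: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, IslandSet]:
    """Synthetic genome layout with islands, shores, shelves and open sea.

    Probes are placed at construction-known distances from island edges, so
    the true island relation of every probe is recomputable from coordinates
    (stored in the ``true_relation`` column for cross-checks).
    """
    n_islands = max(1, n_probes // 40)
    per_chrom = 500
    islands = []
    for k in range(n_islands):
        chrom = f"chr{k // per_chrom + 1}"
        start = 10_000 + (k % per_chrom) * _ISLAND_SPACING
        length = int(rng.integers(600, 1500))
        islands.append((chrom, start, start + length))
    island_set = IslandSet(islands)

    rel_names = list(_RELATION_PROPS)
    rel_draw = rng.choice(
        len(rel_names), size=n_probes, p=list(_RELATION_PROPS.values())
    )
    comp_names = list(_COMPARTMENT_PROPS)
    comp_draw = rng.choice(
        len(comp_names), size=n_probes, p=list(_COMPARTMENT_PROPS.values())
    )
    host = rng.integers(0, n_islands, size=n_probes)
    side = rng.integers(0, 2, size=n_probes)  # 0: right of end, 1: left of start

    rows = []
    gene_counter = 0
    for i in range(n_probes):
        chrom, start, end = islands[host[i]]
        rel = rel_names[rel_draw[i]]
        if rel == "island":
            pos = int(rng.integers(start, end))
        elif rel == "shore":
            d = int(rng.integers(0, _SHORE))
            pos = end + d if side[i] else start - 1 - d
        elif rel == "shelf":
            d = int(rng.integers(_SHORE, _SHORE + _SHELF))
            pos = end + d if side[i] else start - 1 - d
        else:  # open sea: beyond the shelf but before the next island's shelf
            lo = end + _SHORE + _SHELF
            hi = start + _ISLAND_SPACING - _SHORE - _SHELF - 1
            pos = int(rng.integers(lo, max(lo + 1, hi)))
        pos = max(pos, 0)
        comp = comp_names[comp_draw[i]]
        if comp is Compartment.intergenic:
            gene = ""
        else:
            gene_counter += rng.random() < 0.4  # ~2-3 probes per gene
            gene = f"G{gene_counter:05d}"
        rows.append(
            {
                "probe_id": f"cg{i:08d}",
                "chrom": chrom,
                "pos": pos,
                "gene": gene,
                "compartment": comp.value,
                "true_relation": rel,
            }
        )
    ann = pd.DataFrame(rows).set_index("probe_id")
    return ann, island_set


def _draw_subjects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    bins = {BMIClass.N: (18.5, 24.9), BMIClass.Ow: (25.0, 29.9), BMIClass.Ob: (30.0, 40.0)}
    rows = []
    i = 0
    for cls, (lo, hi) in bins.items():
        for _ in range(cfg.n_subjects_per_class):
            i += 1
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "bmi": float(rng.uniform(lo, hi)),
                    "bmi_class": cls,
                    "age": float(np.clip(rng.normal(35, 8), 20, 60)),
                }
            )
    return pd.DataFrame(rows)


def _draw_fa_profiles(
    n: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[dict[str, float]], list[dict[str, float]]]:
    """Log-normal FA draws for both prandial states, percent-normalized.

    Within a saturation group FA are correlated with ``fa_group_rho``;
    across states the same subject's composition is correlated with
    ``fa_state_rho`` (blood FA composition is subject-characteristic, so a
    meal perturbs rather than replaces it).
    """
    fs = [dict() for _ in range(n)]
    ps = [dict() for _ in range(n)]
    rho_s = cfg.fa_state_rho
    for group, members in SATURATION_GROUPS.items():
        k = len(members)
        cov = np.full((k, k), cfg.fa_group_rho)
        np.fill_diagonal(cov, 1.0)
        z_fs = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        z_new = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        z_ps = rho_s * z_fs + math.sqrt(1.0 - rho_s**2) * z_new
        for j, fa in enumerate(members):
            for s in range(n):
                fs[s][fa] = _FA_MEANS[fa] * float(np.exp(cfg.fa_log_sd * z_fs[s, j]))
                ps[s][fa] = _FA_MEANS[fa] * float(np.exp(cfg.fa_log_sd * z_ps[s, j]))
    for prof in (*fs, *ps):
        total = sum(prof.values())
        for fa in prof:
            prof[fa] = 100.0 * prof[fa] / total
    return fs, ps


def _draw_cells(
    subjects: pd.DataFrame,
    state: PrandialState,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    out = []
    for _, row in subjects.iterrows():
        mu = _CELL_MEANS.copy()
        # move the granulocyte mean directly and rescale the lymphoid/myeloid
        # remainder, so the configured drift is realized 1:1 in the mean
        gran = mu[0] + cfg.cell_bmi_tilt * (row.bmi - 26.5)
        if state is PrandialState.PS:
            gran += cfg.cell_shift_ps
        gran = float(np.clip(gran, 0.05, 0.90))
        mu[1:] *= (1.0 - gran) / (1.0 - mu[0])
        mu[0] = gran
        draw = rng.dirichlet(cfg.cell_concentration * mu)
        out.append(dict(zip(CELL_TYPES, draw)))
    return out


def _solve_planted(
    m0: float, x: np.ndarray, low: np.ndarray, high: np.ndarray,
    target_delta: float, target_r: float, probe_id: str,
) -> tuple[float, float]:
    """Slope and noise SD hitting the delta-beta and r targets in expectation."""
    xc = x - x.mean()
    d_high = xc[high].mean()
    d_low = xc[low].mean()

    def gap(slope: float) -> float:
        return (
            m_to_beta(m0 + slope * d_high) - m_to_beta(m0 + slope * d_low)
        ) - target_delta

    lim = 50.0 / max(abs(d_high), abs(d_low), 1e-9)
    try:
        slope = brentq(gap, -lim, lim)
    except ValueError as exc:
        raise ValueError(
            f"probe {probe_id}: delta-beta target {target_delta} unreachable "
            f"from baseline beta {m_to_beta(m0):.3f}"
        ) from exc
    sigma = abs(slope) * xc.std() * np.sqrt(1.0 / target_r**2 - 1.0)
    return slope, sigma


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate paired FS/PS datasets, annotation, islands and a truth table."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    subjects = _draw_subjects(cfg, rng)
    n_sub = len(subjects)
    fa_fs, fa_ps = _draw_fa_profiles(n_sub, cfg, rng)
    cells_fs = _draw_cells(subjects, PrandialState.FS, cfg, rng)
    cells_ps = _draw_cells(subjects, PrandialState.PS, cfg, rng)

    def records(state, fa, cells):
        return [
            SampleRecord(
                subject_id=row.subject_id,
                prandial_state=state,
                bmi=row.bmi,
                bmi_class=row.bmi_class,
                age=row.age,
                fa_profile=fa[i],
                cell_proportions=cells[i],
            )
            for i, row in enumerate(subjects.itertuples(index=False))
        ]

    rec_fs = records(PrandialState.FS, fa_fs, cells_fs)
    rec_ps = records(PrandialState.PS, fa_ps, cells_ps)

    annotation, islands = generate_annotation(cfg.n_probes, rng)
    probe_ids = list(annotation.index)

    # baseline beta: 3-component mixture giving the array's bimodal shape
    comp = rng.choice(3, size=cfg.n_probes, p=list(cfg.mixture_weights))
    ab = np.array([[2.0, 20.0], [5.0, 5.0], [20.0, 2.0]])
    beta0 = rng.beta(ab[comp, 0], ab[comp, 1])
    beta0 = np.clip(beta0, 0.01, 0.99)
    m0 = beta_to_m(beta0)

    m_fs = m0[:, None] + rng.normal(0, cfg.noise_sd_m, (cfg.n_probes, n_sub))
    m_ps = m0[:, None] + rng.normal(0, cfg.noise_sd_m, (cfg.n_probes, n_sub))

    if cfg.cell_loading_sd > 0:
        gamma = rng.normal(0, cfg.cell_loading_sd, cfg.n_probes)
        gran_fs = np.array([c["Gran"] for c in cells_fs])
        gran_ps = np.array([c["Gran"] for c in cells_ps])
        m_fs += gamma[:, None] * (gran_fs - _CELL_MEANS[0])[None, :]
        m_ps += gamma[:, None] * (gran_ps - _CELL_MEANS[0])[None, :]

    cls = np.array([c.value for c in subjects["bmi_class"]])

    truth_rows: list[dict] = []
    taken: set[int] = set()

    def pick(pool: np.ndarray, k: int, what: str) -> np.ndarray:
        pool = np.array([i for i in pool if i not in taken])
        if len(pool) < k:
            raise ValueError(f"not enough feasible probes for {what}")
        chosen = rng.choice(pool, size=k, replace=False)
        taken.update(chosen.tolist())
        return chosen

    # covariate-linked probes (planted in FS): mid-range baselines keep both
    # directions of a 0.2 delta-beta feasible
    feasible = np.flatnonzero((beta0 > 0.15) & (beta0 < 0.85))

    def plant_assoc(kind: str, spec: CovariateSpec, k: int) -> None:
        if k == 0:
            return
        # the effect is present in both prandial states (independently
        # realized noise); extreme groups are covariate tertiles, which for
        # BMI coincide with the N and Ob classes
        per_state = []
        for recs, m_mat in ((rec_fs, m_fs), (rec_ps, m_ps)):
            x = covariate_values(recs, spec)
            order = np.argsort(x, kind="stable")
            tert = n_sub // 3
            per_state.append((x, order[:tert], order[-tert:], m_mat))
        chosen = pick(feasible, k, f"{kind} {spec.name}")
        hyper = rng.random(k) < cfg.direction_hyper_frac
        for j, i in enumerate(chosen):
            sign = 1.0 if hyper[j] else -1.0
            for x, idx_low, idx_high, m_mat in per_state:
                slope, sigma = _solve_planted(
                    float(m0[i]), x, idx_low, idx_high,
                    sign * cfg.target_delta_beta, cfg.target_r, probe_ids[i],
                )
                xc = x - x.mean()
                m_mat[i] = m0[i] + slope * xc + rng.normal(0, sigma, n_sub)
            truth_rows.append(
                {
                    "probe_id": probe_ids[i],
                    "effect_kind": kind,
                    "covariate": spec.name,
                    "target_r": sign * cfg.target_r,
                    "target_delta_beta": sign * cfg.target_delta_beta,
                    "direction": "hyper" if hyper[j] else "hypo",
                    "noise_sd": sigma,
                }
            )

    plant_assoc("bmi_assoc", CovariateSpec.bmi(), cfg.n_planted_bmi)
    for group in SATURATION_GROUPS:
        plant_assoc(
            "fa_assoc", CovariateSpec.group(group), cfg.n_planted_fa_per_group
        )

    # prandial-shift probes: beta offset in PS only, configured class only;
    # the hyper fraction goes preferentially to low-baseline island/promoter
    # probes (methylation gained where there was little)
    if cfg.n_planted_prandial:
        rel = annotation["true_relation"].to_numpy()
        compart = annotation["compartment"].to_numpy()
        regulatory = (rel == "island") | np.isin(
            compart, [Compartment.promoter.value, Compartment.first_exon.value,
                      Compartment.utr5.value]
        )
        n_hyper = int(round(cfg.n_planted_prandial * cfg.prandial_hyper_frac))
        pool_hyper = np.flatnonzero(
            regulatory & (beta0 > 0.03) & (beta0 < 0.35)
        )
        pool_hypo = np.flatnonzero((beta0 > 0.35) & (beta0 < 0.95))
        cls_cols = np.flatnonzero(cls == cfg.prandial_class.value)
        for pool, k, sign, label in (
            (pool_hyper, n_hyper, 1.0, "hyper"),
            (pool_hypo, cfg.n_planted_prandial - n_hyper, -1.0, "hypo"),
        ):
            chosen = pick(pool, k, f"prandial_shift {label}")
            for i in chosen:
                b_target = beta0[i] + sign * cfg.prandial_delta_beta
                if not 0.005 < b_target < 0.995:
                    raise ValueError(
                        f"probe {probe_ids[i]}: prandial shift target "
                        f"{b_target:.3f} outside (0, 1)"
                    )
                shift_m = beta_to_m(b_target) - float(m0[i])
                m_ps[i, cls_cols] += shift_m
                truth_rows.append(
                    {
                        "probe_id": probe_ids[i],
                        "effect_kind": "prandial_shift",
                        "covariate": cfg.prandial_class.value,
                        "target_r": np.nan,
                        "target_delta_beta": sign * cfg.prandial_delta_beta,
                        "direction": label,
                        "noise_sd": cfg.noise_sd_m,
                    }
                )

    beta_fs = np.clip(m_to_beta(m_fs), 1e-6, 1 - 1e-6)
    beta_ps = np.clip(m_to_beta(m_ps), 1e-6, 1 - 1e-6)
    ds_fs = MethylationDataset(
        probe_ids, [r.sample_id for r in rec_fs], beta_fs, rec_fs
    )
    ds_ps = MethylationDataset(
        probe_ids, [r.sample_id for r in rec_ps], beta_ps, rec_ps
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "probe_id", "effect_kind", "covariate", "target_r",
            "target_delta_beta", "direction", "noise_sd",
        ],
    )
    return Cohort(ds_fs, ds_ps, annotation, islands, truth)
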