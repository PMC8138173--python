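"""Set-level synthesis of dmCpG calls.

Overlap percentages between dmCpG sets (with the denominator policies used
for BMI-vs-FA and FA-vs-FA comparisons), direction proportions, FS/PS count
ratios, genomic-context distributions with chi-square goodness-of-fit
against the probe universe, CpG-island geography (island / shore / shelf /
open sea), baseline beta-quartile profiles, and a generic hypergeometric
over-representation engine with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    AssociationResult,
    IslandRelation,
    IslandSet,
    MethylationDataset,
    PairedResult,
)

log = logging.getLogger(__name__)

__all__ = [
    "DmSet",
    "OverlapSummary",
    "ContextDistribution",
    "overlap",
    "direction_proportions",
    "compare_overlap_groups",
    "compare_counts_fs_ps",
    "classify_island_relation",
    "annotate_islands",
    "context_distribution",
    "quartile_distribution",
    "gene_set_enrichment",
    "read_gmt",
]

SHORE_WIDTH = 2000  # bases flanking an island
SHELF_WIDTH = 2000  # bases flanking a shore


@dataclass(frozen=True)
class DmSet:
    """A labelled set of dmCpG probe IDs."""

    label: str
    probe_ids: frozenset[str]

    @classmethod
    def from_results(
        cls, label: str, results: Sequence[AssociationResult] | Sequence[PairedResult]
    ) -> "DmSet":
        return cls(label, frozenset(r.probe_id for r in results if r.is_dmcpg))

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class OverlapSummary:
    label_a: str
    label_b: str
    shared: int
    denominator: int
    percent: float


@dataclass
class ContextDistribution:
    categories: list[str]
    counts: np.ndarray
    background_counts: np.ndarray
    chi2: float
    p: float


def overlap(a: DmSet, b: DmSet, policy: str = "b_count") -> OverlapSummary:
    """Shared probes between two dmCpG sets as a percentage.

    The denominator follows the comparison convention: ``b_count`` (e.g. the
    FA set in BMI-vs-FA comparisons), ``min_count`` (the smaller set, for
    FA-vs-FA comparisons), or ``a_count``.
    """
    shared = len(a.probe_ids & b.probe_ids)
    denom = {
        "a_count": len(a),
        "b_count": len(b),
        "min_count": min(len(a), len(b)),
    }.get(policy)
    if denom is None:
        raise ValueError(f"unknown overlap policy {policy!r}")
    if denom == 0:
        raise ValueError(f"zero denominator for {a.label} vs {b.label} ({policy})")
    return OverlapSummary(a.label, b.label, shared, denom, 100.0 * shared / denom)


def direction_proportions(
    results: Sequence[AssociationResult] | Sequence[PairedResult],
) -> tuple[float, float]:
    """(percent hypomethylated, percent hypermethylated) among dmCpGs."""
    dm = [r for r in results if r.is_dmcpg]
    if not dm:
        raise ValueError("no dmCpGs to partition")
    n_hypo = sum(r.direction == "hypo" for r in dm)
    pct_hypo = 100.0 * n_hypo / len(dm)
    return pct_hypo, 100.0 - pct_hypo


def compare_overlap_groups(
    percents_a: Sequence[float], percents_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two groups of overlap percentages.

    Exact null distribution when the combined sample is small (<= 20) and
    tie-free; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(percents_a, dtype=float)
    b = np.asarray(percents_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_counts_fs_ps(
    fs_counts: Sequence[float], ps_counts: Sequence[float]
) -> tuple[float, float]:
    """Mean per-covariate FS/PS dmCpG count ratio and a paired test p-value.

    Ratio terms with a zero PS count are dropped (logged); the p-value comes
    from the paired test (t or Wilcoxon by normality of the differences)
    applied to the full count vectors.
    """
    from .paired import paired_test

    fs = np.asarray(fs_counts, dtype=float)
    ps = np.asarray(ps_counts, dtype=float)
    if fs.shape != ps.shape:
        raise ValueError("count vectors must align by covariate")
    usable = ps > 0
    if (~usable).any():
        log.info("dropping %d ratio terms with zero PS count", int((~usable).sum()))
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable covariate pairs")
    mean_ratio = float((fs[usable] / ps[usable]).mean())
    if np.all(fs == ps):
        return mean_ratio, 1.0
    _, p = paired_test(ps, fs)  # direction-symmetric, two-sided
    return mean_ratio, p


def classify_island_relation(
    pos: tuple[str, int],
    islands: IslandSet,
    shore_width: int = SHORE_WIDTH,
    shelf_width: int = SHELF_WIDTH,
) -> IslandRelation:
    """Classify a genomic position relative to CpG islands.

    Islands are half-open [start, end).  Positions within ``shore_width``
    bases outside an island boundary are shore; the next ``shelf_width``
    bases are shelf; everything else is open sea.
    """
    chrom, p = pos
    arr = islands.by_chrom().get(str(chrom))
    if arr is None or len(arr) == 0:
        return IslandRelation.open_sea
    starts, ends = arr[:, 0], arr[:, 1]
    i = int(np.searchsorted(starts, p, side="right")) - 1
    dist = np.inf
    if i >= 0:
        if p < ends[i]:
            return IslandRelation.island
        dist = p - ends[i]  # 0 for the first base past the island
    if i + 1 < len(starts):
        dist = min(dist, starts[i + 1] - p - 1)  # gap bases between p and start
    if dist < shore_width:
        return IslandRelation.shore
    if dist < shore_width + shelf_width:
        return IslandRelation.shelf
    return IslandRelation.open_sea


def annotate_islands(
    annotation: pd.DataFrame,
    islands: IslandSet,
    shore_width: int = SHORE_WIDTH,
    shelf_width: int = SHELF_WIDTH,
) -> pd.DataFrame:
    """Add an ``island_relation`` column to a probe annotation table."""
    rel = [
        classify_island_relation(
            (row.chrom, int(row.pos)), islands, shore_width, shelf_width
        ).value
        for row in annotation.itertuples()
    ]
    out = annotation.copy()
    out["island_relation"] = rel
    return out


def context_distribution(
    dmset: DmSet,
    categories: Mapping[str, str] | pd.Series,
    background: Iterable[str],
    min_expected: float = 1.0,
) -> ContextDistribution:
    """Chi-square goodness-of-fit of a dmCpG set's genomic-context counts.

    ``categories`` maps probe_id to a category label (gene compartment or
    island relation).  Expected counts come from the background (probe
    universe) proportions; categories with expected count below
    ``min_expected`` are merged into the preceding category (logged).
    """
    if isinstance(categories, pd.Series):
        categories = categories.to_dict()
    background = list(background)
    if not dmset.probe_ids:
        raise ValueError("empty dmCpG set")
    if not set(dmset.probe_ids) <= set(background):
        raise ValueError("dmCpG set is not a subset of the background universe")
    cats = sorted({categories[p] for p in background})
    bg_counts = np.array(
        [sum(categories[p] == c for p in background) for c in cats], dtype=float
    )
    obs = np.array(
        [sum(categories[p] == c for p in dmset.probe_ids) for c in cats], dtype=float
    )
    expected = bg_counts / bg_counts.sum() * obs.sum()
    # merge sparse categories into their left neighbour
    merged_cats, merged_obs, merged_exp, merged_bg = [], [], [], []
    for c, o, e, b in zip(cats, obs, expected, bg_counts):
        if merged_cats and e < min_expected:
            log.info("merging sparse category %s into %s", c, merged_cats[-1])
            merged_cats[-1] += "+" + c
            merged_obs[-1] += o
            merged_exp[-1] += e
            merged_bg[-1] += b
        else:
            merged_cats.append(c)
            merged_obs.append(o)
            merged_exp.append(e)
            merged_bg.append(b)
    obs = np.asarray(merged_obs)
    expected = np.asarray(merged_exp)
    if len(obs) < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
    return ContextDistribution(
        merged_cats, obs, np.asarray(merged_bg), chi2, p
    )


QUARTILE_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)


def quartile_distribution(
    dmset: DmSet, baseline: MethylationDataset
) -> np.ndarray:
    """Counts of dmCpGs per baseline mean-beta quartile bin.

    Bins are [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1]; the baseline is
    typically the normoweight samples of one prandial state.
    """
    if baseline.n_samples < 1:
        raise ValueError("baseline has no samples")
    idx = {p: i for i, p in enumerate(baseline.probe_ids)}
    missing = [p for p in dmset.probe_ids if p not in idx]
    if missing:
        raise ValueError(f"probes absent from baseline: {sorted(missing)[:5]}")
    means = baseline.beta.mean(axis=1)
    counts = np.zeros(4, dtype=int)
    for p in dmset.probe_ids:
        b = means[idx[p]]
        k = min(int(b / 0.25), 3)  # left-closed bins, last bin closed at 1
        counts[k] += 1
    return counts


def gene_set_enrichment(
    dm_genes: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of dmCpG-hosting genes.

    One-sided (enrichment) hypergeometric p per target set, intersected with
    the universe; Benjamini-Hochberg q-values; ``significant`` iff
    q < ``fdr_alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    dm = set(dm_genes) & universe
    if not set(dm_genes) <= universe:
        raise ValueError("dm genes must be a subset of the universe")
    rows = []
    for name, genes in target_sets.items():
        target = set(genes) & universe
        k = len(dm & target)
        M, n, N = len(universe), len(target), len(dm)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        expected = n * N / M if M else 0.0
        rows.append(
            {
                "set": name,
                "set_size": n,
                "overlap": k,
                "fold": (k / expected) if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df["significant"] = df["q"] < fdr_alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
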