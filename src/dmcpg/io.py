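"""Domain types and readers/writers for methylation cohort data.

The analysis unit is a :class:`MethylationDataset`: a probes x samples matrix
of beta-values (methylation fractions) aligned with per-sample metadata
(:class:`SampleRecord`).  One dataset per prandial state; the same subjects
appear in both states.  All genomic coordinates are 0-based, half-open.

Tabular formats are deliberately plain: beta matrices as TSV with probe IDs
in the first column, sample sheets and probe manifests as CSV, CpG-island
intervals as BED3.  Result tables round-trip losslessly at 6 significant
digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PrandialState",
    "BMIClass",
    "Compartment",
    "IslandRelation",
    "SampleRecord",
    "MethylationDataset",
    "ProbeAnnotation",
    "IslandSet",
    "AssociationResult",
    "PairedResult",
    "bmi_class_of",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_probe_annotation",
    "read_island_bed",
    "read_exclusion_list",
    "write_results",
    "read_results",
    "write_sample_sheet",
    "write_beta_matrix",
]

BETA_CLIP = 1e-6  # beta exactly 0/1 breaks the logit transform; clip at load
CELL_SUM_TOL = 1e-6


class PrandialState(str, Enum):
    FS = "FS"  # fasting
    PS = "PS"  # postprandial


class BMIClass(str, Enum):
    N = "N"    # normoweight, 18.5 <= BMI < 25
    Ow = "Ow"  # overweight, 25 <= BMI < 30
    Ob = "Ob"  # obese, BMI >= 30


class Compartment(str, Enum):
    promoter = "promoter"
    utr5 = "utr5"
    first_exon = "first_exon"
    body = "body"
    utr3 = "utr3"
    intergenic = "intergenic"


class IslandRelation(str, Enum):
    island = "island"
    shore = "shore"
    shelf = "shelf"
    open_sea = "open_sea"


#: Conventional BMI class bins (kg/m^2), half-open on the right.
BMI_BINS: dict[BMIClass, tuple[float, float]] = {
    BMIClass.N: (18.5, 25.0),
    BMIClass.Ow: (25.0, 30.0),
    BMIClass.Ob: (30.0, math.inf),
}


def bmi_class_of(bmi: float) -> BMIClass:
    """Map a BMI value to its conventional class (N/Ow/Ob)."""
    for cls, (lo, hi) in BMI_BINS.items():
        if lo <= bmi < hi:
            return cls
    raise ValueError(f"BMI {bmi} outside the classifiable range (>= 18.5)")


@dataclass
class SampleRecord:
    """One pooled whole-blood sample: a subject in one prandial state.

    ``fa_profile`` maps fatty-acid names to blood percentages (of summed
    measured FA); ``cell_proportions`` maps leukocyte types to fractions
    summing to 1.
    """

    subject_id: str
    prandial_state: PrandialState
    bmi: float
    bmi_class: BMIClass
    age: float
    fa_profile: dict[str, float] = field(default_factory=dict)
    cell_proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prandial_state = PrandialState(self.prandial_state)
        self.bmi_class = BMIClass(self.bmi_class)
        expected = bmi_class_of(self.bmi)
        if expected is not self.bmi_class:
            raise ValueError(
                f"subject {self.subject_id}: BMI {self.bmi} falls in class "
                f"{expected.value}, labelled {self.bmi_class.value}"
            )
        if any(v < 0 for v in self.fa_profile.values()):
            raise ValueError(f"subject {self.subject_id}: negative FA percentage")
        if self.cell_proportions:
            vals = np.asarray(list(self.cell_proportions.values()), float)
            if (vals < 0).any():
                raise ValueError(
                    f"subject {self.subject_id}: negative cell proportion"
                )
            if abs(vals.sum() - 1.0) > CELL_SUM_TOL:
                raise ValueError(
                    f"subject {self.subject_id}: cell proportions sum to "
                    f"{vals.sum():.8f}, expected 1"
                )

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.prandial_state.value}"


@dataclass
class MethylationDataset:
    """Beta-value matrix (probes x samples) with aligned sample metadata."""

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray
    sample_records: list[SampleRecord] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.sample_records is not None:
            rec_ids = [r.sample_id for r in self.sample_records]
            if rec_ids != self.sample_ids:
                raise ValueError("sample_records not aligned with sample_ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def m_values(self) -> np.ndarray:
        from .preprocess import beta_to_m

        return beta_to_m(self.beta)

    def with_samples(self, records: Sequence[SampleRecord]) -> "MethylationDataset":
        """Attach sample metadata, reordering records to the matrix columns.

        Column order in the beta file is authoritative; sample-sheet row
        order is irrelevant.
        """
        by_id = {r.sample_id: r for r in records}
        if len(by_id) != len(records):
            raise ValueError("duplicate sample ids in records")
        missing = [s for s in self.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"no sample record for columns: {missing}")
        ordered = [by_id[s] for s in self.sample_ids]
        return MethylationDataset(
            list(self.probe_ids), list(self.sample_ids), self.beta.copy(), ordered
        )

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        keep = set(probe_ids)
        idx = [i for i, p in enumerate(self.probe_ids) if p in keep]
        return MethylationDataset(
            [self.probe_ids[i] for i in idx],
            list(self.sample_ids),
            self.beta[idx, :],
            list(self.sample_records) if self.sample_records else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MethylationDataset(
            list(self.probe_ids),
            list(sample_ids),
            self.beta[:, idx],
            [self.sample_records[j] for j in idx] if self.sample_records else None,
        )

    def restrict_class(self, bmi_class: BMIClass | str) -> "MethylationDataset":
        if self.sample_records is None:
            raise ValueError("dataset has no sample metadata attached")
        bmi_class = BMIClass(bmi_class)
        keep = [r.sample_id for r in self.sample_records if r.bmi_class is bmi_class]
        return self.subset_samples(keep)

    def single_state(self) -> PrandialState:
        if self.sample_records is None:
            raise ValueError("dataset has no sample metadata attached")
        states = {r.prandial_state for r in self.sample_records}
        if len(states) != 1:
            raise ValueError("dataset mixes prandial states")
        return states.pop()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic context of one array probe (0-based position)."""

    probe_id: str
    chrom: str
    pos: int
    gene: str = ""
    compartment: Compartment = Compartment.intergenic
    island_relation: IslandRelation | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.probe_id}: negative position")
        if (self.compartment is Compartment.intergenic) != (self.gene == ""):
            raise ValueError(
                f"{self.probe_id}: compartment/gene inconsistency "
                f"({self.compartment.value!r} with gene {self.gene!r})"
            )


@dataclass
class IslandSet:
    """Merged, sorted CpG-island intervals (chrom, start, end), half-open."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end), sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=int) for c, v in out.items()}

    def __len__(self) -> int:
        return len(self.intervals)


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Sort and merge half-open intervals; abutting intervals coalesce."""
    cleaned = []
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end} (end <= start)")
        cleaned.append((str(chrom), int(start), int(end)))
    cleaned.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in cleaned:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class AssociationResult:
    """Per-probe outcome of a covariate correlation test in one state."""

    probe_id: str
    covariate: str
    prandial_state: PrandialState
    method: str  # pearson | spearman
    r: float
    p: float
    delta_beta: float
    direction: str  # hypo | hyper
    is_dmcpg: bool
    p_cell_adjusted: float | None = None


@dataclass
class PairedResult:
    """Per-probe outcome of a fasting-vs-postprandial paired comparison."""

    probe_id: str
    bmi_class: BMIClass
    test: str  # paired_t | wilcoxon
    p: float
    delta_beta: float  # mean PS beta - mean FS beta
    direction: str  # hypo | hyper
    is_dmcpg: bool


# ---------------------------------------------------------------------------
# readers


def read_beta_matrix(path: str | Path) -> MethylationDataset:
    """Read a probes x samples beta TSV (first column: probe IDs).

    Probes with any unparsable or missing cell are dropped with a logged
    count.  Beta values of exactly 0 or 1 are clipped to
    ``[BETA_CLIP, 1 - BETA_CLIP]`` with a warning (the logit transform
    diverges there); values outside [0, 1] are an error naming the cell.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate sample IDs in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(probe_ids)) != len(probe_ids):
        dupes = pd.Index(probe_ids)
        raise ValueError(
            f"duplicate probe IDs in {path}: "
            f"{sorted(set(dupes[dupes.duplicated()]))[:5]}"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample IDs in {path}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    for i, j in zip(*np.where(np.isfinite(values) & ((values < 0) | (values > 1)))):
        raise ValueError(
            f"beta {values[i, j]} outside [0, 1] at probe {probe_ids[i]}, "
            f"sample {sample_ids[j]}"
        )
    keep = ~bad.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d probes with missing/unparsable values", n_dropped)
    values = values[keep, :]
    probe_ids = [p for p, k in zip(probe_ids, keep) if k]
    n_clip = int(((values <= 0) | (values >= 1)).sum())
    if n_clip:
        log.warning("clipped %d boundary beta values to (0, 1)", n_clip)
        values = np.clip(values, BETA_CLIP, 1 - BETA_CLIP)
    return MethylationDataset(probe_ids, sample_ids, values)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata from CSV.

    Required columns: ``subject_id, prandial_state, bmi, bmi_class, age``.
    Fatty-acid columns are prefixed ``fa_`` and re-normalized to percentages
    of the per-sample FA sum; cell-proportion columns are prefixed ``cell_``
    and must sum to 1 per sample.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "prandial_state", "bmi", "bmi_class", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    fa_cols = [c for c in df.columns if c.startswith("fa_")]
    cell_cols = [c for c in df.columns if c.startswith("cell_")]
    records = []
    for _, row in df.iterrows():
        fa_raw = {c[3:]: float(row[c]) for c in fa_cols}
        total = sum(fa_raw.values())
        fa = {k: 100.0 * v / total for k, v in fa_raw.items()} if total > 0 else fa_raw
        cells = {c[5:]: float(row[c]) for c in cell_cols}
        records.append(
            SampleRecord(
                subject_id=str(row["subject_id"]),
                prandial_state=PrandialState(str(row["prandial_state"])),
                bmi=float(row["bmi"]),
                bmi_class=BMIClass(str(row["bmi_class"])),
                age=float(row["age"]),
                fa_profile=fa,
                cell_proportions=cells,
            )
        )
    return records


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest CSV into a DataFrame indexed by probe_id.

    Columns: ``probe_id, chrom, pos, gene, compartment`` (positions 0-based).
    Row-level invariants are checked through :class:`ProbeAnnotation`.
    """
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str, "gene": str})
    df["gene"] = df["gene"].fillna("")
    for row in df.itertuples(index=False):
        ProbeAnnotation(
            probe_id=row.probe_id,
            chrom=row.chrom,
            pos=int(row.pos),
            gene=row.gene,
            compartment=Compartment(row.compartment),
        )
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe IDs in annotation")
    return df.set_index("probe_id")


def read_island_bed(path: str | Path) -> IslandSet:
    """Read CpG-island intervals from BED3 (0-based half-open); merge + sort."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return IslandSet(intervals)


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a plain-text probe exclusion list, one probe ID per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# writers

_ASSOC_COLS = [
    "probe_id", "covariate", "prandial_state", "method", "r", "p",
    "p_cell_adjusted", "delta_beta", "direction", "is_dmcpg",
]
_PAIRED_COLS = [
    "probe_id", "bmi_class", "test", "p", "delta_beta", "direction", "is_dmcpg",
]


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".6g")
    if isinstance(value, Enum):
        return value.value
    return str(value)


def write_results(
    results: Sequence[AssociationResult] | Sequence[PairedResult],
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a homogeneous result list as TSV, sorted by probe_id.

    A commented first line records the package version and any parameters.
    Floats are written at 6 significant digits.
    """
    from . import __version__

    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise ValueError(f"mixed result types: {sorted(k.__name__ for k in kinds)}")
    if kinds == {PairedResult}:
        cols = _PAIRED_COLS
    else:
        cols = _ASSOC_COLS
    ptxt = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# dmcpg {__version__}" + (f" | {ptxt}" if ptxt else "") + "\n")
        fh.write("\t".join(cols) + "\n")
        for r in sorted(results, key=lambda r: r.probe_id):
            fh.write("\t".join(_fmt(getattr(r, c)) for c in cols) + "\n")


def read_results(path: str | Path) -> list[AssociationResult] | list[PairedResult]:
    """Read a result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: list = []
    if "covariate" in df.columns:
        for row in df.itertuples(index=False):
            padj = row.p_cell_adjusted
            out.append(
                AssociationResult(
                    probe_id=str(row.probe_id),
                    covariate=str(row.covariate),
                    prandial_state=PrandialState(row.prandial_state),
                    method=row.method,
                    r=float(row.r),
                    p=float(row.p),
                    p_cell_adjusted=None if pd.isna(padj) else float(padj),
                    delta_beta=float(row.delta_beta),
                    direction=row.direction,
                    is_dmcpg=bool(row.is_dmcpg),
                )
            )
    else:
        for row in df.itertuples(index=False):
            out.append(
                PairedResult(
                    probe_id=str(row.probe_id),
                    bmi_class=BMIClass(row.bmi_class),
                    test=row.test,
                    p=float(row.p),
                    delta_beta=float(row.delta_beta),
                    direction=row.direction,
                    is_dmcpg=bool(row.is_dmcpg),
                )
            )
    return out


def write_beta_matrix(dataset: MethylationDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "prandial_state": r.prandial_state.value,
            "bmi": r.bmi,
            "bmi_class": r.bmi_class.value,
            "age": r.age,
        }
        row.update({f"fa_{k}": v for k, v in r.fa_profile.items()})
        row.update({f"cell_{k}": v for k, v in r.cell_proportions.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
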