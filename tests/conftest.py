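import numpy as np
import pytest

from dmcpg.io import BMIClass, PrandialState, SampleRecord
from dmcpg.simulate import generate_cohort, paperlike_config

CELLS = ("Gran", "CD4T", "CD8T", "Bcell", "Mono", "NK")


def make_record(
    subject="S01",
    state="FS",
    bmi=22.0,
    age=35.0,
    fa=None,
    cells=None,
):
    """Hand-rolled sample record with valid defaults."""
    if fa is None:
        fa = {"C14:0": 1.0, "PA": 22.0, "C18:0": 12.0, "OA": 20.0, "LA": 45.0}
    if cells is None:
        cells = dict(zip(CELLS, (0.60, 0.15, 0.08, 0.06, 0.08, 0.03)))
    return SampleRecord(
        subject_id=subject,
        prandial_state=PrandialState(state),
        bmi=bmi,
        bmi_class=BMIClass("N" if bmi < 25 else "Ow" if bmi < 30 else "Ob"),
        age=age,
        fa_profile=fa,
        cell_proportions=cells,
    )


def make_cohort_records(bmis=None, state="FS", rng=None):
    """12 records, 4 per BMI class, with distinct FA profiles."""
    if bmis is None:
        bmis = [20.0, 21.5, 23.0, 24.5, 25.5, 26.5, 28.0, 29.5, 31.0, 33.0, 35.0, 38.0]
    rng = rng or np.random.default_rng(0)
    records = []
    for i, bmi in enumerate(bmis):
        fa = {
            "C14:0": 1.0 + 0.1 * i, "PA": 22.0 + i, "C18:0": 12.0,
            "OA": 20.0 - 0.5 * i, "LA": 45.0 - 0.5 * i,
        }
        cells = np.asarray([0.60, 0.15, 0.08, 0.06, 0.08, 0.03])
        cells = cells + rng.uniform(-0.01, 0.01, 6)
        cells = cells / cells.sum()
        records.append(
            make_record(
                subject=f"S{i + 1:02d}", state=state, bmi=bmi,
                age=30.0 + 0.5 * i, fa=fa, cells=dict(zip(CELLS, cells)),
            )
        )
    return records


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort shared across tests (2,000 probes, fixed seed)."""
    return generate_cohort(paperlike_config(11, n_probes=2000))


@pytest.fixture()
def cohort_records():
    return make_cohort_records()
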