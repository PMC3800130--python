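import numpy as np
import pandas as pd
import pytest

from gliomix.io import ClinicalTable, ExpressionCohort
from gliomix.simulate import SimulationDesign


@pytest.fixture
def toy_matrix_file(tmp_path):
    """3-probe x 2-sample TSV whose body survives a write round-trip."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "probe_id\ts1\ts2\n"
        "A_at\t1.5\t2\n"
        "B_at\t3.25\t4.5\n"
        "C_at\t6\t7.75\n"
    )
    return path


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(0)
    matrix = pd.DataFrame(
        rng.normal(7, 1, size=(4, 6)),
        index=["A_at", "B_at", "C_at", "D_at"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionCohort(
        cohort_id="toy", matrix=matrix,
        probe_to_gene={"A_at": "GENEA", "B_at": "GENEB",
                       "C_at": "GENEC", "D_at": "GENEA"})


@pytest.fixture
def toy_clinical():
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "cohort_id": "toy",
        "grade": ["IV", "IV", "III", "III", "II", "IV"],
        "histology": ["GBM", "GBM", "astrocytoma", "astrocytoma",
                      "oligodendroglioma", "GBM"],
        "recurrence_status": "primary",
        "age_years": [60, 55, 48, 39, 44, 70],
        "sex": ["male", "female", "male", "female", "male", "female"],
        "os_months": [10.0, 14.0, 20.0, 25.0, 30.0, 8.0],
        "event": [1, 1, 0, 1, 0, 1],
    }))


@pytest.fixture
def small_design():
    """Four small cohorts; fast enough for per-test simulation."""
    return SimulationDesign(
        seed=11,
        sample_counts=(80, 80, 80, 80),
        p_true=(0.5, 0.6, 0.55, 0.65),
        mes_corr=(0.35, 0.4, 0.3, 0.45),
        n_background_probes=60,
    )
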