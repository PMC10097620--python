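import numpy as np
import pandas as pd
import pytest

from dimerscope.design import DESIGN_COLUMNS, generate_design
from dimerscope.io_filter import (filter_categories, filter_max_missing,
                                  filter_min_valid, from_dataframe,
                                  log2_transform)
from dimerscope.matrix import IntensityMatrix
from dimerscope.synthetic import default_ground_truth, simulate_lfq


def make_toy_design(groups: dict[str, int]) -> pd.DataFrame:
    """Minimal valid design: one condition per key, n runs each, factors 0."""
    rows = []
    for label, n in groups.items():
        for i in range(1, n + 1):
            rows.append({
                "run_id": f"{label}_r{i}", "condition_label": label,
                "brafwt": 0, "v600e": 0, "dimerizer": 0,
                "sorafenib": 0, "vemurafenib": 0,
                "bio_rep": i, "tech_rep": 1,
            })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def make_matrix(values, groups: dict[str, int], protein_ids=None) -> IntensityMatrix:
    design = make_toy_design(groups)
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein"),
                      columns=design["run_id"])
    return IntensityMatrix(df, design)


@pytest.fixture(scope="session")
def design96():
    return generate_design(3, 2)


@pytest.fixture(scope="session")
def sim_study(design96):
    truth = default_ground_truth(n_proteins=300, seed=11)
    return simulate_lfq(design96, truth, seed=11)


@pytest.fixture(scope="session")
def filtered_matrix(sim_study, design96):
    table = filter_categories(from_dataframe(sim_study.table))
    m = log2_transform(table, design96)
    m = filter_min_valid(m, 3)
    return filter_max_missing(m, 2)
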