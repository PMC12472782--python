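import numpy as np
import pandas as pd
import pytest

from proteopipe import SimulationConfig, generate_matrix


def make_annotation(n_per_cell=3, sexes=False):
    rows = []
    for g in ("WT", "TG"):
        for t in ("VEH", "DCI"):
            for sx in (("M", "F") if sexes else ("NA",)):
                for i in range(n_per_cell):
                    tag = f"{g}-{t}" + (f"-{sx}" if sx != "NA" else "")
                    rows.append({"sample_id": f"{tag}-{i + 1:02d}",
                                 "genotype": g, "treatment": t, "sex": sx})
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def small_annotation():
    return make_annotation(n_per_cell=3)


@pytest.fixture
def small_matrix(small_annotation):
    rng = np.random.default_rng(0)
    values = rng.uniform(10, 1000, (20, len(small_annotation)))
    return pd.DataFrame(values,
                        index=pd.Index([f"P{i:03d}" for i in range(20)],
                                       name="protein_id"),
                        columns=small_annotation.index)


@pytest.fixture
def study_sized():
    """A study-sized simulated dataset: 12 per 2x2 cell (6 M + 6 F), 48 samples."""
    cfg = SimulationConfig(n_proteins=300, n_per_cell=6, sexes=True, seed=11)
    return generate_matrix(cfg)
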