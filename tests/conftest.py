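import numpy as np
import pandas as pd
import pytest

from forpanel.preprocess import ProteinMatrix, SAMPLE_META_COLUMNS
from forpanel.synthetic_data import (
    NoiseModel, generate_dataset, make_archetypes, make_design,
)


@pytest.fixture(scope="session")
def design10():
    return make_design(10, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """6 athletes, 2 acute + 2 chronic + 8 null proteins, default noise."""
    design = make_design(6, seed=2)
    archetypes = make_archetypes(2, 2, 8, seed=2)
    noise = NoiseModel.with_technical_cv(0.10)
    table, truth = generate_dataset(design, archetypes, noise, seed=2)
    return design, table, truth


def build_matrix(values: np.ndarray, batch_ids, is_qc, protein_ids=None,
                 athlete_ids=None, scale="log") -> ProteinMatrix:
    """Assemble a ProteinMatrix directly from arrays (test scaffolding)."""
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(n_p)]
    sample_ids = [f"S{j:03d}" for j in range(n_s)]
    athlete_ids = athlete_ids or [f"A{j:02d}" for j in range(n_s)]
    meta = pd.DataFrame(
        {
            "athlete_id": athlete_ids,
            "arm": ["exercise"] * n_s,
            "occasion": ["D1pre"] * n_s,
            "batch_id": list(batch_ids),
            "injection_order": range(1, n_s + 1),
            "is_qc": list(is_qc),
        },
        index=sample_ids,
    )[SAMPLE_META_COLUMNS]
    return ProteinMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        samples=meta,
        scale=scale,
    )
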