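"""Preprocessing: rollup, batch correction, normalization, technical CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forpanel.preprocess import (
    PreprocessError, compute_technical_cv, correct_batch_effects,
    matrix_from_table, normalize_row_max, rollup_top3,
)
from forpanel.synthetic_data import NoiseModel, generate_dataset, make_archetypes, make_design
from conftest import build_matrix


def peptide_table(peptide_means: dict[str, float], n_samples: int = 4) -> pd.DataFrame:
    """One protein, one athlete; each peptide constant at its stated level."""
    rows = []
    occasions = ["D1pre", "D1post", "D2pre", "D2post"][:n_samples]
    for pep, level in peptide_means.items():
        for j, occ in enumerate(occasions):
            rows.append({
                "athlete_id": "A01", "arm": "exercise", "occasion": occ,
                "batch_id": "B01", "injection_order": j + 2, "is_qc": 0,
                "protein_id": "PROT1", "peptide_id": pep, "intensity": level,
            })
    return pd.DataFrame(rows)


class TestRollup:
    def test_exactly_three_most_abundant_peptides_contribute(self):
        table = peptide_table({"p1": 10, "p2": 8, "p3": 6, "p4": 4, "p5": 2})
        out = rollup_top3(table)
        expected = np.exp(np.mean(np.log([10.0, 8.0, 6.0])))
        assert np.allclose(out["intensity"], expected)
        assert len(out) == 4  # one record per sample

    def test_fewer_than_three_peptides_all_contribute(self):
        table = peptide_table({"p1": 10, "p2": 5})
        out = rollup_top3(table)
        assert np.allclose(out["intensity"], np.exp(np.mean(np.log([10.0, 5.0]))))

    def test_single_constant_peptide_is_identity(self):
        table = peptide_table({"only": 100.0})
        out = rollup_top3(table)
        assert np.allclose(np.log(out["intensity"]), np.log(100.0))

    def test_abundance_ties_break_lexicographically(self):
        # four peptides, two tied at the third rank: 'pa' beats 'pb'
        table = peptide_table({"p1": 10, "p2": 8, "pb": 6, "pa": 6})
        out = rollup_top3(table)
        expected = np.exp(np.mean(np.log([10.0, 8.0, 6.0])))
        assert np.allclose(out["intensity"], expected)

    @given(n_peptides=st.integers(min_value=1, max_value=6))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_top_k_is_min_of_three_and_peptide_count(self, n_peptides):
        levels = {f"p{i}": 10.0 - i for i in range(n_peptides)}
        out = rollup_top3(peptide_table(levels))
        used = sorted(levels.values(), reverse=True)[: min(3, n_peptides)]
        assert np.allclose(out["intensity"], np.exp(np.mean(np.log(used))))

    def test_requires_peptide_ids(self):
        table = peptide_table({"p1": 10})
        table["peptide_id"] = ""
        with pytest.raises(PreprocessError):
            rollup_top3(table)


class TestBatchCorrection:
    def test_pure_location_shift_removed_exactly(self):
        rng = np.random.default_rng(0)
        # shared deviation pattern: every protein has the same variance, so
        # the batch effect is homogeneous in standardized units and the EB
        # adjustment removes it exactly
        pattern = rng.normal(0, 1, size=8)
        offsets = rng.normal(10, 1, size=6)
        base = offsets[:, None] + pattern[None, :]
        delta = 0.7
        values = np.concatenate([base, base + delta], axis=1)
        m = build_matrix(values, batch_ids=["B1"] * 8 + ["B2"] * 8, is_qc=[0] * 16)
        out = correct_batch_effects(m)
        b1 = out.values.iloc[:, :8].mean(axis=1)
        b2 = out.values.iloc[:, 8:].mean(axis=1)
        assert np.allclose(b1, b2, atol=1e-8)

    def test_correction_preserves_shape(self):
        rng = np.random.default_rng(1)
        values = rng.normal(10, 1, size=(5, 12))
        m = build_matrix(values, batch_ids=["B1"] * 6 + ["B2"] * 6, is_qc=[0] * 12)
        out = correct_batch_effects(m)
        assert out.values.shape == m.values.shape
        assert list(out.values.columns) == list(m.values.columns)

    def test_single_batch_is_noop(self, caplog):
        rng = np.random.default_rng(2)
        values = rng.normal(10, 1, size=(3, 6))
        m = build_matrix(values, batch_ids=["B1"] * 6, is_qc=[0] * 6)
        with caplog.at_level("INFO"):
            out = correct_batch_effects(m)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert any("no-op" in r.message for r in caplog.records)

    def test_singleton_batch_raises_naming_the_batch(self):
        values = np.ones((2, 5)) * 10
        m = build_matrix(values, batch_ids=["B1"] * 4 + ["LONELY"], is_qc=[0] * 5)
        with pytest.raises(PreprocessError, match="LONELY"):
            correct_batch_effects(m)

    def test_between_batch_qc_variance_shrinks(self):
        """Planted batch effects: between-batch spread of QC means drops."""
        improved = 0
        for seed in range(20):
            design = make_design(6, seed=seed)
            arch = make_archetypes(0, 0, 8, seed=seed)
            noise = NoiseModel(batch_location_sd=0.4)
            table, _ = generate_dataset(design, arch, noise, seed=seed)
            m = matrix_from_table(table)
            out = correct_batch_effects(m)

            def between_batch_ms(mat):
                qc = mat.values[mat.qc_columns]
                batches = mat.samples.loc[mat.qc_columns, "batch_id"]
                means = qc.T.groupby(batches).mean()
                return float(means.var(axis=0, ddof=1).mean())

            improved += between_batch_ms(out) < between_batch_ms(m)
        assert improved >= 18


class TestRowMaxNormalization:
    def test_direct_arithmetic(self):
        m = build_matrix(np.log([[2.0, 4.0, 8.0]]), batch_ids=["B1"] * 3, is_qc=[0] * 3)
        out = normalize_row_max(m)
        assert np.allclose(out.values.to_numpy(), [[0.25, 0.5, 1.0]])
        assert out.scale == "normalized"

    def test_constant_row_becomes_ones(self):
        m = build_matrix(np.log([[3.0, 3.0, 3.0]]), batch_ids=["B1"] * 3, is_qc=[0] * 3)
        out = normalize_row_max(m)
        assert np.allclose(out.values.to_numpy(), 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = build_matrix(rng.normal(10, 1, (4, 6)), batch_ids=["B1"] * 6, is_qc=[0] * 6)
        once = normalize_row_max(m)
        twice = normalize_row_max(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_every_row_max_is_one_and_values_positive(self):
        rng = np.random.default_rng(4)
        m = build_matrix(rng.normal(8, 2, (10, 9)), batch_ids=["B1"] * 9, is_qc=[0] * 9)
        out = normalize_row_max(m)
        arr = out.values.to_numpy()
        assert np.allclose(arr.max(axis=1), 1.0)
        assert (arr > 0).all() and (arr <= 1).all()

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        base = np.array([[1.0, 2.0, 5.0]])
        m1 = build_matrix(np.log(base), batch_ids=["B1"] * 3, is_qc=[0] * 3)
        m2 = build_matrix(np.log(base * c), batch_ids=["B1"] * 3, is_qc=[0] * 3)
        np.testing.assert_allclose(
            normalize_row_max(m1).values.to_numpy(),
            normalize_row_max(m2).values.to_numpy(),
            rtol=1e-9,
        )

    def test_nonpositive_row_max_raises_with_protein_name(self):
        m = build_matrix([[0.0, 0.0, 0.0]], batch_ids=["B1"] * 3, is_qc=[0] * 3,
                         protein_ids=["BADPROT"], scale="normalized")
        with pytest.raises(PreprocessError, match="BADPROT"):
            normalize_row_max(m)


class TestTechnicalCV:
    def test_equal_qc_values_give_zero(self):
        m = build_matrix(np.log([[5.0, 5.0, 5.0, 5.0]]), batch_ids=["B1"] * 4,
                         is_qc=[1] * 4)
        cv = compute_technical_cv(m)
        assert cv.iloc[0] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = build_matrix(np.log([[90.0, 100.0, 110.0, 100.0]]),
                         batch_ids=["B1"] * 4, is_qc=[1] * 4)
        cv = compute_technical_cv(m)
        expected = np.std([90, 100, 110, 100], ddof=1) / 100.0
        assert cv.iloc[0] == pytest.approx(expected)
        assert cv.iloc[0] == pytest.approx(0.0816, abs=2e-4)

    def test_undefined_with_fewer_than_two_qc(self):
        m = build_matrix(np.log([[5.0, 6.0, 7.0]]), batch_ids=["B1"] * 3,
                         is_qc=[1, 0, 0])
        cv = compute_technical_cv(m)
        assert np.isnan(cv.iloc[0])

    def test_zscore_mode_returns_nonnegative(self):
        rng = np.random.default_rng(5)
        m = build_matrix(rng.normal(10, 0.5, (3, 10)), batch_ids=["B1"] * 10,
                         is_qc=[1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        cv = compute_technical_cv(m, mode="zscore")
        assert (cv.dropna() >= 0).all()

    def test_unknown_mode_rejected(self):
        m = build_matrix(np.log([[1.0, 2.0]]), batch_ids=["B1"] * 2, is_qc=[1, 1])
        with pytest.raises(PreprocessError):
            compute_technical_cv(m, mode="bogus")
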