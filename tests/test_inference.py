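"""Per-protein model fitting, contrasts, multiplicity, and the alpha gate."""

import numpy as np
import pandas as pd
import pytest

from forpanel.inference import (
    AlphaGate, ContrastResult, InferenceError, ModelSpec, adjust_tukey,
    analyze_matrix, cell_means_contrast, compute_contrasts, fit_protein_model,
    permutation_pvalue, select_alpha,
)
from forpanel.preprocess import preprocess_table
from forpanel.synthetic_data import (
    NoiseModel, generate_dataset, make_archetypes, make_design,
)


class TestAlphaGate:
    @pytest.mark.parametrize("cv,expected", [
        (0.20, 0.01),          # noisy protein -> strict threshold
        (0.10, 0.05),          # quiet protein -> default threshold
        (0.15, 0.05),          # boundary: 'exceeded' is a strict inequality
        (0.0, 0.05),
        (float("nan"), 0.01),  # undefined CV -> conservative
        (None, 0.01),
    ])
    def test_gate_levels(self, cv, expected):
        assert select_alpha(cv) == expected

    def test_negative_cv_rejected(self):
        with pytest.raises(InferenceError):
            select_alpha(-0.1)

    def test_gate_requires_strict_below_default(self):
        with pytest.raises(InferenceError):
            AlphaGate(alpha_strict=0.05, alpha_default=0.05)


def _study_frame(design, values_fn):
    """Build (y, samples) for one protein from a per-row value function."""
    meta = design.schedule.copy()
    meta["is_qc"] = 0
    meta.index = [f"S{i:04d}" for i in range(len(meta))]
    y = pd.Series(
        [values_fn(r) for r in meta.itertuples()], index=meta.index, dtype=float
    )
    return y, meta


class TestProteinModel:
    def test_constant_response_has_zero_contrasts(self):
        design = make_design(6, seed=1)
        y, meta = _study_frame(design, lambda r: 0.5)
        fit = fit_protein_model(y, meta)
        contrasts = compute_contrasts(fit)
        assert all(c.estimate == pytest.approx(0.0, abs=1e-12) for c in contrasts)

    def test_strong_effect_with_no_noise_is_detected(self):
        design = make_design(6, seed=1)

        def val(r):
            base = 0.5 + 0.01 * int(r.athlete_id[1:])
            if r.arm == "exercise" and r.occasion in ("D1post", "D2post", "D3post"):
                return base + 0.4
            return base

        y, meta = _study_frame(design, val)
        fit = fit_protein_model(y, meta)
        contrasts = {c.contrast_id: c for c in compute_contrasts(fit)}
        for cid in ("acute_d1", "acute_d2", "acute_d3"):
            assert contrasts[cid].estimate == pytest.approx(0.4)
            assert contrasts[cid].p_raw < 1e-6

    def test_swapping_arm_labels_flips_every_estimate(self):
        design = make_design(5, seed=2)
        rng = np.random.default_rng(0)
        vals = {}

        def val(r):
            key = (r.athlete_id, r.arm, r.occasion)
            if key not in vals:
                vals[key] = float(rng.normal(0.5, 0.1))
            return vals[key]

        y, meta = _study_frame(design, val)
        fit = fit_protein_model(y, meta)
        swapped = meta.copy()
        swapped["arm"] = swapped["arm"].map({"exercise": "rest", "rest": "exercise"})
        fit_sw = fit_protein_model(y, swapped)
        for a, b in zip(compute_contrasts(fit), compute_contrasts(fit_sw)):
            assert a.estimate == pytest.approx(-b.estimate)

    def test_estimates_invariant_to_row_order(self):
        design = make_design(4, seed=3)
        rng = np.random.default_rng(1)
        y, meta = _study_frame(design, lambda r: float(rng.normal(0.5, 0.1)))
        fit = fit_protein_model(y, meta)
        perm = rng.permutation(len(y))
        fit_p = fit_protein_model(y.iloc[perm], meta.iloc[perm])
        pd.testing.assert_series_equal(
            fit.cell_means.sort_index(), fit_p.cell_means.sort_index(), atol=1e-10
        )

    def test_requires_three_athletes(self):
        design = make_design(2, seed=1)
        y, meta = _study_frame(design, lambda r: 0.5)
        with pytest.raises(InferenceError):
            fit_protein_model(y, meta)

    def test_toy_cell_means_arithmetic(self):
        # single-athlete printed values: estimate only, no inference at n=1
        means = pd.Series({
            "exercise:D1pre": 0.5, "exercise:D1post": 0.9,
            "rest:D1pre": 0.5, "rest:D1post": 0.6,
        })
        assert cell_means_contrast(means, "acute_d1") == pytest.approx(0.3)

    def test_unbaselined_recovery_mode(self):
        means = pd.Series({
            "exercise:R1": 0.8, "rest:R1": 0.6,
            "exercise:D1pre": 0.5, "rest:D1pre": 0.5,
        })
        spec = ModelSpec(recovery_baseline="none")
        assert cell_means_contrast(means, "recovery_r1", spec) == pytest.approx(0.2)


def _mk(p_raw, estimate=1.0, se=0.1, status="ok", cid="acute_d1"):
    return ContrastResult("P", cid, estimate, se, p_raw, status=status)


class TestTukeyAdjustment:
    def test_single_estimable_family_is_unadjusted(self):
        c = [_mk(0.04), _mk(np.nan, status="not_estimable", cid="acute_d2")]
        adjust_tukey(c, df=9)
        assert c[0].p_adjusted == c[0].p_raw

    def test_ceiling_preserved(self):
        c = [_mk(1.0, estimate=0.0, se=0.1), _mk(0.5, cid="acute_d2")]
        adjust_tukey(c, df=9)
        assert c[0].p_adjusted == 1.0

    def test_strict_inflation_for_nontrivial_family(self):
        # |t| chosen so the raw two-sided p is 0.04
        from scipy import stats
        t = stats.t.ppf(1 - 0.02, 9)
        c = [_mk(0.04, estimate=t * 0.1, se=0.1),
             _mk(0.5, cid="acute_d2"), _mk(0.5, cid="acute_d3")]
        adjust_tukey(c, k_levels=16, df=9)
        assert c[0].p_adjusted > 0.04

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        c = [_mk(0.0, estimate=float(rng.normal()), se=0.1, cid=f"c{i}")
             for i in range(5)]
        for item in c:
            from scipy import stats
            item.p_raw = float(2 * stats.t.sf(abs(item.estimate / item.std_error), 9))
        adjust_tukey(c, df=9)
        assert all(x.p_adjusted >= x.p_raw for x in c)

    def test_bonferroni_mode(self):
        c = [_mk(0.01), _mk(0.5, cid="acute_d2"), _mk(0.5, cid="acute_d3"),
             _mk(0.5, cid="recovery_r1"), _mk(0.5, cid="recovery_r2")]
        adjust_tukey(c, method="bonferroni5")
        assert c[0].p_adjusted == pytest.approx(0.05)


class TestPermutationOracle:
    def test_extreme_effect_agrees_significant(self):
        design = make_design(8, seed=4)
        arch = make_archetypes(1, 0, 0, effect_size=6.0, responder_prevalence=1.0, seed=4)
        noise = NoiseModel.with_technical_cv(0.05)
        table, _ = generate_dataset(design, arch, noise, seed=4)
        matrix = preprocess_table(table)
        pid = matrix.values.index[0]
        y = matrix.values.loc[pid]
        p_perm = permutation_pvalue(y, matrix.samples, "acute_d1")
        res = analyze_matrix(matrix)
        p_model = float(
            res[(res.protein_id == pid) & (res.contrast_id == "acute_d1")].p_raw.iloc[0]
        )
        assert p_perm <= 0.05 and p_model <= 0.05

    def test_constant_data_agrees_nonsignificant(self):
        design = make_design(6, seed=5)
        meta = design.schedule.copy()
        meta["is_qc"] = 0
        meta.index = [f"S{i:04d}" for i in range(len(meta))]
        y = pd.Series(0.7, index=meta.index)
        assert permutation_pvalue(y, meta, "acute_d1") == 1.0


def test_analyze_matrix_emits_five_contrasts_per_protein(small_dataset):
    _, table, _ = small_dataset
    matrix = preprocess_table(table)
    res = analyze_matrix(matrix)
    assert set(res.groupby("protein_id").size()) == {5}
    ok = res[res.status == "ok"]
    assert ((ok.p_raw >= 0) & (ok.p_raw <= 1)).all()
    assert (ok.p_adjusted >= ok.p_raw - 1e-12).all()
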