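"""Per-protein repeated-measures inference on the crossover design.

Each protein's normalized intensities are fit with a marginal (GEE-style)
model: the 16 time-by-condition cells (8 occasions x 2 arms) enter as a
categorical predictor, athletes are the clusters, and standard errors are
cluster-robust sandwich estimates with the Mancl-DeRouen bias reduction
(10 clusters is a small-sample regime).  Five reported contrasts are
differences-of-differences of cell means:

* ``acute_dK``    = (DKpost - DKpre | exercise) - (DKpost - DKpre | rest)
* ``recovery_rK`` = (RK - D1pre | exercise) - (RK - D1pre | rest)

p-values use a t reference with ``n_clusters - 1`` degrees of freedom and
are adjusted for multiplicity with a studentized-range (Tukey) correction
over the 16-level pairwise family (Bonferroni-over-5 available as a
fallback mode).  The per-protein significance level is gated by the
technical CV: proteins whose QC replicate CV exceeds 15% are tested at
0.01, the rest at 0.05, and proteins with an undefined CV fall back to the
strict level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .preprocess import ProteinMatrix
from .synthetic_data import ARMS, OCCASIONS

logger = logging.getLogger(__name__)

CELLS: tuple[str, ...] = tuple(f"{arm}:{occ}" for arm in ARMS for occ in OCCASIONS)

#: contrast definitions as weights on time-by-condition cell means
CONTRASTS: dict[str, dict[str, float]] = {}
for _day in (1, 2, 3):
    CONTRASTS[f"acute_d{_day}"] = {
        f"exercise:D{_day}post": 1.0, f"exercise:D{_day}pre": -1.0,
        f"rest:D{_day}post": -1.0, f"rest:D{_day}pre": 1.0,
    }
for _r in (1, 2):
    CONTRASTS[f"recovery_r{_r}"] = {
        f"exercise:R{_r}": 1.0, f"exercise:D1pre": -1.0,
        f"rest:R{_r}": -1.0, f"rest:D1pre": 1.0,
    }
CONTRAST_IDS = tuple(CONTRASTS)
ACUTE_CONTRASTS = ("acute_d1", "acute_d2", "acute_d3")
RECOVERY_CONTRASTS = ("recovery_r1", "recovery_r2")


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class AlphaGate:
    """CV-gated significance threshold."""

    cv_threshold: float = 0.15
    alpha_strict: float = 0.01
    alpha_default: float = 0.05

    def __post_init__(self) -> None:
        if not self.alpha_strict < self.alpha_default:
            raise InferenceError("alpha_strict must be < alpha_default")


def select_alpha(cv: float | None, gate: AlphaGate = AlphaGate()) -> float:
    """Significance level for a protein given its technical-replicate CV.

    CV above the 15% threshold (strict inequality) selects the strict level
    0.01, otherwise 0.05; an undefined CV (None/NaN) is treated
    conservatively and also selects the strict level.
    """
    if cv is None or (isinstance(cv, float) and np.isnan(cv)):
        return gate.alpha_strict
    if cv < 0:
        raise InferenceError(f"cv must be >= 0, got {cv}")
    return gate.alpha_strict if cv > gate.cv_threshold else gate.alpha_default


@dataclass(frozen=True)
class ModelSpec:
    """Marginal-model configuration for the per-protein fit."""

    working_correlation: str = "exchangeable"   # or "independence"
    cov_type: str = "bias_reduced"              # "robust" | "bias_reduced" | "naive"
    recovery_baseline: str = "d1pre"            # or "none"


@dataclass(eq=False)
class ProteinFit:
    """Cell means and their cluster-robust covariance for one protein."""

    protein_id: str
    cell_means: pd.Series
    cov: pd.DataFrame
    n_clusters: int
    converged: bool
    df: int = field(init=False)

    def __post_init__(self) -> None:
        self.df = max(self.n_clusters - 1, 1)


@dataclass
class ContrastResult:
    protein_id: str
    contrast_id: str
    estimate: float
    std_error: float
    p_raw: float
    p_adjusted: float = np.nan
    status: str = "ok"

    @property
    def direction(self) -> int:
        return int(np.sign(self.estimate))


def contrast_weights(spec: ModelSpec = ModelSpec()) -> dict[str, dict[str, float]]:
    """The five reported contrasts, honoring the recovery-baseline mode."""
    weights = {cid: dict(w) for cid, w in CONTRASTS.items()}
    if spec.recovery_baseline == "none":
        for r in (1, 2):
            weights[f"recovery_r{r}"] = {f"exercise:R{r}": 1.0, f"rest:R{r}": -1.0}
    elif spec.recovery_baseline != "d1pre":
        raise InferenceError(f"unknown recovery baseline {spec.recovery_baseline!r}")
    return weights


def fit_protein_model(
    y: pd.Series,
    samples: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    protein_id: str = "",
) -> ProteinFit:
    """Fit the 16-cell marginal model for one protein.

    ``y`` is indexed by sample id; ``samples`` supplies athlete_id, arm,
    occasion and is_qc per sample.  QC samples are excluded.  Requires at
    least 3 athletes each contributing at least 2 occasions.
    """
    meta = samples.loc[y.index]
    study = meta["is_qc"] == 0
    y = y[study]
    meta = meta[study]
    cells = (meta["arm"] + ":" + meta["occasion"]).astype(
        pd.CategoricalDtype(categories=[c for c in CELLS], ordered=True)
    )
    present = [c for c in CELLS if (cells == c).any()]
    groups, group_labels = pd.factorize(meta["athlete_id"])
    n_clusters = len(group_labels)
    if n_clusters < 3:
        raise InferenceError("model requires at least 3 athletes")
    per_cluster = meta.groupby("athlete_id")["occasion"].count()
    if (per_cluster < 2).any():
        raise InferenceError("every athlete must contribute at least 2 samples")

    if np.ptp(y.to_numpy(dtype=float)) == 0.0:
        # degenerate constant response: every cell mean equals the constant,
        # all contrasts are exactly zero with zero sampling variance
        k = len(present)
        return ProteinFit(
            protein_id=protein_id,
            cell_means=pd.Series(float(y.iloc[0]), index=present),
            cov=pd.DataFrame(np.zeros((k, k)), index=present, columns=present),
            n_clusters=n_clusters,
            converged=True,
        )

    exog = pd.get_dummies(cells).loc[:, present].to_numpy(dtype=float)
    cov_struct = (
        sm.cov_struct.Exchangeable()
        if spec.working_correlation == "exchangeable"
        else sm.cov_struct.Independence()
    )
    model = sm.GEE(
        y.to_numpy(dtype=float), exog, groups=groups,
        family=sm.families.Gaussian(), cov_struct=cov_struct,
    )
    converged = True
    try:
        res = model.fit(maxiter=100, cov_type=spec.cov_type)
        params = res.params
        cov = res.cov_params()
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            converged = False
    except Exception:  # noqa: BLE001 - non-convergence is flagged, not fatal
        logger.warning("GEE failed to converge for protein %s", protein_id)
        converged = False
        params = np.full(len(present), np.nan)
        cov = np.full((len(present), len(present)), np.nan)
    return ProteinFit(
        protein_id=protein_id,
        cell_means=pd.Series(np.asarray(params), index=present),
        cov=pd.DataFrame(np.asarray(cov), index=present, columns=present),
        n_clusters=n_clusters,
        converged=converged,
    )


def cell_means_contrast(cell_means: pd.Series, contrast_id: str,
                        spec: ModelSpec = ModelSpec()) -> float:
    """Point estimate of a contrast from cell means alone (no inference)."""
    w = contrast_weights(spec)[contrast_id]
    missing = [c for c in w if c not in cell_means.index]
    if missing:
        raise InferenceError(f"missing cells {missing} for contrast {contrast_id}")
    return float(sum(weight * cell_means[c] for c, weight in w.items()))


def compute_contrasts(fit: ProteinFit, spec: ModelSpec = ModelSpec()) -> list[ContrastResult]:
    """The five reported difference-of-difference contrasts with sandwich SEs."""
    out: list[ContrastResult] = []
    weights = contrast_weights(spec)
    for cid in CONTRAST_IDS:
        w = weights[cid]
        if not fit.converged:
            out.append(ContrastResult(fit.protein_id, cid, np.nan, np.nan, np.nan,
                                      status="not_converged"))
            continue
        if any(c not in fit.cell_means.index for c in w):
            out.append(ContrastResult(fit.protein_id, cid, np.nan, np.nan, np.nan,
                                      status="not_estimable"))
            continue
        L = pd.Series(0.0, index=fit.cell_means.index)
        for c, weight in w.items():
            L[c] = weight
        est = float(L @ fit.cell_means)
        var = float(L @ fit.cov @ L)
        se = float(np.sqrt(var)) if var > 0 else 0.0
        if se == 0:
            p = 1.0 if est == 0 else 0.0
        else:
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df=fit.df))
        out.append(ContrastResult(fit.protein_id, cid, est, se, p))
    return out


def adjust_tukey(
    contrasts: list[ContrastResult],
    k_levels: int = 16,
    df: int | None = None,
    method: str = "tukey",
) -> list[ContrastResult]:
    """Multiplicity adjustment over the time-by-condition pairwise family.

    ``method="tukey"`` maps each contrast's t statistic onto the
    studentized-range distribution with ``k_levels`` groups
    (p = P(Q_{k,df} > |t|*sqrt(2))), the classical all-pairs correction for
    a 16-level factor; ``method="bonferroni5"`` multiplies by the number of
    reported contrasts.  A family with a single estimable member is left
    unadjusted.  Adjusted p-values never fall below the raw ones.
    """
    if method not in ("tukey", "bonferroni5"):
        raise InferenceError(f"unknown adjustment method {method!r}")
    estimable = [c for c in contrasts if c.status == "ok"]
    m = len(estimable)
    for c in contrasts:
        if c.status != "ok":
            continue
        if m == 1:
            c.p_adjusted = c.p_raw
            continue
        if method == "bonferroni5":
            c.p_adjusted = min(1.0, m * c.p_raw)
        else:
            d = df if df is not None else 2
            if c.std_error == 0:
                c.p_adjusted = c.p_raw
            else:
                t = abs(c.estimate / c.std_error)
                p = float(stats.studentized_range.sf(t * np.sqrt(2.0), k_levels, d))
                c.p_adjusted = min(1.0, max(p, c.p_raw))
    return contrasts


def analyze_protein(
    y: pd.Series,
    samples: pd.DataFrame,
    cv: float | None,
    spec: ModelSpec = ModelSpec(),
    gate: AlphaGate = AlphaGate(),
    adjust: str = "tukey",
    protein_id: str = "",
) -> tuple[list[ContrastResult], float]:
    """Fit, contrast, adjust, and gate one protein; returns (results, alpha)."""
    fit = fit_protein_model(y, samples, spec=spec, protein_id=protein_id)
    contrasts = compute_contrasts(fit, spec=spec)
    adjust_tukey(contrasts, k_levels=16, df=fit.df, method=adjust)
    alpha = select_alpha(cv, gate)
    return contrasts, alpha


def analyze_matrix(
    matrix: ProteinMatrix,
    spec: ModelSpec = ModelSpec(),
    gate: AlphaGate = AlphaGate(),
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Run the per-protein analysis over a normalized matrix.

    Returns a long DataFrame with one row per (protein, contrast):
    estimate, std_error, p_raw, p_adjusted, alpha_used, status.
    """
    cv = matrix.technical_cv
    rows = []
    for pid in matrix.values.index:
        y = matrix.values.loc[pid]
        cv_p = None if cv is None or pid not in cv.index else float(cv[pid])
        contrasts, alpha = analyze_protein(
            y, matrix.samples, cv_p, spec=spec, gate=gate, adjust=adjust, protein_id=pid
        )
        for c in contrasts:
            rows.append({
                "protein_id": pid, "contrast_id": c.contrast_id,
                "estimate": c.estimate, "std_error": c.std_error,
                "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
                "alpha_used": alpha, "status": c.status,
            })
    return pd.DataFrame(rows)


def permutation_pvalue(
    y: pd.Series,
    samples: pd.DataFrame,
    contrast_id: str = "acute_d1",
    n_permutations: int = 2000,
    seed: int = 0,
    spec: ModelSpec = ModelSpec(),
) -> float:
    """Paired permutation test of one contrast (independent oracle).

    Permutes arm labels within athlete, which flips the sign of each
    athlete's difference-of-differences; the statistic is the mean of the
    per-athlete values.  With up to 20 athletes all 2^n sign patterns are
    enumerated exactly, otherwise ``n_permutations`` random patterns are
    drawn.  Deliberately model-free: no GEE machinery is involved.
    """
    meta = samples.loc[y.index]
    study = meta["is_qc"] == 0
    y = y[study]
    meta = meta[study]
    w = contrast_weights(spec)[contrast_id]
    per_athlete = []
    for _, sub in y.groupby(meta["athlete_id"]):
        cells = meta.loc[sub.index, "arm"] + ":" + meta.loc[sub.index, "occasion"]
        vals = pd.Series(sub.to_numpy(), index=cells.to_numpy())
        if any(c not in vals.index for c in w):
            continue
        per_athlete.append(sum(weight * vals[c] for c, weight in w.items()))
    d = np.asarray(per_athlete, dtype=float)
    n = len(d)
    if n == 0:
        raise InferenceError("no athlete provides all cells of the contrast")
    observed = abs(d.mean())
    if n <= 20:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    null = np.abs(signs @ d) / n
    return float((null >= observed - 1e-12).mean())
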