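"""Statistical power simulation for the crossover design.

Monte-Carlo power of detecting a protein response as a function of cohort
size, mirroring the study's design assumptions: artificial normally
distributed data with the technical variance, cohort sizes 10-50 in steps
of 10, the effect present ("notable") in 80% of athletes, a linear mixed
model with a random athlete intercept and the 16 time-by-condition cells
as categorical fixed effects, and Bonferroni correction for a final panel
of five proteins (test level 0.05/5 = 0.01).

The effect size is expressed in units of the technical standard deviation
and is a required sweep parameter; the tested contrast defaults to the
day-1 acute response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .inference import CELLS, CONTRASTS
from .synthetic_data import ARMS, OCCASIONS

logger = logging.getLogger(__name__)


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerConfig:
    """Configuration of the power sweep (defaults mirror the study setup)."""

    n_grid: tuple[int, ...] = (10, 20, 30, 40, 50)
    n_proteins: int = 12
    responder_prevalence: float = 0.80
    panel_size_for_bonferroni: int = 5
    effect_sizes: tuple[float, ...] = (1.0,)     # shift in technical-sd units
    reps: int = 500
    seed: int = 0
    contrast_id: str = "acute_d1"
    athlete_sd_ratio: float = 2.0                # athlete intercept sd / technical sd

    def __post_init__(self) -> None:
        if not self.n_grid or any(n < 2 for n in self.n_grid):
            raise PowerError("n_grid must contain cohort sizes >= 2")
        if list(self.n_grid) != sorted(self.n_grid):
            raise PowerError("n_grid must be ascending")
        if not 0 < self.responder_prevalence <= 1:
            raise PowerError("responder_prevalence must be in (0, 1]")
        if self.reps < 1:
            raise PowerError("reps must be >= 1")
        if self.panel_size_for_bonferroni < 1:
            raise PowerError("panel size must be >= 1")
        if self.contrast_id not in CONTRASTS:
            raise PowerError(f"unknown contrast {self.contrast_id!r}")

    @property
    def alpha(self) -> float:
        return 0.05 / self.panel_size_for_bonferroni


@dataclass(eq=False)
class PowerCurve:
    """Estimated power per (cohort size, effect size)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def power_at(self, n: int, effect_size: float) -> float:
        sub = self.table[(self.table["n"] == n) & (self.table["effect_size"] == effect_size)]
        if sub.empty:
            raise KeyError((n, effect_size))
        return float(sub["power"].iloc[0])


def _cell_index() -> tuple[np.ndarray, list[str]]:
    cells = [f"{arm}:{occ}" for arm in ARMS for occ in OCCASIONS]
    return np.arange(len(cells)), cells


def _simulate_once(
    rng: np.random.Generator,
    n_athletes: int,
    effect: float,
    technical_sd: float,
    prevalence: float,
    athlete_sd: float,
    L: np.ndarray,
    exog: np.ndarray,
    affected_cols: np.ndarray,
    alpha: float,
) -> bool:
    n_cells = exog.shape[0]
    intercepts = rng.normal(0.0, athlete_sd, size=n_athletes)
    responders = rng.random(n_athletes) < prevalence
    y = np.repeat(intercepts, n_cells) + rng.normal(
        0.0, technical_sd, size=n_athletes * n_cells
    )
    if effect != 0:
        shift = effect * technical_sd
        mask = np.zeros(n_athletes * n_cells, dtype=bool)
        for i in np.flatnonzero(responders):
            mask[i * n_cells + affected_cols] = True
        y[mask] += shift
    groups = np.repeat(np.arange(n_athletes), n_cells)
    X = np.tile(exog, (n_athletes, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True, maxiter=200)
    est = float(L @ res.fe_params)
    cov = np.asarray(res.cov_params())[: len(L), : len(L)]
    se = float(np.sqrt(L @ cov @ L))
    df = n_athletes * n_cells - n_cells
    t = est / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df=df)
    return bool(p <= alpha)


def simulate_power(config: PowerConfig, technical_sd: float) -> PowerCurve:
    """Monte-Carlo power curve over the cohort-size grid.

    For each replicate and cohort size, data for one protein are generated
    as normal log-intensities (athlete random intercept + technical noise);
    responders receive a mean shift of ``effect_size * technical_sd`` at
    the tested contrast's affected cells under the exercise arm.  A linear
    mixed model (random athlete intercept, 16-cell categorical fixed
    effect) is fit and the contrast tested at the Bonferroni panel level.
    """
    if technical_sd <= 0:
        raise PowerError("technical_sd must be > 0")
    _, cells = _cell_index()
    w = CONTRASTS[config.contrast_id]
    # affected cells: the positively-weighted exercise-arm cells of the contrast
    affected_cols = np.array([
        i for i, c in enumerate(cells) if w.get(c, 0.0) > 0 and c.startswith("exercise:")
    ])
    # intercept + 15 treatment dummies: better conditioned than 16 cell
    # indicators, and equivalent for sum-zero contrasts of cell means
    n_cells = len(cells)
    exog = np.hstack([np.ones((n_cells, 1)), np.eye(n_cells)[:, 1:]])
    L = np.array([0.0] + [w.get(c, 0.0) for c in cells[1:]])
    athlete_sd = config.athlete_sd_ratio * technical_sd

    rows = []
    for effect in config.effect_sizes:
        for n in config.n_grid:
            rng = np.random.default_rng(
                (config.seed * 1_000_003 + int(round(effect * 1000)) * 101 + n) % (2**31)
            )
            hits = 0
            for _ in range(config.reps):
                hits += _simulate_once(
                    rng, n, effect, technical_sd, config.responder_prevalence,
                    athlete_sd, L, exog, affected_cols, config.alpha,
                )
            power = hits / config.reps
            rows.append({
                "n": n, "effect_size": effect, "power": power,
                "mc_se": float(np.sqrt(power * (1 - power) / config.reps)),
                "reps": config.reps,
            })
    return PowerCurve(table=pd.DataFrame(rows))


def report_power(curve: PowerCurve, out_tsv=None, out_plot=None) -> pd.DataFrame:
    """Tabulate (and optionally plot) power vs cohort size per effect size."""
    if curve.table.empty:
        raise PowerError("empty power curve")
    table = curve.table.sort_values(["effect_size", "n"], kind="stable").reset_index(drop=True)
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_plot is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for effect, sub in table.groupby("effect_size"):
            ax.errorbar(sub["n"], sub["power"], yerr=2 * sub["mc_se"],
                        marker="o", capsize=3, label=f"effect {effect:g} sd")
        ax.set_xlabel("cohort size (athletes)")
        ax.set_ylabel("power")
        ax.set_ylim(0, 1.02)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_plot, dpi=150)
        plt.close(fig)
    return table
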