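"""Quantitation-table preprocessing: rollup, batch correction, normalization.

The fixed pipeline order is: peptide-to-protein top-3 rollup, then
empirical-Bayes batch correction on the log scale, then normalization of
each protein row relative to its own maximum intensity.  The technical CV
of each protein is computed from the pooled-QC injection replicates on the
pre-normalization intensity scale (a z-score variant is provided as an
alternative mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_META_COLUMNS = ["athlete_id", "arm", "occasion", "batch_id", "injection_order", "is_qc"]


class PreprocessError(ValueError):
    pass


@dataclass(eq=False)
class ProteinMatrix:
    """Proteins x samples grid with sample metadata.

    ``scale`` is ``"log"`` (natural-log intensities, the working scale for
    rollup and batch correction) or ``"normalized"`` (intensity scale after
    row-max normalization, values in (0, 1]).  ``technical_cv`` is a
    per-protein Series (NaN where fewer than two QC observations exist).
    """

    values: pd.DataFrame                      # index: protein_id, columns: sample_id
    samples: pd.DataFrame                     # index: sample_id, SAMPLE_META_COLUMNS
    scale: str = "log"
    technical_cv: pd.Series | None = field(default=None)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            scale=self.scale,
            technical_cv=None if self.technical_cv is None else self.technical_cv.copy(),
        )

    @property
    def qc_columns(self) -> pd.Index:
        return self.samples.index[self.samples["is_qc"] == 1]

    @property
    def study_columns(self) -> pd.Index:
        return self.samples.index[self.samples["is_qc"] == 0]

    def intensity_values(self) -> pd.DataFrame:
        """Values on the raw-intensity scale regardless of internal scale."""
        return np.exp(self.values) if self.scale == "log" else self.values


def sample_key(table: pd.DataFrame) -> pd.Series:
    """Unique sample identifier for a long-format quantitation table."""
    return (
        table["batch_id"].astype(str) + "|" + table["athlete_id"].astype(str)
        + "|" + table["arm"].astype(str) + "|" + table["occasion"].astype(str)
    )


def matrix_from_table(table: pd.DataFrame) -> ProteinMatrix:
    """Pivot a protein-level long table into a log-scale ProteinMatrix."""
    t = table.copy()
    if (t["intensity"] <= 0).any():
        bad = t.index[t["intensity"] <= 0].tolist()[:5]
        raise PreprocessError(f"non-positive intensities at rows {bad}")
    t["sample_id"] = sample_key(t)
    dup = t.duplicated(["sample_id", "protein_id"])
    if dup.any():
        raise PreprocessError(
            "duplicate (sample, protein) records; run the peptide rollup first"
        )
    values = np.log(
        t.pivot(index="protein_id", columns="sample_id", values="intensity")
    )
    meta = (
        t.drop_duplicates("sample_id")
        .set_index("sample_id")[SAMPLE_META_COLUMNS]
        .loc[values.columns]
    )
    return ProteinMatrix(values=values, samples=meta, scale="log")


def rollup_top3(peptide_table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Roll peptide records up to one protein-level record per sample.

    For every protein the ``k`` (default 3) most abundant peptides — ranked
    by mean intensity across the study (non-QC) samples, ties broken
    lexicographically by peptide id — contribute; the protein quantity is
    the mean of their log intensities, reported as a geometric-mean
    intensity.  Proteins with fewer than ``k`` peptides use all of them;
    proteins with no peptide records are dropped with a warning.
    """
    t = peptide_table.copy()
    if "peptide_id" not in t.columns or t["peptide_id"].isna().all():
        raise PreprocessError("rollup requires a populated peptide_id column")
    t = t[t["peptide_id"].astype(str) != ""]
    if t.empty:
        raise PreprocessError("rollup requires a populated peptide_id column")
    if (t["intensity"] <= 0).any():
        raise PreprocessError("rollup requires strictly positive intensities")

    study = t[t["is_qc"] == 0]
    ranking_pop = study if not study.empty else t
    mean_ab = (
        ranking_pop.groupby(["protein_id", "peptide_id"])["intensity"].mean().reset_index()
    )
    # rank by descending abundance, ties broken lexicographically by peptide_id
    mean_ab = mean_ab.sort_values(
        ["protein_id", "intensity", "peptide_id"],
        ascending=[True, False, True], kind="stable",
    )
    top = mean_ab.groupby("protein_id").head(k)
    keep = set(zip(top["protein_id"], top["peptide_id"]))
    t = t[[pair in keep for pair in zip(t["protein_id"], t["peptide_id"])]].copy()

    t["log_intensity"] = np.log(t["intensity"])
    group_cols = SAMPLE_META_COLUMNS + ["protein_id"]
    agg = t.groupby(group_cols, as_index=False)["log_intensity"].mean()
    agg["intensity"] = np.exp(agg["log_intensity"])
    agg["peptide_id"] = ""
    out = agg[
        ["athlete_id", "arm", "occasion", "batch_id", "injection_order",
         "is_qc", "protein_id", "peptide_id", "intensity"]
    ].sort_values(["protein_id", "batch_id", "injection_order"], kind="stable")
    return out.reset_index(drop=True)


def _eb_shrink_batch_params(gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
                            counts: np.ndarray, z: np.ndarray,
                            batch_codes: np.ndarray,
                            tol: float = 1e-6, max_iter: int = 200
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes shrinkage of per-batch location/scale (parametric).

    ``gamma_hat``/``delta_hat_sq``: (n_proteins, n_batches) moment estimates
    on standardized data; shrunk toward their across-protein means using a
    normal prior for locations and an inverse-gamma prior for variances,
    solved by the usual fixed-point iteration.
    """
    n_p, n_b = gamma_hat.shape
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat_sq.copy()
    for b in range(n_b):
        g = gamma_hat[:, b]
        d = delta_hat_sq[:, b]
        n_g = counts[b]
        gbar = g.mean()
        tau2 = g.var(ddof=1) if n_p > 1 else 0.0
        m = d.mean()
        s2 = d.var(ddof=1) if n_p > 1 else 0.0
        if tau2 <= 0 and s2 <= 0:
            # no across-protein heterogeneity to shrink toward: keep moments
            gamma_star[:, b] = gbar
            delta_star[:, b] = d
            continue
        lam = (2 * s2 + m**2) / s2 if s2 > 0 else np.inf
        theta = (m * s2 + m**3) / s2 if s2 > 0 else 0.0
        zb = z[:, batch_codes == b]
        g_new, d_new = g.copy(), d.copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            if tau2 > 0:
                g_new = (n_g * tau2 * g + d_new * gbar) / (n_g * tau2 + d_new)
            else:
                g_new = np.full(n_p, gbar)
            if np.isfinite(lam):
                sse = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sse) / (n_g / 2 + lam - 1)
            change = max(
                np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
            )
            if change < tol:
                break
        gamma_star[:, b] = g_new
        delta_star[:, b] = d_new
    return gamma_star, delta_star


def correct_batch_effects(matrix: ProteinMatrix) -> ProteinMatrix:
    """Remove per-batch location/scale effects on the log scale (EB).

    Per protein and batch, batch means and variances of standardized data
    are estimated, shrunk across proteins by empirical Bayes, and removed so
    every batch is adjusted toward the across-batch grand distribution.  QC
    samples participate in estimation and are retained.  A single-batch
    matrix is returned unchanged; a batch with fewer than two samples is an
    error.
    """
    if matrix.scale != "log":
        raise PreprocessError("batch correction operates on the log scale")
    batches = matrix.samples["batch_id"]
    uniq = batches.unique()
    if len(uniq) < 2:
        logger.info("single batch %s: batch correction is a no-op", uniq.tolist())
        return matrix.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise PreprocessError(
            f"batch(es) with a single sample cannot be corrected: {small.index.tolist()}"
        )

    x = matrix.values.to_numpy(dtype=float)
    codes, uniques = pd.factorize(batches.loc[matrix.values.columns])
    n_b = len(uniques)
    n_counts = np.array([(codes == b).sum() for b in range(n_b)], dtype=float)

    batch_means = np.stack([x[:, codes == b].mean(axis=1) for b in range(n_b)], axis=1)
    grand = batch_means @ (n_counts / n_counts.sum())
    resid = x - batch_means[:, codes]
    pooled_var = (resid**2).sum(axis=1) / (x.shape[1] - n_b)
    pooled_sd = np.sqrt(pooled_var)
    pooled_sd[pooled_sd == 0] = 1.0  # constant rows pass through unchanged

    z = (x - grand[:, None]) / pooled_sd[:, None]
    gamma_hat = np.stack([z[:, codes == b].mean(axis=1) for b in range(n_b)], axis=1)
    delta_hat = np.stack(
        [z[:, codes == b].var(axis=1, ddof=1) for b in range(n_b)], axis=1
    )
    gamma_star, delta_star = _eb_shrink_batch_params(
        gamma_hat, delta_hat, n_counts, z, codes
    )
    denom = np.sqrt(np.where(delta_star > 0, delta_star, 1.0))
    z_adj = (z - gamma_star[:, codes]) / denom[:, codes]
    x_adj = z_adj * pooled_sd[:, None] + grand[:, None]

    out = matrix.copy()
    out.values = pd.DataFrame(x_adj, index=matrix.values.index, columns=matrix.values.columns)
    return out


def normalize_row_max(matrix: ProteinMatrix) -> ProteinMatrix:
    """Divide each protein row by its own maximum on the intensity scale.

    After normalization every row has maximum exactly 1 and all values lie
    in (0, 1].  Idempotent; raises naming the protein if a row's maximum is
    not strictly positive.
    """
    vals = matrix.intensity_values()
    arr = vals.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise PreprocessError("non-finite values before row-max normalization")
    row_max = arr.max(axis=1)
    bad = vals.index[row_max <= 0]
    if len(bad):
        raise PreprocessError(f"non-positive row maximum for protein(s) {bad.tolist()}")
    out = matrix.copy()
    out.values = vals.div(pd.Series(row_max, index=vals.index), axis=0)
    out.scale = "normalized"
    return out


def compute_technical_cv(matrix: ProteinMatrix, mode: str = "raw") -> pd.Series:
    """Per-protein technical CV from the pooled-QC injection replicates.

    ``mode="raw"`` (default): intra-batch CV — within each batch holding at
    least two QC injections, sd/mean of the QC intensities on the
    pre-normalization intensity scale, summarized as the median across
    batches.  The intra-batch computation isolates injection-level noise
    from batch (= athlete) location differences, which in this design are
    confounded with biology.  ``mode="zscore"``: z-score each protein
    across all samples, then sd/|mean| of the pooled QC z-scores — an
    alternative reading that is unstable when the QC mean z is near zero.
    Proteins with fewer than two QC observations get NaN (callers treat
    that conservatively).
    """
    if mode not in ("raw", "zscore"):
        raise PreprocessError(f"unknown CV mode {mode!r}")
    qc_cols = matrix.qc_columns
    intens = matrix.intensity_values()
    n_qc = len(qc_cols)
    out = pd.Series(np.nan, index=intens.index, name="technical_cv")
    if n_qc >= 2:
        if mode == "raw":
            qc = intens[qc_cols]
            batches = matrix.samples.loc[qc_cols, "batch_id"]
            per_batch = []
            for _, cols in qc.T.groupby(batches, sort=True):
                if len(cols) >= 2:
                    per_batch.append(cols.std(axis=0, ddof=1) / cols.mean(axis=0))
            if per_batch:
                out = pd.concat(per_batch, axis=1).median(axis=1)
        else:
            mu = intens.mean(axis=1)
            sd = intens.std(axis=1, ddof=1)
            z = intens.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
            zqc = z[qc_cols]
            out = zqc.std(axis=1, ddof=1) / zqc.mean(axis=1).abs()
        out.name = "technical_cv"
    else:
        logger.warning("fewer than 2 QC records: technical CV undefined for all proteins")
    return out


def preprocess_table(
    table: pd.DataFrame,
    cv_mode: str = "raw",
    batch_correction: bool = True,
) -> ProteinMatrix:
    """Full preprocessing chain: rollup (if peptide-level) -> batch
    correction -> technical CV -> row-max normalization."""
    has_peptides = (
        "peptide_id" in table.columns
        and table["peptide_id"].astype(str).str.len().gt(0).any()
    )
    protein_table = rollup_top3(table) if has_peptides else table
    matrix = matrix_from_table(protein_table)
    if batch_correction:
        matrix = correct_batch_effects(matrix)
    cv = compute_technical_cv(matrix, mode=cv_mode)
    matrix = normalize_row_max(matrix)
    matrix.technical_cv = cv
    return matrix
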