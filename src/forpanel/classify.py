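"""Temporal-pattern classification of proteins into biomarker clusters.

A protein is *significant positive* on a contrast when its adjusted
p-value is at or below the (CV-gated) significance level and the estimate
is positive.  Labels:

``acute_sustained``
    significant positive acutely (post vs pre, exercise vs rest) on all
    three exercise days;
``acute_day1``
    significant positive acutely on day 1 (but not sustained);
``chronic_FOR``
    elevated on recovery morning 1 and/or 2 (exercise vs rest) while not
    responding acutely — the functional-overreaching candidate cluster;
``none``
    everything else.

Two rule modes resolve the acute-exclusion wording for the chronic
cluster: ``strict`` (default) requires no acute contrast significant in
either direction; ``lenient`` tolerates at most one acute contrast
significant positive.  Acute and chronic labels are mutually exclusive:
``acute_sustained`` always wins, and a protein elevated on two or more
exercise days is never ``chronic_FOR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .inference import ACUTE_CONTRASTS, RECOVERY_CONTRASTS, ContrastResult

LABELS = ("acute_day1", "acute_sustained", "chronic_FOR", "none")

#: annotation columns mirroring the published selection flow's subjective
#: narrowing criteria; always emitted empty, for manual curation.
ANNOTATION_COLUMNS = ("graphical_pattern", "literature_support", "biological_plausibility")


class ClassifyError(ValueError):
    pass


@dataclass
class ProteinClassification:
    protein_id: str
    label: str
    alpha_used: float
    rule_mode: str
    evidence: dict[str, dict] = field(default_factory=dict)
    status: str = "ok"


def _evidence(contrasts: list[ContrastResult], alpha: float,
              use_adjusted: bool) -> dict[str, dict]:
    ev = {}
    for c in contrasts:
        ok = c.status == "ok"
        p = c.p_adjusted if use_adjusted else c.p_raw
        sig = bool(ok and p <= alpha)
        ev[c.contrast_id] = {
            "estimate": c.estimate,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adjusted,
            "significant": sig,
            "positive": sig and c.estimate > 0,
            "negative": sig and c.estimate < 0,
            "status": c.status,
        }
    return ev


def classify_protein(
    contrasts: list[ContrastResult],
    alpha: float,
    mode: str = "strict",
    use_adjusted: bool = False,
) -> ProteinClassification:
    """Assign one protein's cluster label from its five contrasts.

    Significance of each contrast is judged on its own p-value against the
    CV-gated level ``alpha`` (the reported contrasts are single planned
    differences-of-differences, not members of the all-pairs family);
    ``use_adjusted=True`` switches to the family-adjusted p-values instead.
    """
    if not 0 < alpha < 1:
        raise ClassifyError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in ("strict", "lenient"):
        raise ClassifyError(f"unknown rule mode {mode!r}")
    pid = contrasts[0].protein_id if contrasts else ""
    ev = _evidence(contrasts, alpha, use_adjusted)
    needed = set(ACUTE_CONTRASTS) | set(RECOVERY_CONTRASTS)
    flagged = [cid for cid in needed
               if cid not in ev or ev[cid]["status"] != "ok"]
    if flagged:
        return ProteinClassification(
            pid, "none", alpha, mode, ev, status="incomplete_evidence"
        )

    acute_pos = [ev[c]["positive"] for c in ACUTE_CONTRASTS]
    acute_any = [ev[c]["significant"] for c in ACUTE_CONTRASTS]
    recovery_pos = [ev[c]["positive"] for c in RECOVERY_CONTRASTS]

    if all(acute_pos):
        label = "acute_sustained"
    else:
        if mode == "strict":
            chronic_ok = not any(acute_any)
        else:
            chronic_ok = sum(acute_pos) <= 1
        if any(recovery_pos) and chronic_ok:
            label = "chronic_FOR"
        elif acute_pos[0]:
            label = "acute_day1"
        else:
            label = "none"
    return ProteinClassification(pid, label, alpha, mode, ev)


def summarize_clusters(
    classifications: list[ProteinClassification],
) -> tuple[dict[str, int], pd.DataFrame]:
    """Counts per label and a per-protein table sorted by label then id.

    The table carries empty annotation columns for the manual narrowing
    criteria (graphical pattern, literature support, biological
    plausibility) that are not automated here.
    """
    counts = {label: 0 for label in LABELS}
    rows = []
    for c in classifications:
        counts[c.label] = counts.get(c.label, 0) + 1
        row = {
            "protein_id": c.protein_id,
            "label": c.label,
            "alpha_used": c.alpha_used,
            "rule_mode": c.rule_mode,
            "status": c.status,
        }
        for cid, e in c.evidence.items():
            row[f"{cid}_significant"] = e["significant"]
            row[f"{cid}_direction"] = (
                0 if not e["significant"] else (1 if e["estimate"] > 0 else -1)
            )
        for col in ANNOTATION_COLUMNS:
            row[col] = ""
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["label", "protein_id"], kind="stable").reset_index(drop=True)
    return counts, table


def classify_results(
    results: pd.DataFrame,
    mode: str = "strict",
    use_adjusted: bool = False,
) -> list[ProteinClassification]:
    """Classify every protein in an ``analyze_matrix`` result frame."""
    out = []
    for pid, sub in results.groupby("protein_id", sort=True):
        contrasts = [
            ContrastResult(
                protein_id=pid,
                contrast_id=r["contrast_id"],
                estimate=r["estimate"],
                std_error=r["std_error"],
                p_raw=r["p_raw"],
                p_adjusted=r["p_adjusted"],
                status=r["status"],
            )
            for _, r in sub.iterrows()
        ]
        alpha = float(sub["alpha_used"].iloc[0])
        out.append(classify_protein(contrasts, alpha, mode=mode, use_adjusted=use_adjusted))
    return out
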