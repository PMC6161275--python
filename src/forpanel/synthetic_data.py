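"""Synthetic dried-blood-spot proteomics data with a known ground truth.

Emulates a randomized, counterbalanced crossover study in which every
athlete completes a 3-day exercise overload arm and a 3-day rest arm, each
sampled pre and post on the three days plus two recovery mornings
(8 occasions per arm, 16 study samples per athlete).  Each athlete's 16
samples form one mass-spectrometry batch, monitored by four injections of a
pooled quality-control (QC) sample: one before the batch, one after, and two
interior.

Proteins are planted with one of three temporal response archetypes:

``acute``
    up-regulated immediately post-exercise on each of the three exercise
    days (D1post, D2post, D3post under the exercise arm);
``chronic``
    unchanged acutely but elevated on the recovery mornings (R1 and/or R2
    under the exercise arm) — the functional-overreaching signature;
``null``
    no condition-dependent signal.

Effects are multiplicative fold-changes present in a configurable fraction
of athletes (the responder prevalence, default 0.8).  Intensities are
generated lognormal: normal on the log scale with a per-protein baseline,
an athlete random effect, per-batch location/scale perturbations, and
technical (injection-level) noise calibrated to a target technical CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS: tuple[str, str] = ("exercise", "rest")
OCCASIONS: tuple[str, ...] = (
    "D1pre", "D1post", "D2pre", "D2post", "D3pre", "D3post", "R1", "R2",
)
ACUTE_OCCASIONS: tuple[str, ...] = ("D1post", "D2post", "D3post")
RECOVERY_OCCASIONS: tuple[str, ...] = ("R1", "R2")

#: injection slots of the four pooled-QC runs within a 20-injection batch
#: (before all study samples, two interior, after all study samples).
QC_SLOTS: tuple[int, int, int, int] = (1, 8, 14, 20)

N_INJECTIONS_PER_BATCH = 16 + len(QC_SLOTS)


class DesignError(ValueError):
    """Raised when a study design or generator input is invalid."""


@dataclass(eq=False)
class StudyDesign:
    """Crossover sampling schedule plus MS batch/QC layout.

    ``schedule`` holds one row per study sample (athlete, arm, occasion,
    batch_id, injection_order); ``qc_schedule`` one row per pooled-QC
    injection (batch_id, qc_rep, injection_order).
    """

    n_athletes: int
    athletes: tuple[str, ...]
    arm_order: dict[str, str]            # athlete -> "exercise_first" | "rest_first"
    batch_of: dict[str, str]             # athlete -> batch id
    schedule: pd.DataFrame
    qc_schedule: pd.DataFrame
    arms: tuple[str, str] = ARMS
    occasions: tuple[str, ...] = OCCASIONS
    qc_positions_per_batch: tuple[int, ...] = QC_SLOTS

    def validate(self) -> None:
        if self.n_athletes < 1:
            raise DesignError("design must contain at least one athlete")
        per_athlete = self.schedule.groupby("athlete_id").size()
        if not (per_athlete == 16).all():
            raise DesignError("every athlete must have exactly 16 study samples")
        n_first = sum(v == "exercise_first" for v in self.arm_order.values())
        n_second = self.n_athletes - n_first
        if abs(n_first - n_second) > 1:
            raise DesignError("arm order is not counterbalanced")
        if len(set(self.batch_of.values())) != self.n_athletes:
            raise DesignError("expected exactly one batch per athlete")
        per_batch_qc = self.qc_schedule.groupby("batch_id").size()
        if not (per_batch_qc == 4).all():
            raise DesignError("every batch must have exactly 4 QC injections")
        for athlete in self.athletes:
            sub = self.schedule[self.schedule["athlete_id"] == athlete]
            for arm in self.arms:
                occ = sub.loc[sub["arm"] == arm, "occasion"]
                if sorted(occ) != sorted(self.occasions):
                    raise DesignError(
                        f"athlete {athlete}, arm {arm}: occasions not unique/complete"
                    )

    @property
    def batches(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.batch_of.values()))


def make_design(n_athletes: int, seed: int) -> StudyDesign:
    """Build the crossover design for ``n_athletes``.

    Arm order (exercise-first vs rest-first) is assigned counterbalanced and
    shuffled by ``seed``; within each batch the 16 study injections are
    randomized over the non-QC slots.
    """
    if n_athletes < 1:
        raise DesignError(f"n_athletes must be >= 1, got {n_athletes}")
    rng = np.random.default_rng(seed)
    athletes = tuple(f"A{i + 1:02d}" for i in range(n_athletes))
    batches = tuple(f"B{i + 1:02d}" for i in range(n_athletes))
    batch_of = dict(zip(athletes, batches))

    orders = ["exercise_first"] * ((n_athletes + 1) // 2)
    orders += ["rest_first"] * (n_athletes - len(orders))
    rng.shuffle(orders)
    arm_order = dict(zip(athletes, orders))

    study_slots = [s for s in range(1, N_INJECTIONS_PER_BATCH + 1) if s not in QC_SLOTS]
    rows = []
    qc_rows = []
    for athlete, batch in batch_of.items():
        pairs = [(arm, occ) for arm in ARMS for occ in OCCASIONS]
        slots = rng.permutation(study_slots)
        for (arm, occ), slot in zip(pairs, slots):
            rows.append((athlete, arm, occ, batch, int(slot)))
        for k, slot in enumerate(QC_SLOTS, start=1):
            qc_rows.append((batch, k, slot))
    schedule = pd.DataFrame(
        rows, columns=["athlete_id", "arm", "occasion", "batch_id", "injection_order"]
    )
    qc_schedule = pd.DataFrame(qc_rows, columns=["batch_id", "qc_rep", "injection_order"])
    design = StudyDesign(
        n_athletes=n_athletes,
        athletes=athletes,
        arm_order=arm_order,
        batch_of=batch_of,
        schedule=schedule,
        qc_schedule=qc_schedule,
    )
    design.validate()
    return design


@dataclass(frozen=True)
class ProteinArchetype:
    """Planted temporal response class of one protein."""

    protein_id: str
    klass: str                            # "acute" | "chronic" | "null"
    effect_size: float                    # multiplicative fold-change, > 0
    responder_prevalence: float = 0.8
    affected_occasions: tuple[str, ...] = ()
    technical_cv_target: float = 0.10

    def __post_init__(self) -> None:
        if self.klass not in ("acute", "chronic", "null"):
            raise DesignError(f"unknown archetype class {self.klass!r}")
        if self.effect_size <= 0:
            raise DesignError("effect_size must be > 0")
        if self.klass == "null" and self.effect_size != 1.0:
            raise DesignError("null archetypes must have effect_size 1")
        if not 0 < self.responder_prevalence <= 1:
            raise DesignError("responder_prevalence must be in (0, 1]")
        bad = set(self.affected_occasions) - set(OCCASIONS)
        if bad:
            raise DesignError(f"unknown occasions {sorted(bad)}")


def make_archetypes(
    n_acute: int,
    n_chronic: int,
    n_null: int,
    effect_size: float = 2.0,
    responder_prevalence: float = 0.8,
    technical_cv_target: float = 0.10,
    chronic_occasions: tuple[str, ...] = RECOVERY_OCCASIONS,
    seed: int = 0,
) -> list[ProteinArchetype]:
    """Build a protein panel of planted acute / chronic / null archetypes.

    Acute archetypes affect D1post, D2post, D3post (exercise arm only);
    chronic archetypes affect ``chronic_occasions`` (default both recovery
    mornings); null archetypes have fold-change fixed at 1.
    """
    for name, n in (("n_acute", n_acute), ("n_chronic", n_chronic), ("n_null", n_null)):
        if n < 0:
            raise DesignError(f"{name} must be >= 0, got {n}")
    if not set(chronic_occasions) <= set(RECOVERY_OCCASIONS) or not chronic_occasions:
        raise DesignError("chronic_occasions must be a nonempty subset of R1/R2")
    del seed  # protein identity is deterministic; kept for interface stability
    archetypes: list[ProteinArchetype] = []
    i = 0
    for _ in range(n_acute):
        i += 1
        archetypes.append(ProteinArchetype(
            protein_id=f"P{i:04d}", klass="acute", effect_size=effect_size,
            responder_prevalence=responder_prevalence,
            affected_occasions=ACUTE_OCCASIONS,
            technical_cv_target=technical_cv_target,
        ))
    for _ in range(n_chronic):
        i += 1
        archetypes.append(ProteinArchetype(
            protein_id=f"P{i:04d}", klass="chronic", effect_size=effect_size,
            responder_prevalence=responder_prevalence,
            affected_occasions=tuple(chronic_occasions),
            technical_cv_target=technical_cv_target,
        ))
    for _ in range(n_null):
        i += 1
        archetypes.append(ProteinArchetype(
            protein_id=f"P{i:04d}", klass="null", effect_size=1.0,
            responder_prevalence=responder_prevalence,
            affected_occasions=(),
            technical_cv_target=technical_cv_target,
        ))
    return archetypes


def technical_sd_for_cv(cv: float) -> float:
    """Log-scale SD giving a lognormal coefficient of variation of ``cv``.

    For lognormal intensities CV = sqrt(exp(sigma^2) - 1), inverted here.
    """
    if cv < 0:
        raise DesignError("cv must be >= 0")
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class NoiseModel:
    """Variance components of the generator, all on the natural-log scale.

    Defaults emulate plausible DBS proteomics variability: ~30%
    between-athlete biological variation, ~20% batch location shifts, mild
    batch-to-batch scale drift, and technical noise calibrated to a 10%
    injection-replicate CV.
    """

    baseline_log_mean: float = 14.0
    baseline_log_sd: float = 1.0
    athlete_random_effect_sd: float = 0.3
    batch_location_sd: float = 0.2
    batch_scale_sd: float = 0.1
    technical_sd: float = technical_sd_for_cv(0.10)

    def __post_init__(self) -> None:
        for name in ("baseline_log_sd", "athlete_random_effect_sd",
                     "batch_location_sd", "batch_scale_sd", "technical_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")

    @classmethod
    def with_technical_cv(cls, cv: float, **kwargs) -> "NoiseModel":
        return cls(technical_sd=technical_sd_for_cv(cv), **kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: what was planted where, per protein."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    def klass_of(self, protein_id: str) -> str:
        row = self.records.loc[self.records["protein_id"] == protein_id]
        if row.empty:
            raise KeyError(protein_id)
        return str(row["klass"].iloc[0])


QUANT_COLUMNS = [
    "athlete_id", "arm", "occasion", "batch_id", "injection_order",
    "is_qc", "protein_id", "peptide_id", "intensity",
]


def generate_dataset(
    design: StudyDesign,
    archetypes: list[ProteinArchetype],
    noise: NoiseModel,
    seed: int,
    missing_rate: float = 0.0,
    peptides_per_protein: int = 1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a long-format quantitation table and its truth ledger.

    Study-sample log intensity is baseline + athlete effect + planted effect
    (responders only, affected occasions only) + batch location, with batch-
    scaled technical noise.  QC injections share the pooled per-protein
    baseline and differ only by batch effects and technical noise.  With
    ``peptides_per_protein > 1`` each protein's signal is emitted on several
    peptides with fixed per-peptide abundance offsets and independent
    technical noise (exercising the top-3 rollup).
    """
    design.validate()
    if not 0 <= missing_rate < 1:
        raise DesignError("missing_rate must be in [0, 1)")
    if peptides_per_protein < 1:
        raise DesignError("peptides_per_protein must be >= 1")
    ids = [a.protein_id for a in archetypes]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate protein_id in archetypes")

    rng = np.random.default_rng(seed)
    n_p = len(archetypes)
    n_a = design.n_athletes
    batches = list(design.batches)
    n_b = len(batches)
    athlete_idx = {a: i for i, a in enumerate(design.athletes)}
    batch_idx = {b: i for i, b in enumerate(batches)}

    # sample frame: study rows then QC rows
    study = design.schedule.copy()
    study["is_qc"] = 0
    qc = design.qc_schedule.copy()
    qc["athlete_id"] = "POOL"
    qc["arm"] = "QC"
    qc["occasion"] = "QC" + qc["qc_rep"].astype(str)
    qc["is_qc"] = 1
    samples = pd.concat(
        [study[["athlete_id", "arm", "occasion", "batch_id", "injection_order", "is_qc"]],
         qc[["athlete_id", "arm", "occasion", "batch_id", "injection_order", "is_qc"]]],
        ignore_index=True,
    )
    n_s = len(samples)
    s_batch = samples["batch_id"].map(batch_idx).to_numpy()
    s_is_qc = samples["is_qc"].to_numpy(dtype=bool)
    s_athlete = np.where(
        s_is_qc, 0, samples["athlete_id"].map(athlete_idx).fillna(0).astype(int)
    )

    mu = rng.normal(noise.baseline_log_mean, noise.baseline_log_sd, size=n_p)
    athlete_eff = rng.normal(0.0, noise.athlete_random_effect_sd, size=(n_p, n_a))
    batch_loc = rng.normal(0.0, noise.batch_location_sd, size=(n_p, n_b))
    batch_scale = np.exp(rng.normal(0.0, noise.batch_scale_sd, size=(n_p, n_b)))

    responders = np.zeros((n_p, n_a), dtype=bool)
    affected = np.zeros((n_p, n_s), dtype=bool)
    key = (samples["arm"] + ":" + samples["occasion"]).to_numpy()
    truth_rows = []
    for p, arch in enumerate(archetypes):
        resp = rng.random(n_a) < arch.responder_prevalence
        responders[p] = resp
        targets = {f"exercise:{occ}" for occ in arch.affected_occasions}
        if targets:
            affected[p] = np.isin(key, list(targets))
        truth_rows.append({
            "protein_id": arch.protein_id,
            "klass": arch.klass,
            "effect_size": arch.effect_size,
            "responders": ";".join(a for a, r in zip(design.athletes, resp) if r),
            "affected_occasions": ";".join(arch.affected_occasions),
        })
    log_effect = np.log([a.effect_size for a in archetypes])

    base = (
        mu[:, None]
        + np.where(s_is_qc[None, :], 0.0, athlete_eff[:, s_athlete])
        + batch_loc[:, s_batch]
        + np.where(affected & responders[:, s_athlete] & ~s_is_qc[None, :],
                   log_effect[:, None], 0.0)
    )

    frames = []
    for k in range(peptides_per_protein):
        if peptides_per_protein == 1:
            pep_offset = np.zeros(n_p)
            pep_ids = [""] * n_p
        else:
            pep_offset = rng.normal(0.0, 0.5, size=n_p)
            pep_ids = [f"{pid}_pep{k + 1}" for pid in ids]
        eps = rng.standard_normal((n_p, n_s))
        log_i = base + pep_offset[:, None] + batch_scale[:, s_batch] * noise.technical_sd * eps
        wide = pd.DataFrame(np.exp(log_i), index=ids, columns=range(n_s))
        long = wide.stack().rename("intensity").reset_index()
        long.columns = ["protein_id", "sample_idx", "intensity"]
        long["peptide_id"] = long["protein_id"].map(dict(zip(ids, pep_ids)))
        frames.append(long)
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(
        samples.reset_index(names="sample_idx"), on="sample_idx", how="left"
    ).drop(columns="sample_idx")
    table = table[QUANT_COLUMNS].sort_values(
        ["protein_id", "peptide_id", "batch_id", "injection_order"], kind="stable"
    ).reset_index(drop=True)

    if missing_rate > 0:
        keep = rng.random(len(table)) >= missing_rate
        keep |= table["is_qc"].to_numpy(dtype=bool)  # QC records always kept
        n_drop = int((~keep).sum())
        logger.info("dropping %d study records at missing_rate=%.3g", n_drop, missing_rate)
        table = table[keep].reset_index(drop=True)

    truth = SyntheticTruth(records=pd.DataFrame(truth_rows))
    return table, truth
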