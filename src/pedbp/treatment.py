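"""Hypertension diagnosis, antihypertensive medication with a CYP3A43
nonresponse interaction, and smoking dynamics.

Hypertension is SBP > 140 mmHg, DBP > 90 mmHg (strict), or current
medication use.  Diagnosis is made on raw (pre-medication) pressures at
each exam; individuals treated at exam 1 keep their affection status and
their treatment at later exams regardless of subsequent values.  Treated
responders have 6.2/7.9 mmHg subtracted from observed SBP/DBP; carriers
of a deleterious CYP3A43 coding variant are nonresponders whose pressures
are unchanged by treatment.

The fraction of hypertensives on medication rises across exams
(0.55, 0.67, 0.82).  By default the incident treatment probability at
exams 2-3 is solved from the realized carry-over so the *marginal*
treated fraction among current hypertensives tracks those targets; a
simpler per-exam Bernoulli variant is available.

Smoking starts at 22.9% prevalence; each smoker quits with probability
1.45% at each later exam, never resumes, and smoking has no effect on
any trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentParams",
    "diagnose_hypertension",
    "is_nonresponder",
    "assign_medication",
    "apply_medication",
    "persist_diagnosis",
    "simulate_smoking",
]


@dataclass(frozen=True)
class TreatmentParams:
    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    med_effect_sbp: float = 6.2  # mmHg subtracted in treated responders
    med_effect_dbp: float = 7.9
    treat_prob_by_exam: tuple[float, float, float] = (0.55, 0.67, 0.82)
    smoker_init: float = 0.229
    quit_rate: float = 0.0145
    carrier_dosage_cutoff: float = 0.5
    marginal_treatment_matching: bool = True

    def __post_init__(self):
        for p in (*self.treat_prob_by_exam, self.smoker_init, self.quit_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.med_effect_sbp < 0 or self.med_effect_dbp < 0:
            raise ValueError("medication effects must be nonnegative")


def diagnose_hypertension(sbp, dbp, on_meds, params: TreatmentParams = TreatmentParams()):
    """Hypertension flag: SBP > 140, DBP > 90 (strict), or medication use."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    out = (sbp > params.sbp_threshold) | (dbp > params.dbp_threshold) | np.asarray(on_meds, dtype=bool)
    return bool(out) if out.ndim == 0 else out


def is_nonresponder(dosages, cutoff: float = 0.5):
    """Medication nonresponse: carries any deleterious CYP3A43 variant,
    i.e. any of the three interaction dosages >= ``cutoff`` (for integer
    dosages: at least one minor allele).

    ``dosages`` is an array-like of shape (..., n_variants); NaN raises.
    """
    arr = np.asarray(dosages, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing interaction-variant dosage")
    out = (arr >= cutoff).any(axis=-1)
    return bool(out) if out.ndim == 0 else out


def assign_medication(
    exam: int,
    hypertensive: np.ndarray,
    previously_treated: np.ndarray,
    params: TreatmentParams = TreatmentParams(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Treatment flags at ``exam`` (1-based).

    Previously treated individuals remain treated.  Untreated current
    hypertensives start treatment with a probability chosen so that the
    treated fraction among hypertensives tracks the per-exam target
    (or, with ``marginal_treatment_matching=False``, simply the target
    itself).  Never-hypertensive, never-treated individuals stay
    untreated.
    """
    if exam not in (1, 2, 3):
        raise ValueError("exam must be 1, 2 or 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hypertensive = np.asarray(hypertensive, dtype=bool)
    previously_treated = np.asarray(previously_treated, dtype=bool)
    target = params.treat_prob_by_exam[exam - 1]
    eligible = hypertensive & ~previously_treated
    if params.marginal_treatment_matching:
        n_htn = int(hypertensive.sum())
        n_prev = int((hypertensive & previously_treated).sum())
        n_elig = int(eligible.sum())
        if n_elig == 0 or n_htn == 0:
            q = 0.0
        else:
            q = np.clip((target * n_htn - n_prev) / n_elig, 0.0, 1.0)
    else:
        q = target
    incident = eligible & (rng.random(hypertensive.shape) < q)
    return previously_treated | incident


def apply_medication(
    sbp, dbp, treated, nonresponder, params: TreatmentParams = TreatmentParams()
):
    """Observed pressures after treatment: treated responders have
    (6.2, 7.9) mmHg subtracted from (SBP, DBP); everyone else unchanged."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    effective = np.asarray(treated, dtype=bool) & ~np.asarray(nonresponder, dtype=bool)
    out_s = sbp - np.where(effective, params.med_effect_sbp, 0.0)
    out_d = dbp - np.where(effective, params.med_effect_dbp, 0.0)
    if out_s.ndim == 0:
        return float(out_s), float(out_d)
    return out_s, out_d


def persist_diagnosis(
    raw_sbp: pd.DataFrame,
    raw_dbp: pd.DataFrame,
    treated: pd.DataFrame,
    params: TreatmentParams = TreatmentParams(),
) -> pd.DataFrame:
    """Per-exam hypertension flags from raw pressures and treatment.

    Inputs are person x exam frames (columns ``e1..e3``).  An individual
    treated at exam 1 is flagged at every exam; otherwise the flag at an
    exam is the raw-value threshold rule or current medication use.
    Untreated individuals can revert to unaffected at a later exam.
    """
    out = {}
    treated_e1 = treated["e1"].to_numpy(dtype=bool)
    for e in (1, 2, 3):
        base = diagnose_hypertension(
            raw_sbp[f"e{e}"].to_numpy(),
            raw_dbp[f"e{e}"].to_numpy(),
            treated[f"e{e}"].to_numpy(dtype=bool),
            params,
        )
        out[f"e{e}"] = base | treated_e1
    return pd.DataFrame(out, index=raw_sbp.index)


def simulate_smoking(
    n: int,
    params: TreatmentParams = TreatmentParams(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smoking flags, shape (n, 3): Bernoulli(0.229) at exam 1, each
    smoker quitting with probability 0.0145 at exams 2 and 3; quitters
    never resume and nonsmokers never start."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    smoke = np.zeros((n, 3), dtype=bool)
    smoke[:, 0] = rng.random(n) < params.smoker_init
    for e in (1, 2):
        quits = rng.random(n) < params.quit_rate
        smoke[:, e] = smoke[:, e - 1] & ~quits
    return smoke
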