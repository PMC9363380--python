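"""CKD-EPI creatinine eGFR and one-year renal outcomes.

Implements the 2009 creatinine-based CKD-EPI equation without the race
coefficient,

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
           * 0.993^age * 1.018 [if female]

with kappa = 0.7 / 0.9 and alpha = -0.329 / -0.411 for women / men, serum
creatinine (Scr) in mg/dL, age in years, and eGFR in ml/min/1.73 m2.
The module also provides the numerical inverse (creatinine for a target
eGFR), the one-year change and percent change, and the >=10 % decline
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, MissingDataError

#: Sex-specific constants of the 2009 CKD-EPI creatinine equation.
CKDEPI_2009 = {
    "female": {"kappa": 0.7, "alpha": -0.329, "sex_factor": 1.018},
    "male": {"kappa": 0.9, "alpha": -0.411, "sex_factor": 1.0},
}
_BASE = 141.0
_AGE_FACTOR = 0.993
_EXP_HIGH = -1.209

#: Creatinine above this (mg/dL) is treated as a probable unit error
#: (values in umol/L are ~88x larger) unless the check is disabled.
CREATININE_UNIT_LIMIT = 15.0

#: eGFR below which chronic kidney disease is flagged (ml/min/1.73 m2).
CKD_EGFR_THRESHOLD = 60.0


def _sex_constants(sex):
    sex_arr = np.asarray(sex)
    bad = ~np.isin(sex_arr, list(CKDEPI_2009))
    if np.any(bad):
        raise ConfigurationError(
            f"sex must be one of {sorted(CKDEPI_2009)}, got {np.unique(sex_arr[bad]).tolist()}"
        )
    f, m = CKDEPI_2009["female"], CKDEPI_2009["male"]
    is_f = sex_arr == "female"
    kappa = np.where(is_f, f["kappa"], m["kappa"])
    alpha = np.where(is_f, f["alpha"], m["alpha"])
    sf = np.where(is_f, f["sex_factor"], m["sex_factor"])
    return kappa, alpha, sf


def egfr_ckdepi(creatinine, sex, age, *, unit_check: bool = True):
    """Estimated GFR (ml/min/1.73 m2) from serum creatinine, sex and age.

    Accepts scalars or arrays (broadcast together). Strictly decreasing in
    both creatinine and age.

    Parameters
    ----------
    creatinine
        Serum creatinine in mg/dL, strictly positive.
    sex
        ``"male"`` or ``"female"`` (scalar or array).
    age
        Age in years, strictly positive.
    unit_check
        Reject creatinine > 15 mg/dL, which almost always means the value
        is in umol/L. Pass ``False`` for deliberately extreme inputs.
    """
    scr = np.asarray(creatinine, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(scr)) or np.any(scr <= 0):
        raise ValueError("creatinine must be finite and > 0 (mg/dL)")
    if np.any(~np.isfinite(age_arr)) or np.any(age_arr <= 0):
        raise ValueError("age must be finite and > 0 (years)")
    if unit_check and np.any(scr > CREATININE_UNIT_LIMIT):
        raise ValueError(
            f"creatinine > {CREATININE_UNIT_LIMIT} mg/dL suggests umol/L units; "
            "convert to mg/dL or pass unit_check=False"
        )
    kappa, alpha, sf = _sex_constants(sex)
    ratio = scr / kappa
    out = (
        _BASE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _EXP_HIGH
        * _AGE_FACTOR**age_arr
        * sf
    )
    return float(out) if out.shape == () else out


def creatinine_for_egfr(egfr, sex, age, *, tol: float = 1e-8):
    """Serum creatinine (mg/dL) that yields a target eGFR, by bisection.

    The CKD-EPI equation is strictly decreasing in creatinine, so the
    inverse is unique; bisection over [1e-3, 40] mg/dL converges to `tol`.
    Used by the synthetic-cohort generator so that generated creatinine and
    the estimator share one eGFR definition.
    """
    target = np.atleast_1d(np.asarray(egfr, dtype=float))
    if np.any(~np.isfinite(target)) or np.any(target <= 0):
        raise ValueError("target eGFR must be finite and > 0")
    age_b = np.broadcast_to(np.asarray(age, dtype=float), target.shape)
    sex_b = np.broadcast_to(np.asarray(sex), target.shape)
    lo = np.full(target.shape, 1e-3)
    hi = np.full(target.shape, 40.0)
    # ~log2(40/1e-8) ~ 32 + margin iterations
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        f = egfr_ckdepi(mid, sex_b, age_b, unit_check=False)
        # eGFR decreasing in creatinine: too-high eGFR => raise creatinine
        high = f > target
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    return float(out[0]) if np.asarray(egfr).shape == () else out


@dataclass(frozen=True)
class RenalOutcome:
    """One-year renal outcome for a single participant."""

    egfr_baseline: float
    egfr_year1: float
    delta_egfr: float
    pct_change: float
    decline_flag: bool
    ckd_baseline_flag: bool


def renal_outcome(
    creatinine_baseline,
    creatinine_year1,
    sex,
    age,
    *,
    threshold: float = 10.0,
    strict: bool = False,
    unit_check: bool = True,
) -> RenalOutcome:
    """Renal outcome from baseline and year-1 creatinine for one participant.

    Percent change is ``100 * (eGFR_1y - eGFR_0) / eGFR_0``; a decline is
    flagged when the percent change is <= -threshold (``strict=True`` makes
    the boundary exclusive). Age at year 1 is taken as baseline age + 1.
    """
    for name, value in (
        ("baseline", creatinine_baseline),
        ("year-1", creatinine_year1),
    ):
        if value is None or not np.isfinite(value):
            raise MissingDataError(f"{name} creatinine is missing")
    e0 = egfr_ckdepi(creatinine_baseline, sex, age, unit_check=unit_check)
    e1 = egfr_ckdepi(creatinine_year1, sex, age + 1.0, unit_check=unit_check)
    delta = e1 - e0
    pct = 100.0 * delta / e0
    decline = pct < -threshold if strict else pct <= -threshold
    return RenalOutcome(
        egfr_baseline=e0,
        egfr_year1=e1,
        delta_egfr=delta,
        pct_change=pct,
        decline_flag=bool(decline),
        ckd_baseline_flag=bool(e0 < CKD_EGFR_THRESHOLD),
    )


def add_renal_outcomes(wide, *, threshold: float = 10.0, strict: bool = False):
    """Append eGFR outcome columns to a per-participant wide table.

    Expects columns ``creatinine_baseline``, ``creatinine_year1``, ``sex``,
    ``age``; adds ``egfr_baseline``, ``egfr_year1``, ``delta_egfr``,
    ``pct_change_egfr``, ``decline`` and ``ckd_baseline``.
    """
    required = {"creatinine_baseline", "creatinine_year1", "sex", "age"}
    missing = required - set(wide.columns)
    if missing:
        raise MissingDataError(f"outcome table lacks columns: {sorted(missing)}")
    out = wide.copy()
    scr0 = out["creatinine_baseline"].to_numpy(dtype=float)
    scr1 = out["creatinine_year1"].to_numpy(dtype=float)
    if np.any(~np.isfinite(scr0)) or np.any(~np.isfinite(scr1)):
        raise MissingDataError(
            "missing creatinine in outcome computation; apply exclusions first"
        )
    sex = out["sex"].to_numpy()
    age = out["age"].to_numpy(dtype=float)
    e0 = egfr_ckdepi(scr0, sex, age)
    e1 = egfr_ckdepi(scr1, sex, age + 1.0)
    pct = 100.0 * (e1 - e0) / e0
    out["egfr_baseline"] = e0
    out["egfr_year1"] = e1
    out["delta_egfr"] = e1 - e0
    out["pct_change_egfr"] = pct
    out["decline"] = (pct < -threshold) if strict else (pct <= -threshold)
    out["ckd_baseline"] = e0 < CKD_EGFR_THRESHOLD
    return out
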