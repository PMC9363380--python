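"""Analytic-sample construction and exposure-change categorization.

Exclusion filters mirror a typical longitudinal nutrition cohort: records
with an incomplete food-frequency questionnaire at either timepoint, with
implausible total energy intake (outside sex-specific bounds, by default
women <500 or >3500 kcal/day and men <800 or >4000 kcal/day), or with
missing serum creatinine at either timepoint are dropped. Attribution is
sequential: a participant failing several rules is counted under the first.

One-year score change is categorized into four exposure groups: decrease or
maintenance (change <= 0, the reference) and tertiles of the strictly
positive changes; each category also carries its median change for the
trend test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

#: Sex-specific plausibility bounds on total energy intake (kcal/day).
#: A record is excluded when energy is strictly below the lower or strictly
#: above the upper bound; the bounds themselves are retained.
DEFAULT_ENERGY_BOUNDS = {"female": (500.0, 3500.0), "male": (800.0, 4000.0)}

CHANGE_CATEGORIES = ("DecrMaint", "T1", "T2", "T3")


@dataclass
class CohortFlow:
    """Participant flow through the exclusion filters."""

    n_enrolled: int
    n_excluded_ffq: int = 0
    n_excluded_energy: int = 0
    n_excluded_creatinine: int = 0
    overlap_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name != "overlap_counts" and value < 0:
                raise ConfigurationError(f"flow count {name} is negative")
        if self.n_analytic < 0:
            raise ConfigurationError("exclusions exceed the enrolled count")

    @property
    def n_analytic(self) -> int:
        return (
            self.n_enrolled
            - self.n_excluded_ffq
            - self.n_excluded_energy
            - self.n_excluded_creatinine
        )

    def report(self) -> str:
        return (
            f"Enrolled participants: {self.n_enrolled}\n"
            f"Excluded, incomplete dietary questionnaire: {self.n_excluded_ffq}\n"
            f"Excluded, extreme total energy intake: {self.n_excluded_energy}\n"
            f"Excluded, missing creatinine: {self.n_excluded_creatinine}\n"
            f"Analytic sample: {self.n_analytic}\n"
        )

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_excluded_ffq": self.n_excluded_ffq,
            "n_excluded_energy": self.n_excluded_energy,
            "n_excluded_creatinine": self.n_excluded_creatinine,
            "n_analytic": self.n_analytic,
            "overlap_counts": dict(self.overlap_counts),
        }


def apply_exclusions(
    cohort: pd.DataFrame,
    *,
    energy_bounds: dict[str, tuple[float, float]] | None = None,
    report_overlap: bool = False,
) -> tuple[pd.DataFrame, CohortFlow]:
    """Drop ineligible participants from a long-format cohort table.

    Parameters
    ----------
    cohort
        One row per participant-timepoint with at least ``participant_id``,
        ``timepoint``, ``sex``, ``ffq_complete``, ``energy_kcal`` and
        ``creatinine_mgdl`` columns.
    energy_bounds
        Sex -> (lower, upper) kcal/day plausibility bounds (strict
        inequalities); defaults to :data:`DEFAULT_ENERGY_BOUNDS`.
    report_overlap
        Additionally count, per rule, participants failing that rule
        regardless of attribution order.

    Returns
    -------
    (analytic cohort, CohortFlow)
        The table restricted to retained participants (both timepoints),
        and the flow accounting with sequential (first-failing-rule)
        attribution.
    """
    required = {"participant_id", "timepoint", "sex", "ffq_complete", "energy_kcal", "creatinine_mgdl"}
    missing = required - set(cohort.columns)
    if missing:
        raise SchemaError(f"cohort table lacks required columns: {sorted(missing)}")
    bounds = DEFAULT_ENERGY_BOUNDS if energy_bounds is None else energy_bounds

    by_pid = cohort.groupby("participant_id", sort=True)
    n_timepoints = by_pid["timepoint"].nunique()
    ffq_ok = by_pid["ffq_complete"].all() & (n_timepoints == 2)

    sex = by_pid["sex"].first()
    lo = sex.map({s: b[0] for s, b in bounds.items()})
    hi = sex.map({s: b[1] for s, b in bounds.items()})
    if lo.isna().any():
        raise SchemaError(f"no energy bounds for sex value(s) {sorted(sex[lo.isna()].unique())}")
    energy_min = by_pid["energy_kcal"].min()
    energy_max = by_pid["energy_kcal"].max()
    # exclusion bounds are strict ("below 500", "above 3500"): a value
    # exactly on a bound is retained
    energy_ok = (energy_min >= lo) & (energy_max <= hi) & energy_min.notna()

    creat_ok = cohort["creatinine_mgdl"].notna().groupby(cohort["participant_id"]).all()
    creat_ok = creat_ok.reindex(ffq_ok.index)

    fail_ffq = ~ffq_ok
    fail_energy = ffq_ok & ~energy_ok
    fail_creat = ffq_ok & energy_ok & ~creat_ok

    flow = CohortFlow(
        n_enrolled=int(len(ffq_ok)),
        n_excluded_ffq=int(fail_ffq.sum()),
        n_excluded_energy=int(fail_energy.sum()),
        n_excluded_creatinine=int(fail_creat.sum()),
    )
    if report_overlap:
        flow.overlap_counts = {
            "ffq": int((~ffq_ok).sum()),
            "energy": int((~energy_ok).sum()),
            "creatinine": int((~creat_ok).sum()),
        }
    keep = ffq_ok & energy_ok & creat_ok
    analytic = cohort[cohort["participant_id"].isin(keep[keep].index)].copy()
    return analytic, flow


def categorize_change(deltas: pd.DataFrame, *, delta_col: str = "delta") -> pd.DataFrame:
    """Assign each participant's score change to DecrMaint or T1-T3.

    Changes <= 0 form the decrease/maintenance reference category; strictly
    positive changes are ranked (ties broken by participant_id) and split
    into three near-equal groups, with boundary ties pushed into the lower
    tertile. Each row gains ``category`` and ``category_median`` (the
    within-category median change, the trend-test coding).

    Raises
    ------
    ConfigurationError
        If fewer than 3 strictly positive changes exist (tertiles undefined)
        or all category medians coincide.
    """
    if delta_col not in deltas.columns or "participant_id" not in deltas.columns:
        raise SchemaError(f"expected columns 'participant_id' and {delta_col!r}")
    out = deltas.copy()
    d = out[delta_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(d)):
        raise SchemaError(f"{delta_col!r} contains missing values")

    positive = d > 0
    n_pos = int(positive.sum())
    if n_pos < 3:
        raise ConfigurationError(
            f"tertiles of increase need >= 3 strictly positive changes, got {n_pos}"
        )
    category = np.full(len(out), "DecrMaint", dtype=object)

    pos_idx = np.flatnonzero(positive)
    order = np.lexsort((out["participant_id"].to_numpy()[pos_idx], d[pos_idx]))
    sorted_idx = pos_idx[order]
    sorted_d = d[sorted_idx]
    # near-equal rank thirds, then push boundary ties down
    tert = np.minimum((np.arange(n_pos) * 3) // n_pos, 2)
    for i in range(1, n_pos):
        if sorted_d[i] == sorted_d[i - 1] and tert[i] > tert[i - 1]:
            tert[i] = tert[i - 1]
    category[sorted_idx] = np.array(["T1", "T2", "T3"], dtype=object)[tert]
    out["category"] = pd.Categorical(category, categories=list(CHANGE_CATEGORIES))

    medians = out.groupby("category", observed=False)[delta_col].median()
    if medians.dropna().nunique() < 2:
        raise ConfigurationError("degenerate change categories: all medians equal")
    out["category_median"] = out["category"].map(medians).astype(float)
    return out
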