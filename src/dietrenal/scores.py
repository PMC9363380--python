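"""The four a priori dietary pattern scores.

* 17-item energy-reduced Mediterranean diet screener (0-17): one point per
  binary criterion met (criteria in :mod:`dietrenal.criteria`).
* Trichopoulou Mediterranean diet score (0-9): favorable components score 1
  when intake is at or above the sex-specific population median, unfavorable
  components score 1 when below it, and alcohol scores 1 inside a moderate
  sex-specific window (10-50 g/day men, 5-25 g/day women).
* DASH score (8-40): eight components scored 1-5 by population quintile,
  ascending for favorable foods and descending for sodium, red/processed
  meat and sugar-sweetened beverages.
* Protein diet score (0-20): 0-10 points for the undecile stratum of protein
  energy share plus 0-10 for the stratum of the plant:animal protein ratio.

Every function returns both the total and a per-component breakdown, and
each has a vectorized cohort-level counterpart used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CriteriaTable
from .errors import MissingDataError
from .reference import (
    ALCOHOL_WINDOW,
    DASH_FAVORABLE,
    DASH_UNFAVORABLE,
    PROTEIN_COMPONENTS,
    TRICHOPOULOU_FAVORABLE,
    TRICHOPOULOU_UNFAVORABLE,
    PopulationReference,
    assign_stratum,
    component_values,
)

SCORE_NAMES = ("ermed17", "trichopoulou", "dash", "protein_diet")

SCORE_RANGES = {
    "ermed17": (0, 17),
    "trichopoulou": (0, 9),
    "dash": (8, 40),
    "protein_diet": (0, 20),
}


@dataclass(frozen=True)
class DietScorePanel:
    """The four score totals (and breakdowns) for one participant-timepoint."""

    ermed17: int
    trichopoulou: int
    dash: int
    protein_diet: int
    breakdown: dict

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.ermed17, self.trichopoulou, self.dash, self.protein_diet)


def _as_frame(record) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    return pd.DataFrame([record])


# ---------------------------------------------------------------------------
# 17-item screener


def ermed17_indicators(df: pd.DataFrame, criteria: CriteriaTable, *, use_preanswered: bool = True) -> pd.DataFrame:
    """Per-item 0/1 indicator columns (``ermed_item_1`` .. ``ermed_item_17``).

    For each item a pre-answered boolean column is used when present and
    non-missing (``use_preanswered``); otherwise the criterion is evaluated
    on the item's dietary variable. An item resolvable neither way raises
    :class:`MissingDataError` naming it.
    """
    n = len(df)
    out = {}
    for crit in criteria:
        col = f"ermed_item_{crit.item}"
        values = np.full(n, -1, dtype=float)
        if use_preanswered and col in df.columns:
            pre = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            values = np.where(np.isfinite(pre), pre, -1.0)
        unresolved = values < 0
        if np.any(unresolved):
            if crit.variable not in df.columns:
                raise MissingDataError(
                    f"screener item {crit.item} ({crit.label}): no pre-answered "
                    f"boolean and no column {crit.variable!r}"
                )
            var = pd.to_numeric(df[crit.variable], errors="coerce").to_numpy(dtype=float)
            bad = unresolved & ~np.isfinite(var)
            if np.any(bad):
                raise MissingDataError(
                    f"screener item {crit.item} ({crit.label}): missing value "
                    f"in {crit.variable!r} for {int(bad.sum())} record(s)"
                )
            sex = df["sex"].to_numpy() if "sex" in df.columns else None
            met = crit.evaluate(var, sex=sex)
            values = np.where(unresolved, np.asarray(met, dtype=float), values)
        out[col] = values.astype(int)
    return pd.DataFrame(out, index=df.index)


def score_ermed17(record, criteria: CriteriaTable, *, use_preanswered: bool = True):
    """Screener total (0-17) and the 17-vector of item indicators."""
    ind = ermed17_indicators(_as_frame(record), criteria, use_preanswered=use_preanswered)
    vec = ind.iloc[0].to_numpy(dtype=int)
    return int(vec.sum()), vec


# ---------------------------------------------------------------------------
# Trichopoulou Mediterranean diet score


def trichopoulou_components(df: pd.DataFrame, ref: PopulationReference) -> pd.DataFrame:
    """Per-component 0/1 points of the Trichopoulou score for every row."""
    sex = df["sex"].to_numpy()
    medians = {}
    for comp in list(TRICHOPOULOU_FAVORABLE) + list(TRICHOPOULOU_UNFAVORABLE):
        med = np.array([ref.median(comp, s) for s in sex])
        medians[comp] = med
    out = {}
    for comp in TRICHOPOULOU_FAVORABLE:
        x = component_values(df, comp)
        _check_finite(x, comp, allow_inf=comp.endswith("ratio"))
        out[comp] = (x >= medians[comp]).astype(int)
    for comp in TRICHOPOULOU_UNFAVORABLE:
        x = component_values(df, comp)
        _check_finite(x, comp)
        out[comp] = (x < medians[comp]).astype(int)
    alcohol = pd.to_numeric(df["alcohol_g"], errors="coerce").to_numpy(dtype=float)
    _check_finite(alcohol, "alcohol")
    lo = np.where(sex == "female", ALCOHOL_WINDOW["female"][0], ALCOHOL_WINDOW["male"][0])
    hi = np.where(sex == "female", ALCOHOL_WINDOW["female"][1], ALCOHOL_WINDOW["male"][1])
    out["alcohol"] = ((alcohol >= lo) & (alcohol <= hi)).astype(int)
    return pd.DataFrame(out, index=df.index)


def score_trichopoulou(record, ref: PopulationReference):
    """Trichopoulou total (0-9) and per-component breakdown for one record."""
    comp = trichopoulou_components(_as_frame(record), ref)
    row = comp.iloc[0]
    return int(row.sum()), row.to_dict()


# ---------------------------------------------------------------------------
# DASH score


def dash_components(df: pd.DataFrame, ref: PopulationReference) -> pd.DataFrame:
    """Per-component 1-5 points of the DASH score for every row."""
    out = {}
    for comp in DASH_FAVORABLE:
        x = component_values(df, comp)
        _check_finite(x, comp)
        out[comp] = assign_stratum(x, ref.quintile_cutoffs[comp]) + 1
    for comp in DASH_UNFAVORABLE:
        x = component_values(df, comp)
        _check_finite(x, comp)
        out[comp] = 5 - assign_stratum(x, ref.quintile_cutoffs[comp])
    return pd.DataFrame(out, index=df.index)


def score_dash(record, ref: PopulationReference):
    """DASH total (8-40) and per-component breakdown for one record."""
    comp = dash_components(_as_frame(record), ref)
    row = comp.iloc[0]
    return int(row.sum()), row.to_dict()


# ---------------------------------------------------------------------------
# Protein diet score


def protein_diet_components(df: pd.DataFrame, ref: PopulationReference) -> pd.DataFrame:
    """Per-component 0-10 stratum points of the protein diet score."""
    out = {}
    for comp in PROTEIN_COMPONENTS:
        x = component_values(df, comp)
        if np.any(np.isnan(x)):
            raise MissingDataError(f"missing {comp} for protein diet score")
        out[comp] = assign_stratum(x, ref.undecile_cutoffs[comp])
    return pd.DataFrame(out, index=df.index)


def score_protein_diet(record, ref: PopulationReference):
    """Protein diet score total (0-20) and per-component breakdown."""
    comp = protein_diet_components(_as_frame(record), ref)
    row = comp.iloc[0]
    return int(row.sum()), row.to_dict()


# ---------------------------------------------------------------------------
# Panel


def score_panel(record, ref: PopulationReference, criteria: CriteriaTable) -> DietScorePanel:
    """All four scores for one participant-timepoint."""
    try:
        ermed_total, ermed_vec = score_ermed17(record, criteria)
    except MissingDataError as exc:
        raise MissingDataError(f"ermed17: {exc}") from exc
    try:
        tri_total, tri_break = score_trichopoulou(record, ref)
    except MissingDataError as exc:
        raise MissingDataError(f"trichopoulou: {exc}") from exc
    try:
        dash_total, dash_break = score_dash(record, ref)
    except MissingDataError as exc:
        raise MissingDataError(f"dash: {exc}") from exc
    try:
        pds_total, pds_break = score_protein_diet(record, ref)
    except MissingDataError as exc:
        raise MissingDataError(f"protein_diet: {exc}") from exc
    return DietScorePanel(
        ermed17=ermed_total,
        trichopoulou=tri_total,
        dash=dash_total,
        protein_diet=pds_total,
        breakdown={
            "ermed17": {f"item_{i + 1}": int(v) for i, v in enumerate(ermed_vec)},
            "trichopoulou": tri_break,
            "dash": dash_break,
            "protein_diet": pds_break,
        },
    )


def score_cohort(
    df: pd.DataFrame,
    ref: PopulationReference,
    criteria: CriteriaTable,
    *,
    use_preanswered: bool = True,
) -> pd.DataFrame:
    """Vectorized scores for every row of a cohort table.

    Returns a copy of the identifier columns plus the four totals and the
    17 screener item indicators.
    """
    ind = ermed17_indicators(df, criteria, use_preanswered=use_preanswered)
    tri = trichopoulou_components(df, ref)
    dash = dash_components(df, ref)
    pds = protein_diet_components(df, ref)
    keep = [c for c in ("participant_id", "timepoint") if c in df.columns]
    out = df[keep].copy() if keep else pd.DataFrame(index=df.index)
    out["ermed17"] = ind.sum(axis=1).astype(int)
    out["trichopoulou"] = tri.sum(axis=1).astype(int)
    out["dash"] = dash.sum(axis=1).astype(int)
    out["protein_diet"] = pds.sum(axis=1).astype(int)
    for col in ind.columns:
        out[col] = ind[col]
    return out


def tidy_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """Long-format (participant_id, timepoint, score, value) score table."""
    id_cols = [c for c in ("participant_id", "timepoint") if c in scored.columns]
    return scored.melt(
        id_vars=id_cols,
        value_vars=list(SCORE_NAMES),
        var_name="score",
        value_name="value",
    )


def _check_finite(x: np.ndarray, component: str, *, allow_inf: bool = False) -> None:
    bad = np.isnan(x) if allow_inf else ~np.isfinite(x)
    if np.any(bad):
        raise MissingDataError(
            f"missing intake for component {component!r} in {int(bad.sum())} record(s)"
        )
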