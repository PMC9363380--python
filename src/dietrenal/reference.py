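"""Population reference statistics the median/quantile-based scores require.

The Trichopoulou Mediterranean diet score is anchored to sex-specific
medians of component intake, the DASH score to population quintiles, and
the protein diet score to 11 equal-frequency strata (undeciles) of protein
energy share and of the plant-to-animal protein ratio. All of these are
estimated from a cohort — by default its baseline rows — and then frozen,
so that one-year score changes reflect intake change rather than cutoff
drift.

Quantiles use the median-unbiased estimator; a value tied exactly with a
cutoff is assigned to the lower stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError

QUANTILE_METHOD = "median_unbiased"

#: Trichopoulou components scored against sex-specific medians
#: (component name -> intake column; the MUFA:SFA ratio is derived).
TRICHOPOULOU_FAVORABLE = {
    "vegetables": "veg_g",
    "fruits_nuts": "fruits_nuts_g",
    "legumes": "legumes_g",
    "cereals_potatoes": "cereals_potatoes_g",
    "fish": "fish_g",
    "mufa_sfa_ratio": "mufa_sfa_ratio",
}
TRICHOPOULOU_UNFAVORABLE = {
    "meat": "meat_g",
    "dairy": "dairy_g",
}
TRICHOPOULOU_MEDIAN_COMPONENTS = {**TRICHOPOULOU_FAVORABLE, **TRICHOPOULOU_UNFAVORABLE}

#: Moderate-alcohol windows (g/day, inclusive) of the Trichopoulou score.
ALCOHOL_WINDOW = {"male": (10.0, 50.0), "female": (5.0, 25.0)}

#: DASH components scored by population quintile.
DASH_FAVORABLE = {
    "fruits": "fruit_g",
    "vegetables": "veg_g",
    "legumes_nuts": "legumes_nuts_g",
    "low_fat_dairy": "lowfat_dairy_g",
    "whole_grains": "whole_grains_g",
}
DASH_UNFAVORABLE = {
    "sodium": "sodium_g",
    "red_processed_meat": "red_processed_meat_g",
    "sugar_sweetened_beverages": "ssb_g",
}
DASH_COMPONENTS = {**DASH_FAVORABLE, **DASH_UNFAVORABLE}

#: Protein-diet-score components stratified into undeciles.
PROTEIN_COMPONENTS = ("protein_pct", "plant_animal_ratio")


def component_values(df: pd.DataFrame, component: str) -> np.ndarray:
    """Component values for every row of a cohort table, deriving ratios.

    ``mufa_sfa_ratio`` and ``plant_animal_ratio`` are computed from their
    gram columns; a zero denominator maps to +inf so that the ordering
    stays monotone (top stratum) instead of failing.
    """
    if component == "mufa_sfa_ratio":
        num = df["mufa_g"].to_numpy(dtype=float)
        den = df["sfa_g"].to_numpy(dtype=float)
    elif component == "plant_animal_ratio":
        num = df["plant_protein_g"].to_numpy(dtype=float)
        den = df["animal_protein_g"].to_numpy(dtype=float)
    elif component == "protein_pct":
        return df["protein_pct_energy"].to_numpy(dtype=float)
    else:
        col = (
            TRICHOPOULOU_MEDIAN_COMPONENTS.get(component)
            or DASH_COMPONENTS.get(component)
            or component
        )
        if col not in df.columns:
            raise MissingDataError(f"cohort table lacks column {col!r} for component {component!r}")
        return df[col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return ratio


def assign_stratum(values, cutoffs) -> np.ndarray:
    """0-based stratum index for each value given ascending cutoffs.

    Ties with a cutoff go to the lower stratum (``searchsorted`` with
    ``side='left'``).
    """
    return np.searchsorted(np.asarray(cutoffs, dtype=float), np.asarray(values, dtype=float), side="left")


@dataclass
class PopulationReference:
    """Frozen reference statistics for the median/quantile-anchored scores."""

    sex_specific_medians: dict[tuple[str, str], float] = field(default_factory=dict)
    quintile_cutoffs: dict[str, np.ndarray] = field(default_factory=dict)
    undecile_cutoffs: dict[str, np.ndarray] = field(default_factory=dict)
    source_n: int = 0

    def median(self, component: str, sex: str) -> float:
        key = (component, sex)
        if key not in self.sex_specific_medians:
            raise MissingDataError(f"no reference median for component {component!r}, sex {sex!r}")
        return self.sex_specific_medians[key]

    def validate(self) -> None:
        for comp, cuts in {**self.quintile_cutoffs, **self.undecile_cutoffs}.items():
            arr = np.asarray(cuts, dtype=float)
            if np.any(np.diff(arr) < 0):
                raise ConfigurationError(f"cutoffs for {comp!r} are not non-decreasing")
        for key, med in self.sex_specific_medians.items():
            if not np.isfinite(med):
                raise ConfigurationError(f"median for {key} is not finite")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, *, timepoint: str | None = "baseline") -> "PopulationReference":
        """Estimate all reference statistics from a cohort table.

        Parameters
        ----------
        cohort
            Long- or wide-format table with one row per participant(-timepoint)
            and the intake columns named in the component maps.
        timepoint
            If the table has a ``timepoint`` column, restrict to this value
            (default ``"baseline"``); pass ``None`` to use all rows.
        """
        df = _restrict_timepoint(cohort, timepoint)
        ref = cls(source_n=len(df))
        ref.sex_specific_medians = compute_sex_specific_medians(df, timepoint=None)
        ref.quintile_cutoffs = compute_quintile_cutoffs(df, timepoint=None)
        ref.undecile_cutoffs = compute_undecile_cutoffs(df, timepoint=None)
        ref.validate()
        return ref


def _restrict_timepoint(cohort: pd.DataFrame, timepoint: str | None) -> pd.DataFrame:
    if timepoint is not None and "timepoint" in cohort.columns:
        return cohort[cohort["timepoint"] == timepoint]
    return cohort


def compute_sex_specific_medians(
    cohort: pd.DataFrame,
    components=None,
    *,
    timepoint: str | None = "baseline",
) -> dict[tuple[str, str], float]:
    """Per-sex median intake of each component (g/day or derived ratio)."""
    df = _restrict_timepoint(cohort, timepoint)
    if "sex" not in df.columns:
        raise MissingDataError("cohort table lacks a 'sex' column")
    out: dict[tuple[str, str], float] = {}
    for comp in components or TRICHOPOULOU_MEDIAN_COMPONENTS:
        values = component_values(df, comp)
        for sex in ("male", "female"):
            stratum = values[(df["sex"] == sex).to_numpy()]
            stratum = stratum[~np.isnan(stratum)]
            if stratum.size == 0:
                raise MissingDataError(
                    f"empty stratum: no {sex} participants with {comp} intake"
                )
            out[(comp, sex)] = float(np.median(stratum))
    return out


def compute_quintile_cutoffs(
    cohort: pd.DataFrame,
    components=None,
    *,
    timepoint: str | None = "baseline",
) -> dict[str, np.ndarray]:
    """Four cutoffs per component at the 20/40/60/80 empirical percentiles."""
    df = _restrict_timepoint(cohort, timepoint)
    out: dict[str, np.ndarray] = {}
    for comp in components or DASH_COMPONENTS:
        values = component_values(df, comp)
        values = values[np.isfinite(values)]
        if values.size < 5:
            raise MissingDataError(
                f"quintile cutoffs for {comp!r} need >= 5 observations, got {values.size}"
            )
        if np.unique(values).size == 1:
            raise ConfigurationError(f"component {comp!r} is constant; quintiles undefined")
        if np.unique(values).size < 5:
            warnings.warn(
                f"component {comp!r} has fewer than 5 distinct values; "
                "quintile groups will be heavily tied",
                stacklevel=2,
            )
        out[comp] = np.quantile(values, [0.2, 0.4, 0.6, 0.8], method=QUANTILE_METHOD)
    return out


def compute_undecile_cutoffs(
    cohort: pd.DataFrame,
    components=None,
    *,
    timepoint: str | None = "baseline",
) -> dict[str, np.ndarray]:
    """Ten cutoffs per component defining 11 equal-frequency strata."""
    df = _restrict_timepoint(cohort, timepoint)
    out: dict[str, np.ndarray] = {}
    for comp in components or PROTEIN_COMPONENTS:
        values = component_values(df, comp)
        values = values[~np.isnan(values)]
        if values.size < 11:
            raise MissingDataError(
                f"undecile cutoffs for {comp!r} need >= 11 observations, got {values.size}"
            )
        # +inf ratios (zero denominator) sit above any finite cutoff, so
        # interpolated cutoffs are computed on the finite part only
        finite = values[np.isfinite(values)]
        probs = np.arange(1, 11) / 11.0
        out[comp] = np.quantile(finite, probs, method=QUANTILE_METHOD)
    return out
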