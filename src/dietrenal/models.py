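"""Nested multivariable association models with cluster-robust variance.

Two outcomes are modelled: one-year eGFR change (ordinary least squares)
and >=10 % eGFR decline (logistic regression). The exposure is a dietary
score's one-year change, either as four categories (decrease/maintenance
reference vs tertiles of increase) or continuous per 1-point change.
Covariate tiers are nested:

* M1 - sex and age (linear models also include baseline eGFR);
* M2 - M1 plus BMI, smoking, education, physical activity, diabetes,
  hypertension, hypercholesterolemia, recruiting-center size quartile,
  intervention arm, and energy intake;
* M3 - M2 plus the baseline value of the dietary score and one-year weight
  change.

Standard errors are sandwich estimates clustered on the recruiting center
(configurable), with the usual G/(G-1)-type finite-sample correction by
default. The trend test re-codes the exposure as each participant's
category-median change, interactions are tested by likelihood ratio, and
the screener item-removal analysis refits both outcomes after deleting one
of the 17 items, rescaling estimates by 16/17 (on the log scale for odds
ratios) to keep them comparable with the full score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CHANGE_CATEGORIES
from .errors import ConfigurationError, EstimationError, SchemaError, SeparationError

TIERS = ("M1", "M2", "M3")

_SMOKING_LEVELS = ("never", "former", "current")
_EDUCATION_LEVELS = ("primary", "secondary", "graduate")


@dataclass
class ModelSpec:
    """What to fit: outcome, exposure coding, covariate tier, clustering."""

    outcome: str  # "delta_egfr" (linear) or "decline" (logistic)
    score: str
    coding: str = "categorical"  # or "continuous"
    tier: str = "M1"
    cluster: str = "center"
    small_sample_correction: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in ("delta_egfr", "decline"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.coding not in ("categorical", "continuous"):
            raise ConfigurationError(f"unknown exposure coding {self.coding!r}")
        if self.tier not in TIERS:
            raise ConfigurationError(f"model tier must be one of {TIERS}")

    @property
    def is_linear(self) -> bool:
        return self.outcome == "delta_egfr"


@dataclass
class AssociationResult:
    """Per-category (or per-point) effect estimates for one fitted model."""

    score: str
    outcome: str
    tier: str
    coding: str
    scale: str  # "beta" or "or"
    estimates: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    continuous_estimate: tuple[float, float, float] | None = None
    p_trend: float | None = None
    n_per_category: dict[str, int] | None = None
    n_obs: int = 0


@dataclass
class ItemRemovalResult:
    """Rescaled 16-item estimates after removing one screener item."""

    item: int
    rescaled_beta: float
    beta_ci: tuple[float, float]
    pct_change_beta: float
    rescaled_or: float
    or_ci: tuple[float, float]
    pct_change_or: float


def rescale_beta(beta: float, n_kept: int = 16, n_full: int = 17) -> float:
    """Rescale a reduced-score coefficient to the full score's point scale."""
    return beta * n_kept / n_full


def rescale_or(odds_ratio: float, n_kept: int = 16, n_full: int = 17) -> float:
    """Rescale an odds ratio on the log scale to the full score's point scale."""
    return float(np.exp(np.log(odds_ratio) * n_kept / n_full))


def pct_change_vs_full(reduced: float, full: float, *, scale: str = "beta") -> float:
    """Percent change of a reduced-score estimate relative to the full score.

    Odds ratios are compared on the log scale so that attenuation toward the
    null reads as a negative percent change regardless of effect direction.
    """
    if scale == "or":
        reduced, full = np.log(reduced), np.log(full)
    if full == 0:
        raise ConfigurationError("full-score estimate is zero; percent change undefined")
    return float(100.0 * (reduced - full) / full)


def add_center_size_quartile(data: pd.DataFrame, *, center_col: str = "center") -> pd.DataFrame:
    """Add ``center_size_quartile`` (1-4) by quartile of center enrolment.

    Quartiles are formed at the center level (every participant of a center
    shares its quartile); with fewer than four centers, as many groups as
    centers are formed.
    """
    out = data.copy()
    sizes = out[center_col].value_counts()
    n_groups = min(4, len(sizes))
    quart = pd.qcut(sizes.rank(method="first"), n_groups, labels=False) + 1
    out["center_size_quartile"] = out[center_col].map(quart).astype(int)
    return out


def _dummies(series: pd.Series, levels, prefix: str) -> pd.DataFrame:
    cols = {}
    for level in levels[1:]:  # first level is the reference
        cols[f"{prefix}_{level}"] = (series == level).astype(float)
    return pd.DataFrame(cols, index=series.index)


def tier_covariates(data: pd.DataFrame, spec: ModelSpec, *, baseline_score_col: str | None = None) -> pd.DataFrame:
    """Resolved covariate design columns for the spec's tier."""
    X = pd.DataFrame(index=data.index)
    X["sex_female"] = (data["sex"] == "female").astype(float)
    X["age"] = data["age"].astype(float)
    if spec.is_linear:
        X["egfr_baseline"] = data["egfr_baseline"].astype(float)
    if spec.tier in ("M2", "M3"):
        X["bmi"] = data["bmi"].astype(float)
        X = pd.concat([X, _dummies(data["smoking"], _SMOKING_LEVELS, "smoking")], axis=1)
        X = pd.concat([X, _dummies(data["education"], _EDUCATION_LEVELS, "education")], axis=1)
        X["phys_activity"] = data["phys_activity"].astype(float)
        for flag in ("diabetes", "hypertension", "hypercholesterolemia", "intervention"):
            X[flag] = data[flag].astype(float)
        if "center_size_quartile" not in data.columns:
            data = add_center_size_quartile(data, center_col=spec.cluster)
        q_levels = sorted(data["center_size_quartile"].unique())
        X = pd.concat(
            [X, _dummies(data["center_size_quartile"], q_levels, "center_q")], axis=1
        )
        X["energy_kcal"] = data["energy_kcal"].astype(float)
    if spec.tier == "M3":
        col = baseline_score_col or f"{spec.score}_baseline"
        X["baseline_score"] = data[col].astype(float)
        X["weight_change"] = data["weight_change"].astype(float)
    return X


def _exposure_columns(data: pd.DataFrame, spec: ModelSpec, exposure_col: str | None) -> pd.DataFrame:
    if spec.coding == "continuous":
        col = exposure_col or f"{spec.score}_delta"
        return pd.DataFrame({"per_point": data[col].astype(float)}, index=data.index)
    col = exposure_col or f"{spec.score}_category"
    cats = data[col].astype(str)
    unknown = set(cats.unique()) - set(CHANGE_CATEGORIES)
    if unknown:
        raise SchemaError(f"unexpected exposure categories {sorted(unknown)} in {col!r}")
    return _dummies(cats, list(CHANGE_CATEGORIES), "cat").rename(
        columns=lambda c: c.replace("cat_", "")
    )


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    exposure_col: str | None = None,
    extra_covariates: list[str] | None = None,
    baseline_score_col: str | None = None,
):
    """Assemble (y, X, groups) for a spec; X includes an intercept."""
    missing = [c for c in ("sex", "age", spec.cluster) if c not in data.columns]
    if missing:
        raise SchemaError(f"model data lacks columns: {missing}")
    exposure = _exposure_columns(data, spec, exposure_col)
    covariates = tier_covariates(data, spec, baseline_score_col=baseline_score_col)
    X = pd.concat([exposure, covariates], axis=1)
    if extra_covariates:
        for col in extra_covariates:
            X[col] = data[col].astype(float)
    X.insert(0, "const", 1.0)

    for col in X.columns[1:]:
        if X[col].nunique() <= 1:
            raise EstimationError(f"covariate {col!r} is constant; design is singular")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise EstimationError("design matrix is rank deficient (collinear columns)")

    if spec.is_linear:
        y = data["delta_egfr"].astype(float)
    else:
        y = data["decline"].astype(float)
    groups = data[spec.cluster]
    if groups.nunique() < 2:
        raise EstimationError(
            f"cluster-robust variance needs >= 2 clusters in {spec.cluster!r}"
        )
    return y, X, groups


def _robust_fit(model, spec: ModelSpec, groups):
    cov_kwds = {"groups": np.asarray(groups), "use_correction": spec.small_sample_correction}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if isinstance(model, sm.Logit):
            # z critical values for ML fits (the usual software convention)
            res = model.fit(disp=0, cov_type="cluster", cov_kwds=cov_kwds, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise EstimationError("logistic fit did not converge")
            return res
        # linear models: t critical values with G-1 degrees of freedom, the
        # standard finite-cluster inference convention
        return model.fit(cov_type="cluster", cov_kwds=cov_kwds, use_t=True)


def _category_counts(data: pd.DataFrame, spec: ModelSpec) -> dict[str, int] | None:
    col = f"{spec.score}_category"
    if col not in data.columns:
        return None
    counts = data[col].astype(str).value_counts()
    return {c: int(counts.get(c, 0)) for c in CHANGE_CATEGORIES}


def fit_linear_change(data: pd.DataFrame, spec: ModelSpec, **design_kwargs) -> AssociationResult:
    """OLS of one-year eGFR change with cluster-robust 95% CIs."""
    if not spec.is_linear:
        raise ConfigurationError("spec outcome must be 'delta_egfr' for a linear fit")
    y, X, groups = build_design(data, spec, **design_kwargs)
    res = _robust_fit(sm.OLS(y, X), spec, groups)
    return _extract_result(res, spec, data, scale="beta")


def fit_logistic_decline(data: pd.DataFrame, spec: ModelSpec, **design_kwargs) -> AssociationResult:
    """Logistic model of >=10 % eGFR decline; ORs with cluster-robust CIs."""
    if spec.is_linear:
        raise ConfigurationError("spec outcome must be 'decline' for a logistic fit")
    y, X, groups = build_design(data, spec, **design_kwargs)
    if y.nunique() < 2:
        raise SeparationError("outcome has a single level; logistic model undefined")
    if spec.coding == "categorical":
        cells = pd.crosstab(data[f"{spec.score}_category"].astype(str), y)
        if (cells == 0).any().any():
            empty = cells[(cells == 0).any(axis=1)].index.tolist()
            raise SeparationError(
                f"zero-event exposure category {empty}; odds ratios are not estimable"
            )
    res = _robust_fit(sm.Logit(y, X), spec, groups)
    return _extract_result(res, spec, data, scale="or")


def _extract_result(res, spec: ModelSpec, data: pd.DataFrame, *, scale: str) -> AssociationResult:
    ci = res.conf_int(alpha=0.05)
    params = res.params

    def triple(name):
        est, lo, hi = params[name], ci.loc[name, 0], ci.loc[name, 1]
        if scale == "or":
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        return (float(est), float(lo), float(hi))

    out = AssociationResult(
        score=spec.score,
        outcome=spec.outcome,
        tier=spec.tier,
        coding=spec.coding,
        scale=scale,
        n_obs=int(res.nobs),
    )
    if spec.coding == "categorical":
        null = 1.0 if scale == "or" else 0.0
        out.estimates["DecrMaint"] = (null, null, null)
        for cat in CHANGE_CATEGORIES[1:]:
            out.estimates[cat] = triple(cat)
        out.n_per_category = _category_counts(data, spec)
    else:
        out.continuous_estimate = triple("per_point")
    return out


def trend_test(data: pd.DataFrame, spec: ModelSpec) -> float:
    """Two-sided trend p-value: exposure coded as its category-median change.

    Each participant's exposure value is the median one-year change of their
    category; the model is refitted with this single continuous regressor and
    its cluster-robust p-value returned.
    """
    col = f"{spec.score}_category_median"
    if col not in data.columns:
        raise SchemaError(f"model data lacks column {col!r}")
    if data[col].nunique() < 2:
        raise ConfigurationError("all category medians are equal; trend is undefined")
    cont = ModelSpec(
        outcome=spec.outcome,
        score=spec.score,
        coding="continuous",
        tier=spec.tier,
        cluster=spec.cluster,
        small_sample_correction=spec.small_sample_correction,
    )
    y, X, groups = build_design(data, cont, exposure_col=col)
    model = sm.Logit(y, X) if not spec.is_linear else sm.OLS(y, X)
    res = _robust_fit(model, cont, groups)
    return float(res.pvalues["per_point"])


def interaction_lrt(data: pd.DataFrame, spec: ModelSpec, modifier: str):
    """Likelihood-ratio test for exposure-by-modifier interaction.

    Fits the spec's model with the modifier as an additional main effect,
    then again with exposure x modifier cross-product terms, and refers
    twice the log-likelihood difference to chi-square with one degree of
    freedom per added term. Returns ``(statistic, df, p_value)``.
    """
    if modifier not in data.columns:
        raise SchemaError(f"modifier column {modifier!r} not in data")
    mod = data[modifier]
    if mod.nunique() < 2:
        raise ConfigurationError(f"modifier {modifier!r} has fewer than 2 levels")

    y, X, _ = build_design(data, spec)
    if mod.dtype == object or isinstance(mod.dtype, pd.CategoricalDtype):
        levels = sorted(mod.astype(str).unique())
        mod_cols = _dummies(mod.astype(str), levels, f"mod_{modifier}")
    elif mod.dtype == bool or set(mod.unique()) <= {0, 1, True, False}:
        mod_cols = pd.DataFrame({f"mod_{modifier}": mod.astype(float)}, index=data.index)
    else:
        mod_cols = pd.DataFrame({f"mod_{modifier}": mod.astype(float)}, index=data.index)

    exposure_cols = [c for c in X.columns if c in CHANGE_CATEGORIES or c == "per_point"]

    def _add_if_independent(frame: pd.DataFrame, name: str, values) -> bool:
        candidate = frame.assign(**{name: values})
        if np.linalg.matrix_rank(candidate.to_numpy(dtype=float)) == candidate.shape[1]:
            frame[name] = np.asarray(values, dtype=float)
            return True
        return False

    # modifier main effect may already sit in the covariate tier (e.g. sex);
    # add it only where it is not collinear with existing columns
    X_base = X.copy()
    for c in mod_cols.columns:
        _add_if_independent(X_base, c, mod_cols[c])
    X_full = X_base.copy()
    added = 0
    for e in exposure_cols:
        for m in mod_cols.columns:
            if _add_if_independent(X_full, f"{e}:{m}", X[e].to_numpy() * mod_cols[m].to_numpy()):
                added += 1
    if added == 0:
        raise EstimationError(
            f"no estimable cross-product terms for modifier {modifier!r}"
        )

    model_cls = sm.OLS if spec.is_linear else sm.Logit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.is_linear:
            ll0 = model_cls(y, X_base).fit().llf
            ll1 = model_cls(y, X_full).fit().llf
        else:
            ll0 = model_cls(y, X_base).fit(disp=0, maxiter=200).llf
            ll1 = model_cls(y, X_full).fit(disp=0, maxiter=200).llf
    from scipy import stats

    statistic = float(2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(max(statistic, 0.0), added))
    return statistic, added, p


def item_removal_analysis(
    data: pd.DataFrame,
    *,
    score: str = "ermed17",
    tier: str = "M3",
    cluster: str = "center",
    n_items: int = 17,
    small_sample_correction: bool = True,
) -> tuple[list[ItemRemovalResult], AssociationResult, AssociationResult]:
    """Leave-one-item-out decomposition of the screener's association.

    For each of the 17 items, the item is removed from the score at both
    timepoints, both outcome models are refitted with the continuous
    16-item score change (adjusting additionally for the removed item's own
    one-year change, and using the 16-item baseline score in tier M3), and
    the coefficient (log odds ratio) is rescaled by 16/17. Percent change
    is relative to the full-score estimate.

    Returns ``(per-item results, full linear result, full logistic result)``.
    """
    work = data.copy()
    lin_spec = ModelSpec(
        outcome="delta_egfr", score=score, coding="continuous", tier=tier,
        cluster=cluster, small_sample_correction=small_sample_correction,
    )
    log_spec = ModelSpec(
        outcome="decline", score=score, coding="continuous", tier=tier,
        cluster=cluster, small_sample_correction=small_sample_correction,
    )
    full_lin = fit_linear_change(work, lin_spec)
    full_log = fit_logistic_decline(work, log_spec)
    full_beta = full_lin.continuous_estimate[0]
    full_or = full_log.continuous_estimate[0]

    results: list[ItemRemovalResult] = []
    for item in range(1, n_items + 1):
        b_col, y_col = f"ermed_item_{item}_baseline", f"ermed_item_{item}_year1"
        if b_col not in work.columns or y_col not in work.columns:
            raise SchemaError(f"item-removal needs columns {b_col!r} and {y_col!r}")
        try:
            item_delta = work[y_col].astype(float) - work[b_col].astype(float)
            work["_reduced_delta"] = work[f"{score}_delta"].astype(float) - item_delta
            work["_reduced_baseline"] = work[f"{score}_baseline"].astype(float) - work[b_col].astype(float)
            work["_item_delta"] = item_delta
            extra = ["_item_delta"] if item_delta.nunique() > 1 else []
            kwargs = dict(
                exposure_col="_reduced_delta",
                extra_covariates=extra,
                baseline_score_col="_reduced_baseline" if tier == "M3" else None,
            )
            lin = fit_linear_change(work, lin_spec, **kwargs)
            log = fit_logistic_decline(work, log_spec, **kwargs)
        except EstimationError as exc:
            raise EstimationError(f"item {item}: {exc}") from exc
        beta, beta_lo, beta_hi = lin.continuous_estimate
        or_, or_lo, or_hi = log.continuous_estimate
        scale = n_items - 1, n_items
        results.append(
            ItemRemovalResult(
                item=item,
                rescaled_beta=rescale_beta(beta, *scale),
                beta_ci=(rescale_beta(beta_lo, *scale), rescale_beta(beta_hi, *scale)),
                pct_change_beta=pct_change_vs_full(rescale_beta(beta, *scale), full_beta),
                rescaled_or=rescale_or(or_, *scale),
                or_ci=(rescale_or(or_lo, *scale), rescale_or(or_hi, *scale)),
                pct_change_or=pct_change_vs_full(rescale_or(or_, *scale), full_or, scale="or"),
            )
        )
    return results, full_lin, full_log


def item_removal_table(results: list[ItemRemovalResult]) -> pd.DataFrame:
    """Tidy table of the item-removal analysis."""
    return pd.DataFrame(
        {
            "item": [r.item for r in results],
            "rescaled_beta": [r.rescaled_beta for r in results],
            "beta_ci_low": [r.beta_ci[0] for r in results],
            "beta_ci_high": [r.beta_ci[1] for r in results],
            "pct_change_beta": [r.pct_change_beta for r in results],
            "rescaled_or": [r.rescaled_or for r in results],
            "or_ci_low": [r.or_ci[0] for r in results],
            "or_ci_high": [r.or_ci[1] for r in results],
            "pct_change_or": [r.pct_change_or for r in results],
        }
    )
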