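"""Synthetic two-timepoint cohort generator.

Emulates the table structure of an elderly Mediterranean intervention
cohort: men 55-75 and women 60-75 years, overweight/obese, recruited by a
modest number of centers, with food-group intakes and screener variables
measured at baseline and year 1. Intakes are log-normal (positive,
right-skewed, as food-frequency data are) with a participant-level latent
factor inducing baseline/year-1 correlation; screener item booleans are
derived from the generated dietary variables through the same criteria
table the scorer uses, so generated data and scores can never disagree.

Kidney function is generated *backwards* from the estimator: a baseline
creatinine draw fixes baseline eGFR through the CKD-EPI equation; the
year-1 eGFR target is baseline eGFR plus a configurable true effect of the
designated score's one-year change, a center random intercept sized to hit
a configurable intra-center correlation, a mean drift, and noise; year-1
creatinine is then obtained by numerically inverting CKD-EPI. The
generator and the estimator therefore share one eGFR definition exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .criteria import load_criteria
from .errors import ConfigurationError
from .reference import PopulationReference
from .renal import creatinine_for_egfr, egfr_ckdepi
from .scores import SCORE_NAMES, score_cohort

SCHEMA_VERSION = 1

#: (median g/day, log-scale sigma) for each food-group intake column.
#: Location targets are typical Mediterranean-cohort intakes; the energy
#: distribution is calibrated to a 2348 +/- 550 kcal/day cohort mean.
DEFAULT_INTAKES: dict[str, tuple[float, float]] = {
    "veg_g": (300.0, 0.45),
    "fruit_g": (330.0, 0.50),
    "nuts_g": (12.0, 0.80),
    "legumes_g": (20.0, 0.50),
    "cereals_potatoes_g": (180.0, 0.45),
    "fish_g": (90.0, 0.50),
    "meat_g": (130.0, 0.40),
    "dairy_g": (330.0, 0.55),
    "lowfat_dairy_g": (120.0, 0.80),
    "whole_grains_g": (25.0, 1.00),
    "sodium_g": (3.0, 0.35),
    "red_processed_meat_g": (90.0, 0.50),
    "ssb_g": (25.0, 1.20),
    "mufa_g": (45.0, 0.30),
    "sfa_g": (25.0, 0.30),
    "plant_protein_g": (32.0, 0.30),
    "animal_protein_g": (55.0, 0.35),
}

#: (median, log-scale sigma) for the screener's frequency variables
#: (units or servings per day/week, matching each criterion's scale).
DEFAULT_ITEM_VARIABLES: dict[str, tuple[float, float]] = {
    "veg_units_day": (2.0, 0.45),
    "fruit_units_day": (2.6, 0.50),
    "red_meat_serv_wk": (1.6, 0.70),
    "butter_serv_wk": (0.6, 1.10),
    "ssb_serv_wk": (0.8, 1.20),
    "legume_serv_wk": (2.6, 0.50),
    "fish_serv_wk": (3.0, 0.50),
    "sweets_serv_wk": (2.4, 0.80),
    "nuts_serv_wk": (2.8, 0.80),
    "sofrito_serv_wk": (2.0, 0.70),
    "white_bread_serv_day": (1.0, 0.80),
    "wholegrain_serv_wk": (2.0, 1.20),
    "refined_grain_serv_wk": (2.8, 0.70),
    "wine_glasses_day": (0.8, 1.00),
}

#: Probability of a "yes" for the screener's habit booleans.
DEFAULT_ITEM_BOOLEANS: dict[str, float] = {
    "evoo_only": 0.70,
    "lean_meat_pref": 0.60,
    "artif_sweetener_pref": 0.30,
}

DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "diabetes": 0.30,
    "hypertension": 0.84,
    "hypercholesterolemia": 0.70,
    "smoking_current": 0.13,
    "smoking_former": 0.43,
    "education_secondary": 0.28,
    "education_graduate": 0.22,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    n_participants: int = 1000
    n_centers: int = 23
    seed: int = 0
    sex_fraction_female: float = 0.48
    age_range_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (55.0, 75.0), "female": (60.0, 75.0)}
    )
    intake_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTAKES)
    )
    item_variable_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_VARIABLES)
    )
    item_boolean_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_BOOLEANS)
    )
    energy_distribution: tuple[float, float] = (2347.9, 549.5)  # mean, sd kcal/day
    protein_pct_distribution: tuple[float, float] = (16.9, 2.8)  # mean, sd % energy
    creatinine_distribution_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (0.92, 0.15), "female": (0.72, 0.15)}
    )
    true_effect_beta: float = 0.23  # ml/min/1.73m2 per 1-point score change
    effect_score: str = "ermed17"
    intra_center_icc: float = 0.02
    egfr_noise_sd: float = 7.0  # within-participant 1-year eGFR noise
    egfr_drift: float = -0.94  # population mean 1-year eGFR change
    longitudinal_corr: float = 0.5  # latent baseline/year-1 intake correlation
    boolean_persistence: float = 0.75
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    criteria_preset: str = "printed"

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_centers < 1 or self.n_centers > self.n_participants:
            raise ConfigurationError("n_centers must be in [1, n_participants]")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigurationError("sex_fraction_female must be in [0, 1]")
        if not 0.0 <= self.intra_center_icc < 1.0:
            raise ConfigurationError("intra_center_icc must be in [0, 1)")
        if self.egfr_noise_sd <= 0:
            raise ConfigurationError("egfr_noise_sd must be > 0")
        if not 0.0 <= self.longitudinal_corr < 1.0:
            raise ConfigurationError("longitudinal_corr must be in [0, 1)")
        if not 0.0 <= self.boolean_persistence <= 1.0:
            raise ConfigurationError("boolean_persistence must be in [0, 1]")
        if self.effect_score not in SCORE_NAMES:
            raise ConfigurationError(f"effect_score must be one of {SCORE_NAMES}")
        for name, dists in (
            ("intake_distributions", self.intake_distributions),
            ("item_variable_distributions", self.item_variable_distributions),
        ):
            for key, (med, sig) in dists.items():
                if med <= 0 or sig <= 0:
                    raise ConfigurationError(f"{name}[{key!r}] must have positive location and scale")
        for key, (med, sig) in self.creatinine_distribution_by_sex.items():
            if med <= 0 or sig <= 0:
                raise ConfigurationError(
                    f"creatinine_distribution_by_sex[{key!r}] must be positive"
                )
        if self.energy_distribution[0] <= 0 or self.energy_distribution[1] <= 0:
            raise ConfigurationError("energy_distribution must be positive (mean, sd)")
        if self.protein_pct_distribution[0] <= 0 or self.protein_pct_distribution[1] <= 0:
            raise ConfigurationError("protein_pct_distribution must be positive (mean, sd)")
        for key, p in {**self.covariate_prevalences, **self.item_boolean_prevalences}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence {key!r} must be in [0, 1]")
        for sex, (lo, hi) in self.age_range_by_sex.items():
            if not 0 < lo < hi:
                raise ConfigurationError(f"age_range_by_sex[{sex!r}] must be an increasing positive range")


@dataclass
class SyntheticCohort:
    """A generated cohort: the long table plus the ground truth that made it."""

    table: pd.DataFrame
    ground_truth: dict
    config: GeneratorConfig

    @property
    def n_participants(self) -> int:
        return self.table["participant_id"].nunique()

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort table (CSV) and ground-truth metadata (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_path = out / "cohort.csv"
        truth_path = out / "ground_truth.json"
        self.table.to_csv(table_path, index=False)
        payload = {"schema_version": SCHEMA_VERSION, **self.ground_truth}
        truth_path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
        return {"cohort": table_path, "ground_truth": truth_path}


def _correlated_lognormal(rng, median, sigma, n, rho):
    """Two timepoints of a log-normal variable with latent correlation rho."""
    z = rng.standard_normal(n)
    e0 = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    sqrt_r = np.sqrt(rho)
    sqrt_1r = np.sqrt(1.0 - rho)
    mu = np.log(median)
    x0 = np.exp(mu + sigma * (sqrt_r * z + sqrt_1r * e0))
    x1 = np.exp(mu + sigma * (sqrt_r * z + sqrt_1r * e1))
    return x0, x1


def _persistent_bernoulli(rng, p, n, persistence):
    b0 = rng.random(n) < p
    redraw = rng.random(n) >= persistence
    b1 = np.where(redraw, rng.random(n) < p, b0)
    return b0.astype(float), b1.astype(float)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a reproducible two-timepoint synthetic cohort.

    Fixed seed implies byte-identical output. See the module docstring for
    the generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    rho = config.longitudinal_corr

    pid = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < config.sex_fraction_female, "female", "male")
    age = np.empty(n)
    for s, (lo, hi) in config.age_range_by_sex.items():
        mask = sex == s
        age[mask] = rng.uniform(lo, hi, mask.sum())
    age = np.round(age, 1)

    # centers of unequal size (Dirichlet weights), every center non-empty
    weights = rng.dirichlet(np.full(config.n_centers, 4.0))
    center = rng.choice(config.n_centers, size=n, p=weights)
    for c in range(config.n_centers):
        if not np.any(center == c):
            center[rng.integers(n)] = c

    # covariates (baseline; treated as fixed over the single year)
    prev = config.covariate_prevalences
    bmi = np.clip(rng.normal(32.5, 3.5, n), 27.0, 40.0)
    height = np.where(sex == "female", rng.normal(1.58, 0.06, n), rng.normal(1.70, 0.07, n))
    weight0 = np.round(bmi * height**2, 1)
    weight1 = np.round(weight0 + rng.normal(-1.0, 3.0, n), 1)
    u = rng.random(n)
    smoking = np.where(
        u < prev["smoking_current"],
        "current",
        np.where(u < prev["smoking_current"] + prev["smoking_former"], "former", "never"),
    )
    u = rng.random(n)
    education = np.where(
        u < prev["education_graduate"],
        "graduate",
        np.where(u < prev["education_graduate"] + prev["education_secondary"], "secondary", "primary"),
    )
    phys_activity = np.exp(rng.normal(np.log(1800.0), 0.9, n))
    diabetes = rng.random(n) < prev["diabetes"]
    hypertension = rng.random(n) < prev["hypertension"]
    hypercholesterolemia = rng.random(n) < prev["hypercholesterolemia"]
    intervention = rng.random(n) < 0.5

    # energy: log-normal with the configured arithmetic mean and sd
    e_mean, e_sd = config.energy_distribution
    sigma2 = np.log1p((e_sd / e_mean) ** 2)
    e_sigma = np.sqrt(sigma2)
    e_median = np.exp(np.log(e_mean) - sigma2 / 2.0)
    energy0, energy1 = _correlated_lognormal(rng, e_median, e_sigma, n, rho)

    p_mean, p_sd = config.protein_pct_distribution
    z = rng.standard_normal(n)
    prot0 = p_mean + p_sd * (np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n))
    prot1 = p_mean + p_sd * (np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n))
    prot0 = np.clip(prot0, 5.0, 35.0)
    prot1 = np.clip(prot1, 5.0, 35.0)

    cols0: dict[str, np.ndarray] = {}
    cols1: dict[str, np.ndarray] = {}
    for name, (med, sig) in sorted(config.intake_distributions.items()):
        cols0[name], cols1[name] = _correlated_lognormal(rng, med, sig, n, rho)
    for name, (med, sig) in sorted(config.item_variable_distributions.items()):
        cols0[name], cols1[name] = _correlated_lognormal(rng, med, sig, n, rho)
    for name, p in sorted(config.item_boolean_prevalences.items()):
        cols0[name], cols1[name] = _persistent_bernoulli(rng, p, n, config.boolean_persistence)

    other0, other1 = _correlated_lognormal(rng, 2.0, 1.0, n, rho)
    for cols, other in ((cols0, other0), (cols1, other1)):
        # 10 g alcohol per glass of wine plus a small non-wine share
        cols["alcohol_g"] = cols["wine_glasses_day"] * 10.0 + other
        cols["fruits_nuts_g"] = cols["fruit_g"] + cols["nuts_g"]
        cols["legumes_nuts_g"] = cols["legumes_g"] + cols["nuts_g"]

    def assemble(timepoint, cols, energy, prot, age_tp, weight):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "timepoint": timepoint,
                "sex": sex,
                "age": age_tp,
                "center": center,
                "bmi": np.round(bmi, 2),
                "smoking": smoking,
                "education": education,
                "phys_activity": np.round(phys_activity, 1),
                "diabetes": diabetes,
                "hypertension": hypertension,
                "hypercholesterolemia": hypercholesterolemia,
                "intervention": intervention,
                "weight_kg": weight,
                "ffq_complete": True,
                "energy_kcal": np.round(energy, 1),
                "protein_pct_energy": np.round(prot, 2),
                **{k: np.round(v, 3) for k, v in sorted(cols.items())},
            }
        )

    base = assemble("baseline", cols0, energy0, prot0, age, weight0)
    year1 = assemble("year1", cols1, energy1, prot1, np.round(age + 1.0, 1), weight1)
    long = pd.concat([base, year1], ignore_index=True)

    # screener items derived from the generated variables through the same
    # criteria the scorer applies (consistency by construction)
    criteria = load_criteria(config.criteria_preset)
    ref = PopulationReference.from_cohort(long, timepoint="baseline")
    scored = score_cohort(long, ref, criteria, use_preanswered=False)
    for col in scored.columns:
        if col.startswith("ermed_item_"):
            long[col] = scored[col].astype(bool)

    delta = (
        scored.pivot(index="participant_id", columns="timepoint", values=config.effect_score)
        .loc[pid]
        .astype(float)
    )
    score_delta = (delta["year1"] - delta["baseline"]).to_numpy()

    # kidney function, generated backwards through CKD-EPI
    scr0 = np.empty(n)
    for s, (med, sig) in config.creatinine_distribution_by_sex.items():
        mask = sex == s
        scr0[mask] = np.exp(rng.normal(np.log(med), sig, mask.sum()))
    scr0 = np.clip(scr0, 0.3, 3.0)
    egfr0 = egfr_ckdepi(scr0, sex, age)

    icc = config.intra_center_icc
    sigma_b = config.egfr_noise_sd * np.sqrt(icc / (1.0 - icc))
    center_effects = rng.normal(0.0, sigma_b, config.n_centers) if sigma_b > 0 else np.zeros(config.n_centers)
    noise = rng.normal(0.0, config.egfr_noise_sd, n)
    egfr1 = (
        egfr0
        + config.egfr_drift
        + config.true_effect_beta * score_delta
        + center_effects[center]
        + noise
    )
    egfr1 = np.maximum(egfr1, 5.0)
    scr1 = creatinine_for_egfr(egfr1, sex, age + 1.0)

    long.loc[long["timepoint"] == "baseline", "creatinine_mgdl"] = scr0
    long.loc[long["timepoint"] == "year1", "creatinine_mgdl"] = scr1

    ground_truth = {
        "seed": config.seed,
        "true_effect_beta": config.true_effect_beta,
        "effect_score": config.effect_score,
        "intra_center_icc": config.intra_center_icc,
        "egfr_noise_sd": config.egfr_noise_sd,
        "egfr_drift": config.egfr_drift,
        "n_participants": n,
        "n_centers": config.n_centers,
        "center_effects": center_effects.tolist(),
        "target_egfr_baseline_mean": float(np.mean(egfr0)),
        "target_egfr_year1_mean": float(np.mean(egfr1)),
    }
    return SyntheticCohort(table=long, ground_truth=ground_truth, config=config)


def inject_exclusion_violations(
    cohort: SyntheticCohort,
    *,
    n_missing_ffq: int = 0,
    n_extreme_energy: int = 0,
    n_missing_creatinine: int = 0,
    overlap: bool = False,
    seed: int = 0,
) -> SyntheticCohort:
    """Return a copy of the cohort with exclusion-rule violations planted.

    Exactly the requested numbers of participants are marked as (a) missing
    the dietary questionnaire at year 1, (b) having extreme energy intake
    (men 4500 kcal/day, women 3800 kcal/day — both beyond the sex-specific
    upper bounds), and (c) missing year-1 creatinine. Violation sets are
    disjoint unless ``overlap=True``.
    """
    table = cohort.table.copy()
    pids = np.sort(table["participant_id"].unique())
    total = n_missing_ffq + n_extreme_energy + n_missing_creatinine
    n_avail = len(pids)
    if (not overlap and total > n_avail) or max(
        n_missing_ffq, n_extreme_energy, n_missing_creatinine
    ) > n_avail:
        raise ConfigurationError(
            f"requested {total} violations but the cohort has {n_avail} participants"
        )
    rng = np.random.default_rng(seed)
    if overlap:
        ffq_ids = rng.choice(pids, n_missing_ffq, replace=False)
        energy_ids = rng.choice(pids, n_extreme_energy, replace=False)
        creat_ids = rng.choice(pids, n_missing_creatinine, replace=False)
    else:
        chosen = rng.choice(pids, total, replace=False)
        ffq_ids = chosen[:n_missing_ffq]
        energy_ids = chosen[n_missing_ffq : n_missing_ffq + n_extreme_energy]
        creat_ids = chosen[n_missing_ffq + n_extreme_energy :]

    is_year1 = table["timepoint"] == "year1"
    is_base = table["timepoint"] == "baseline"
    table.loc[is_year1 & table["participant_id"].isin(ffq_ids), "ffq_complete"] = False
    energy_rows = is_base & table["participant_id"].isin(energy_ids)
    table.loc[energy_rows, "energy_kcal"] = np.where(
        table.loc[energy_rows, "sex"] == "male", 4500.0, 3800.0
    )
    table.loc[is_year1 & table["participant_id"].isin(creat_ids), "creatinine_mgdl"] = np.nan

    truth = dict(cohort.ground_truth)
    truth["injected_violations"] = {
        "missing_ffq": sorted(map(str, ffq_ids)),
        "extreme_energy": sorted(map(str, energy_ids)),
        "missing_creatinine": sorted(map(str, creat_ids)),
    }
    return SyntheticCohort(table=table, ground_truth=truth, config=replace(cohort.config))


def _criterion_satisfying_value(crit, sex: str, *, meet: bool) -> float:
    """A variable value that meets (or violates) one screener criterion."""
    t = crit.threshold
    if crit.op == "between":
        lo, hi = crit.bounds_by_sex[sex]
        return 0.5 * (lo + hi) if meet else hi + 1.0
    if meet:
        return {"ge": t, "gt": t + 1.0, "le": t, "lt": 0.5 * t}[crit.op]
    return {"ge": 0.5 * t, "gt": t, "le": t + 1.0, "lt": t}[crit.op]


def extreme_profile_record(
    ref: PopulationReference,
    criteria,
    *,
    kind: str = "max",
    sex: str = "male",
) -> dict:
    """A dietary profile at the admissible extreme of every score component.

    ``kind="max"`` builds a record meeting all 17 screener criteria, at or
    above the sex-specific median of every favorable Trichopoulou component
    and below it for unfavorable ones, inside the moderate-alcohol window,
    above the top quintile cutoff of favorable DASH components (below the
    first for unfavorable), and above the top undecile cutoff of both
    protein components — i.e. the (17, 9, 40, 20) profile relative to the
    given reference. ``kind="min"`` is the mirror-image (0, 0, 8, 0)
    profile. Useful for structural validation of the scoring stack.
    """
    if kind not in ("max", "min"):
        raise ConfigurationError("kind must be 'max' or 'min'")
    high = kind == "max"
    rec: dict = {"participant_id": "EXTREME", "timepoint": "baseline", "sex": sex, "age": 65.0}

    for crit in criteria:
        rec[crit.variable] = _criterion_satisfying_value(crit, sex, meet=high)

    def above(x):
        return 2.0 * abs(x) + 1.0

    def below(x):
        return 0.5 * x if x > 0 else 0.0

    from .reference import (  # local import to avoid cycle at module load
        DASH_FAVORABLE,
        DASH_UNFAVORABLE,
        TRICHOPOULOU_FAVORABLE,
        TRICHOPOULOU_UNFAVORABLE,
    )

    med = ref.sex_specific_medians
    for comp, col in TRICHOPOULOU_FAVORABLE.items():
        if comp == "mufa_sfa_ratio":
            continue
        m = med[(comp, sex)]
        rec[col] = above(m) if high else below(m)
    for comp, col in TRICHOPOULOU_UNFAVORABLE.items():
        m = med[(comp, sex)]
        rec[col] = below(m) if high else above(m)
    ratio_med = med[("mufa_sfa_ratio", sex)]
    rec["sfa_g"] = 10.0
    rec["mufa_g"] = (above(ratio_med) if high else below(ratio_med)) * rec["sfa_g"]
    lo_alc, hi_alc = (10.0, 50.0) if sex == "male" else (5.0, 25.0)
    rec["alcohol_g"] = 0.5 * (lo_alc + hi_alc) if high else 0.0

    for comp, col in DASH_FAVORABLE.items():
        cuts = ref.quintile_cutoffs[comp]
        rec[col] = above(cuts[-1]) if high else below(cuts[0])
    for comp, col in DASH_UNFAVORABLE.items():
        cuts = ref.quintile_cutoffs[comp]
        rec[col] = below(cuts[0]) if high else above(cuts[-1])
    # derived sums must stay consistent with their parts where both exist
    rec["fruit_g"] = rec.get("fruit_g", 0.0)
    rec["nuts_g"] = max(rec.get("fruits_nuts_g", 0.0) - rec["fruit_g"], 0.0)

    p_cuts = ref.undecile_cutoffs["protein_pct"]
    rec["protein_pct_energy"] = min(above(p_cuts[-1]), 99.0) if high else below(p_cuts[0])
    if not high and rec["protein_pct_energy"] <= 0:
        rec["protein_pct_energy"] = min(0.5 * p_cuts[0], 0.5)
    r_cuts = ref.undecile_cutoffs["plant_animal_ratio"]
    if high:
        rec["animal_protein_g"] = 1.0
        rec["plant_protein_g"] = above(r_cuts[-1])
    else:
        rec["animal_protein_g"] = 100.0
        rec["plant_protein_g"] = below(r_cuts[0]) * 100.0
    return rec


def empirical_icc(values, groups) -> float:
    """One-way ANOVA intraclass correlation ICC(1) of `values` by `groups`.

    Uses the standard mean-squares estimator with the unequal-group-size
    correction n0 = (N - sum(k_g^2)/N) / (G - 1).
    """
    v = np.asarray(values, dtype=float)
    g = pd.Series(groups)
    n_total = len(v)
    counts = g.value_counts()
    n_groups = len(counts)
    if n_groups < 2:
        raise ConfigurationError("ICC needs at least two groups")
    grand = v.mean()
    group_means = pd.Series(v).groupby(g.values).mean()
    group_counts = pd.Series(v).groupby(g.values).count()
    ssb = float((group_counts * (group_means - grand) ** 2).sum())
    ssw = float(((v - group_means.reindex(g.values).to_numpy()) ** 2).sum())
    msb = ssb / (n_groups - 1)
    msw = ssw / (n_total - n_groups)
    n0 = (n_total - float((counts**2).sum()) / n_total) / (n_groups - 1)
    return float((msb - msw) / (msb + (n0 - 1) * msw))
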