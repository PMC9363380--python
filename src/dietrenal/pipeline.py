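"""End-to-end orchestration: generate/load -> score -> outcomes -> models.

The pipeline turns a long-format cohort table (one row per
participant-timepoint) into a per-participant analysis frame, then fits the
nested association models for every requested score, tier and outcome, the
trend tests, and the screener item-removal decomposition, writing tidy
tables plus a manifest with checksums for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import apply_exclusions, categorize_change
from .criteria import load_criteria
from .errors import ConfigurationError, EstimationError
from .models import (
    ModelSpec,
    add_center_size_quartile,
    fit_linear_change,
    fit_logistic_decline,
    item_removal_analysis,
    item_removal_table,
    trend_test,
)
from .reference import PopulationReference
from .renal import add_renal_outcomes
from .scores import SCORE_NAMES, score_cohort, tidy_scores
from .simulate import GeneratorConfig, generate_cohort

STATIC_COLUMNS = (
    "sex",
    "age",
    "center",
    "bmi",
    "smoking",
    "education",
    "phys_activity",
    "diabetes",
    "hypertension",
    "hypercholesterolemia",
    "intervention",
)


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "dietrenal_run"
    seed: int = 0
    input_path: str | None = None  # CSV/parquet long cohort; None => generate
    generator: dict = field(default_factory=dict)
    criteria_preset: str = "printed"
    reference: str = "baseline"  # or "per-timepoint"
    decline_threshold: float = 10.0
    strict_decline: bool = False
    scores: tuple = SCORE_NAMES
    tiers: tuple = ("M1", "M2", "M3")
    cluster: str = "center"
    run_item_removal: bool = True
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file {path} does not exist")
        doc = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if cfg.reference not in ("baseline", "per-timepoint"):
            raise ConfigurationError("reference must be 'baseline' or 'per-timepoint'")
        return cfg


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input cohort file {path} does not exist")
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def build_analysis_frame(
    analytic: pd.DataFrame,
    *,
    criteria=None,
    reference: str = "baseline",
    decline_threshold: float = 10.0,
    strict_decline: bool = False,
    cluster: str = "center",
) -> pd.DataFrame:
    """Per-participant wide modelling frame from a long analytic cohort.

    Computes the population reference (baseline rows by default), scores
    both timepoints, appends eGFR outcomes and exposure-change categories
    for every score.
    """
    criteria = criteria or load_criteria()
    baseline = analytic[analytic["timepoint"] == "baseline"]
    year1 = analytic[analytic["timepoint"] == "year1"]

    ref0 = PopulationReference.from_cohort(baseline, timepoint=None)
    scored0 = score_cohort(baseline, ref0, criteria)
    if reference == "per-timepoint":
        ref1 = PopulationReference.from_cohort(year1, timepoint=None)
    else:
        ref1 = ref0
    scored1 = score_cohort(year1, ref1, criteria)

    wide = baseline.set_index("participant_id")[list(STATIC_COLUMNS)].copy()
    b = baseline.set_index("participant_id")
    y = year1.set_index("participant_id")
    wide["energy_kcal"] = b["energy_kcal"]
    wide["weight_change"] = y["weight_kg"] - b["weight_kg"]
    wide["creatinine_baseline"] = b["creatinine_mgdl"]
    wide["creatinine_year1"] = y["creatinine_mgdl"]

    s0 = scored0.set_index("participant_id")
    s1 = scored1.set_index("participant_id")
    for score in SCORE_NAMES:
        wide[f"{score}_baseline"] = s0[score]
        wide[f"{score}_year1"] = s1[score]
        wide[f"{score}_delta"] = s1[score] - s0[score]
    for i in range(1, 18):
        wide[f"ermed_item_{i}_baseline"] = s0[f"ermed_item_{i}"]
        wide[f"ermed_item_{i}_year1"] = s1[f"ermed_item_{i}"]

    wide = wide.reset_index()
    wide = add_renal_outcomes(wide, threshold=decline_threshold, strict=strict_decline)
    wide = add_center_size_quartile(wide, center_col=cluster)

    for score in SCORE_NAMES:
        cats = categorize_change(
            wide[["participant_id", f"{score}_delta"]].rename(columns={f"{score}_delta": "delta"})
        )
        wide[f"{score}_category"] = cats["category"].astype(str).to_numpy()
        wide[f"{score}_category_median"] = cats["category_median"].to_numpy()
    return wide


def association_table(results) -> pd.DataFrame:
    """Tidy table of AssociationResult objects."""
    rows = []
    for r in results:
        if r.coding == "categorical":
            for cat, (est, lo, hi) in r.estimates.items():
                rows.append(
                    {
                        "score": r.score, "outcome": r.outcome, "tier": r.tier,
                        "exposure": cat, "scale": r.scale, "estimate": est,
                        "ci_low": lo, "ci_high": hi, "p_trend": r.p_trend,
                        "n": (r.n_per_category or {}).get(cat),
                    }
                )
        else:
            est, lo, hi = r.continuous_estimate
            rows.append(
                {
                    "score": r.score, "outcome": r.outcome, "tier": r.tier,
                    "exposure": "per_point", "scale": r.scale, "estimate": est,
                    "ci_low": lo, "ci_high": hi, "p_trend": r.p_trend, "n": r.n_obs,
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)
    criteria = load_criteria(config.criteria_preset)

    if config.input_path is not None:
        long = load_cohort_table(config.input_path)
        ground_truth = None
    else:
        gen_kwargs = dict(config.generator)
        gen_kwargs.setdefault("seed", config.seed)
        gen = GeneratorConfig(**gen_kwargs)
        cohort = generate_cohort(gen)
        long = cohort.table
        ground_truth = cohort.ground_truth
        long.to_csv(out / "cohort.csv", index=False)

    analytic, flow = apply_exclusions(long)
    (out / "flow.txt").write_text(flow.report())
    (out / "flow.json").write_text(json.dumps(flow.to_dict(), indent=2) + "\n")

    frame = build_analysis_frame(
        analytic,
        criteria=criteria,
        reference=config.reference,
        decline_threshold=config.decline_threshold,
        strict_decline=config.strict_decline,
        cluster=config.cluster,
    )
    frame.to_csv(out / "analysis_frame.csv", index=False)

    scored_long = pd.concat(
        [
            frame[["participant_id"]].assign(timepoint=tp, **{
                s: frame[f"{s}_{tp}"] for s in SCORE_NAMES
            })
            for tp in ("baseline", "year1")
        ],
        ignore_index=True,
    )
    tidy_scores(scored_long).to_csv(out / "scores.csv", index=False)

    results = []
    for score in config.scores:
        for tier in config.tiers:
            for outcome, fit in (
                ("delta_egfr", fit_linear_change),
                ("decline", fit_logistic_decline),
            ):
                spec = ModelSpec(
                    outcome=outcome, score=score, coding="categorical",
                    tier=tier, cluster=config.cluster,
                )
                try:
                    res = fit(frame, spec)
                    res.p_trend = trend_test(frame, spec)
                except EstimationError as exc:
                    raise EstimationError(f"{score}/{tier}/{outcome}: {exc}") from exc
                results.append(res)
                cont = ModelSpec(
                    outcome=outcome, score=score, coding="continuous",
                    tier=tier, cluster=config.cluster,
                )
                results.append(fit(frame, cont))
    assoc = association_table(results)
    assoc.to_csv(out / "associations.csv", index=False)

    if config.run_item_removal and "ermed17" in config.scores:
        removal, full_lin, full_log = item_removal_analysis(frame, cluster=config.cluster)
        table = item_removal_table(removal)
        table.to_csv(out / "item_removal.csv", index=False)

    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "ground_truth": ground_truth,
        "outputs": {},
    }
    for path in sorted(out.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
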