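import numpy as np
import pandas as pd
import pytest

from dietrenal.criteria import load_criteria
from dietrenal.pipeline import build_analysis_frame
from dietrenal.cohort import apply_exclusions
from dietrenal.reference import PopulationReference
from dietrenal.simulate import GeneratorConfig, generate_cohort

#: A male record that satisfies every criterion of the printed screener
#: preset and has plausible intakes for all score components.
BASE_RECORD = dict(
    participant_id="R1",
    timepoint="baseline",
    sex="male",
    age=65.0,
    veg_g=300.0,
    fruit_g=300.0,
    nuts_g=10.0,
    fruits_nuts_g=310.0,
    legumes_g=20.0,
    legumes_nuts_g=30.0,
    cereals_potatoes_g=180.0,
    fish_g=90.0,
    meat_g=120.0,
    dairy_g=300.0,
    lowfat_dairy_g=100.0,
    whole_grains_g=30.0,
    sodium_g=3.0,
    red_processed_meat_g=80.0,
    ssb_g=20.0,
    mufa_g=45.0,
    sfa_g=25.0,
    alcohol_g=15.0,
    energy_kcal=2300.0,
    protein_pct_energy=17.0,
    plant_protein_g=30.0,
    animal_protein_g=55.0,
    evoo_only=1.0,
    veg_units_day=2.0,
    fruit_units_day=3.0,
    red_meat_serv_wk=1.0,
    butter_serv_wk=0.5,
    ssb_serv_wk=0.5,
    legume_serv_wk=3.0,
    fish_serv_wk=3.0,
    sweets_serv_wk=2.0,
    nuts_serv_wk=3.0,
    lean_meat_pref=1.0,
    sofrito_serv_wk=2.0,
    artif_sweetener_pref=1.0,
    white_bread_serv_day=1.0,
    wholegrain_serv_wk=5.0,
    refined_grain_serv_wk=2.0,
    wine_glasses_day=2.5,
)

#: Value overrides that make every screener criterion fail.
FAILING_ITEM_VALUES = dict(
    evoo_only=0.0,
    veg_units_day=1.0,
    fruit_units_day=1.0,
    red_meat_serv_wk=4.0,
    butter_serv_wk=2.0,
    ssb_serv_wk=3.0,
    legume_serv_wk=1.0,
    fish_serv_wk=1.0,
    sweets_serv_wk=5.0,
    nuts_serv_wk=1.0,
    lean_meat_pref=0.0,
    sofrito_serv_wk=1.0,
    artif_sweetener_pref=0.0,
    white_bread_serv_day=0.5,
    wholegrain_serv_wk=1.0,
    refined_grain_serv_wk=5.0,
    wine_glasses_day=0.0,
)


def make_record(**overrides) -> dict:
    rec = dict(BASE_RECORD)
    rec.update(overrides)
    return rec


@pytest.fixture(scope="session")
def criteria():
    return load_criteria("printed")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_participants=300, n_centers=8, seed=42))


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    return PopulationReference.from_cohort(small_cohort.table)


@pytest.fixture(scope="session")
def analysis_frame(small_cohort):
    """Per-participant modelling frame for the shared cohort."""
    analytic, _ = apply_exclusions(small_cohort.table)
    return build_analysis_frame(analytic)


def cohort_records(n: int, seed: int = 0, sexes=None, timepoint="baseline", **columns):
    """n random valid records with optional per-column overrides.

    ``columns`` values may be scalars (applied to all records) or sequences
    of length n; every other component varies randomly so that population
    references are well defined.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        rec = random_record(rng)
        rec["participant_id"] = f"P{i:04d}"
        rec["timepoint"] = timepoint
        if sexes is not None:
            rec["sex"] = sexes[i] if not isinstance(sexes, str) else sexes
        for col, vals in columns.items():
            rec[col] = float(vals) if np.isscalar(vals) else float(vals[i])
        records.append(rec)
    return records


def random_record(rng: np.random.Generator) -> dict:
    """A random but valid record, for property tests."""
    rec = make_record()
    for key, value in BASE_RECORD.items():
        if isinstance(value, float) and key not in ("age",):
            rec[key] = float(value * rng.uniform(0.2, 3.0))
    rec["sex"] = str(rng.choice(["male", "female"]))
    rec["fruits_nuts_g"] = rec["fruit_g"] + rec["nuts_g"]
    rec["legumes_nuts_g"] = rec["legumes_g"] + rec["nuts_g"]
    rec["protein_pct_energy"] = float(np.clip(rec["protein_pct_energy"], 1.0, 99.0))
    return rec
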