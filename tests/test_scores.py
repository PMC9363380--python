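from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietrenal.criteria import load_criteria
from dietrenal.errors import MissingDataError
from dietrenal.reference import PopulationReference
from dietrenal.scores import (
    SCORE_RANGES,
    dash_components,
    score_cohort,
    score_dash,
    score_ermed17,
    score_panel,
    score_protein_diet,
    score_trichopoulou,
)
from dietrenal.simulate import extreme_profile_record

from conftest import FAILING_ITEM_VALUES, cohort_records, make_record, random_record


# ---------------------------------------------------------------------------
# 17-item screener


def test_all_criteria_met_scores_seventeen(criteria):
    total, vec = score_ermed17(make_record(), criteria)
    assert total == 17
    assert vec.tolist() == [1] * 17


def test_no_criteria_met_scores_zero(criteria):
    total, vec = score_ermed17(make_record(**FAILING_ITEM_VALUES), criteria)
    assert total == 0
    assert vec.tolist() == [0] * 17


def test_exact_subset_of_items_met(criteria):
    # flip everything off, then re-satisfy items 2, 7 and 12 only
    rec = make_record(**FAILING_ITEM_VALUES)
    rec["veg_units_day"] = 2.0
    rec["legume_serv_wk"] = 3.0
    rec["sofrito_serv_wk"] = 2.0
    total, vec = score_ermed17(rec, criteria)
    assert total == 3
    assert [i + 1 for i, v in enumerate(vec) if v] == [2, 7, 12]


def test_preanswered_booleans_take_precedence(criteria):
    rec = make_record(**{f"ermed_item_{i}": 0 for i in range(1, 18)})
    total, _ = score_ermed17(rec, criteria)
    assert total == 0  # intakes say 17, pre-answered booleans say 0
    total2, _ = score_ermed17(rec, criteria, use_preanswered=False)
    assert total2 == 17


def test_unresolvable_item_error_names_the_item(criteria):
    rec = make_record()
    del rec["sofrito_serv_wk"]
    with pytest.raises(MissingDataError, match="item 12"):
        score_ermed17(rec, criteria)


# ---------------------------------------------------------------------------
# Trichopoulou


@pytest.fixture(scope="module")
def tri_ref():
    return PopulationReference.from_cohort(pd.DataFrame(cohort_records(60, seed=21)), timepoint=None)


def test_maximal_male_profile_scores_nine(tri_ref, criteria):
    rec = extreme_profile_record(tri_ref, criteria, kind="max", sex="male")
    rec["alcohol_g"] = 30.0  # inside the male 10-50 g/day window
    total, breakdown = score_trichopoulou(rec, tri_ref)
    assert total == 9
    assert all(v == 1 for v in breakdown.values())


def test_alcohol_window_is_sex_specific(tri_ref, criteria):
    man = extreme_profile_record(tri_ref, criteria, kind="max", sex="male")
    woman = extreme_profile_record(tri_ref, criteria, kind="max", sex="female")
    man["alcohol_g"] = 30.0
    woman["alcohol_g"] = 30.0  # above the female 5-25 g/day window
    assert score_trichopoulou(man, tri_ref)[1]["alcohol"] == 1
    assert score_trichopoulou(woman, tri_ref)[1]["alcohol"] == 0
    woman["alcohol_g"] = 15.0
    assert score_trichopoulou(woman, tri_ref)[1]["alcohol"] == 1


def test_favorable_component_at_exact_median_scores_one(tri_ref):
    rec = make_record(sex="male", veg_g=tri_ref.median("vegetables", "male"))
    _, breakdown = score_trichopoulou(rec, tri_ref)
    assert breakdown["vegetables"] == 1


def test_unfavorable_component_at_exact_median_scores_zero(tri_ref):
    rec = make_record(sex="male", meat_g=tri_ref.median("meat", "male"))
    _, breakdown = score_trichopoulou(rec, tri_ref)
    assert breakdown["meat"] == 0


def test_scale_invariance_of_median_anchored_components():
    records = cohort_records(60, seed=22)
    df = pd.DataFrame(records)
    ref = PopulationReference.from_cohort(df, timepoint=None)
    scaled = df.copy()
    scaled["veg_g"] = scaled["veg_g"] * 7.0
    ref_scaled = PopulationReference.from_cohort(scaled, timepoint=None)
    for i in range(len(df)):
        b1 = score_trichopoulou(df.iloc[i], ref)[1]
        b2 = score_trichopoulou(scaled.iloc[i], ref_scaled)[1]
        assert b1 == b2


# ---------------------------------------------------------------------------
# DASH


@pytest.fixture(scope="module")
def dash_ref():
    return PopulationReference.from_cohort(pd.DataFrame(cohort_records(100, seed=23)), timepoint=None)


def test_dash_extremes_hit_40_and_8(dash_ref, criteria):
    top = extreme_profile_record(dash_ref, criteria, kind="max")
    bottom = extreme_profile_record(dash_ref, criteria, kind="min")
    assert score_dash(top, dash_ref)[0] == 40
    assert score_dash(bottom, dash_ref)[0] == 8


def test_dash_middle_quintile_contributes_three(dash_ref):
    cuts = dash_ref.quintile_cutoffs["fruits"]
    rec = make_record(fruit_g=0.5 * (cuts[1] + cuts[2]))  # inside quintile 3
    _, breakdown = score_dash(rec, dash_ref)
    assert breakdown["fruits"] == 3


def test_dash_unfavorable_components_score_inversely(dash_ref):
    cuts = dash_ref.quintile_cutoffs["sodium"]
    low = make_record(sodium_g=cuts[0] * 0.5)
    high = make_record(sodium_g=cuts[-1] * 2.0)
    assert score_dash(low, dash_ref)[1]["sodium"] == 5
    assert score_dash(high, dash_ref)[1]["sodium"] == 1


def test_dash_quintiles_balanced_without_ties():
    n = 100
    records = cohort_records(n, seed=24)
    df = pd.DataFrame(records)
    ref = PopulationReference.from_cohort(df, timepoint=None)
    comp = dash_components(df, ref)
    for name in comp.columns:
        counts = comp[name].value_counts()
        # rank-based oracle: each of the 5 groups holds exactly n/5
        assert sorted(counts.tolist()) == [n // 5] * 5


# ---------------------------------------------------------------------------
# Protein diet score


@pytest.fixture(scope="module")
def pds_ref():
    return PopulationReference.from_cohort(pd.DataFrame(cohort_records(110, seed=25)), timepoint=None)


def test_protein_extremes(pds_ref, criteria):
    top = extreme_profile_record(pds_ref, criteria, kind="max")
    bottom = extreme_profile_record(pds_ref, criteria, kind="min")
    assert score_protein_diet(top, pds_ref)[0] == 20
    assert score_protein_diet(bottom, pds_ref)[0] == 0


def test_highest_protein_lowest_ratio_gives_ten(pds_ref, criteria):
    rec = extreme_profile_record(pds_ref, criteria, kind="max")
    rec["plant_protein_g"] = 0.01
    rec["animal_protein_g"] = 200.0  # ratio below the first cutoff
    total, breakdown = score_protein_diet(rec, pds_ref)
    assert breakdown["protein_pct"] == 10
    assert breakdown["plant_animal_ratio"] == 0
    assert total == 10


def test_zero_animal_protein_lands_in_top_ratio_stratum(pds_ref):
    rec = make_record(animal_protein_g=0.0, plant_protein_g=5.0)
    _, breakdown = score_protein_diet(rec, pds_ref)
    assert breakdown["plant_animal_ratio"] == 10


# ---------------------------------------------------------------------------
# Panel and properties


def test_panel_extremes_match_published_ranges(pds_ref, criteria):
    top = extreme_profile_record(pds_ref, criteria, kind="max")
    bottom = extreme_profile_record(pds_ref, criteria, kind="min")
    assert score_panel(top, pds_ref, criteria).as_tuple() == (17, 9, 40, 20)
    assert score_panel(bottom, pds_ref, criteria).as_tuple() == (0, 0, 8, 0)


def test_panel_totals_equal_component_scores_and_breakdown_sums(pds_ref, criteria):
    rng = np.random.default_rng(26)
    for _ in range(200):
        rec = random_record(rng)
        panel = score_panel(rec, pds_ref, criteria)
        assert panel.ermed17 == score_ermed17(rec, criteria)[0]
        assert panel.trichopoulou == score_trichopoulou(rec, pds_ref)[0]
        assert panel.dash == score_dash(rec, pds_ref)[0]
        assert panel.protein_diet == score_protein_diet(rec, pds_ref)[0]
        for name, total in zip(
            ("ermed17", "trichopoulou", "dash", "protein_diet"), panel.as_tuple()
        ):
            assert total == sum(panel.breakdown[name].values())


@lru_cache(maxsize=1)
def _property_reference():
    # hypothesis cannot request fixtures; build the shared reference once
    ref = PopulationReference.from_cohort(
        pd.DataFrame(cohort_records(110, seed=25)), timepoint=None
    )
    return ref, load_criteria()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_score_totals_stay_in_published_ranges(seed):
    ref, criteria = _property_reference()
    rec = random_record(np.random.default_rng(seed))
    panel = score_panel(rec, ref, criteria)
    for name, total in zip(("ermed17", "trichopoulou", "dash", "protein_diet"), panel.as_tuple()):
        lo, hi = SCORE_RANGES[name]
        assert lo <= total <= hi


def test_monotonicity_in_single_components(pds_ref, criteria):
    rng = np.random.default_rng(27)
    for _ in range(50):
        rec = random_record(rng)
        base = score_panel(rec, pds_ref, criteria)
        up = dict(rec)
        up["fruit_g"] = rec["fruit_g"] * 1.5  # favorable in DASH
        assert score_dash(up, pds_ref)[1]["fruits"] >= base.breakdown["dash"]["fruits"]
        worse = dict(rec)
        worse["red_processed_meat_g"] = rec["red_processed_meat_g"] * 1.5  # unfavorable
        assert (
            score_dash(worse, pds_ref)[1]["red_processed_meat"]
            <= base.breakdown["dash"]["red_processed_meat"]
        )
        more_veg = dict(rec)
        more_veg["veg_g"] = rec["veg_g"] * 1.5
        assert (
            score_trichopoulou(more_veg, pds_ref)[1]["vegetables"]
            >= base.breakdown["trichopoulou"]["vegetables"]
        )


def test_cohort_scoring_matches_record_scoring(pds_ref, criteria):
    df = pd.DataFrame(cohort_records(40, seed=28))
    scored = score_cohort(df, pds_ref, criteria)
    for i in range(0, 40, 7):
        rec = df.iloc[i]
        assert scored["ermed17"].iloc[i] == score_ermed17(rec, criteria)[0]
        assert scored["dash"].iloc[i] == score_dash(rec, pds_ref)[0]
        assert scored["trichopoulou"].iloc[i] == score_trichopoulou(rec, pds_ref)[0]
        assert scored["protein_diet"].iloc[i] == score_protein_diet(rec, pds_ref)[0]
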