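"""Survey-weighted intake estimation and the underreporting adjustment."""

import numpy as np
import pandas as pd
import pytest

from sodium_cra.intake import (
    UNTARGETED,
    adjust_underreporting,
    category_intake,
    population_mean,
    total_intake,
)


def _strata_two():
    return pd.DataFrame(
        {
            "stratum_id": ["F:25-29", "M:25-29"],
            "sex": ["F", "M"],
            "age_lo": [25, 25],
            "age_hi": [29, 29],
            "age_mid": [27.5, 27.5],
            "mean_sbp": [115.0, 117.0],
            "htn_prev": [0.1, 0.1],
            "htn_prev_se": [0.02, 0.02],
            "population": [1.0e5, 1.0e5],
        }
    )


def _composition():
    return pd.DataFrame(
        {
            "food_id": ["bread1", "meat1", "other1"],
            "category_id": ["bread", "processed_meat", UNTARGETED],
            "sodium_mg_per_100g": [500.0, 1000.0, 200.0],
        }
    )


def test_single_person_single_food_definitional():
    recalls = pd.DataFrame(
        {
            "person_id": ["p1"],
            "stratum_id": ["F:25-29"],
            "survey_weight": [2.0],
            "food_id": ["bread1"],
            "grams_per_day": [200.0],
        }
    )
    out = category_intake(recalls, _composition())
    bread = out[out["category_id"] == "bread"].iloc[0]
    assert bread["mean_mg"] == pytest.approx(1000.0)  # 200 g x 500 mg/100 g
    assert bread["se_mg"] == pytest.approx(0.0)


def test_identical_persons_have_zero_se():
    recalls = pd.DataFrame(
        {
            "person_id": ["p1", "p2", "p3"],
            "stratum_id": ["F:25-29"] * 3,
            "survey_weight": [1.0, 2.0, 0.5],
            "food_id": ["meat1"] * 3,
            "grams_per_day": [100.0] * 3,
        }
    )
    out = category_intake(recalls, _composition())
    meat = out[out["category_id"] == "processed_meat"].iloc[0]
    assert meat["mean_mg"] == pytest.approx(1000.0)
    assert meat["se_mg"] == pytest.approx(0.0)


def _random_survey(rng, n=80):
    foods = _composition()["food_id"].tolist()
    rows = []
    for i in range(n):
        stratum = "F:25-29" if i % 2 == 0 else "M:25-29"
        w = float(rng.uniform(0.5, 3.0))
        for food in rng.choice(foods, size=rng.integers(1, 4), replace=False):
            rows.append(
                {
                    "person_id": f"p{i}",
                    "stratum_id": stratum,
                    "survey_weight": w,
                    "food_id": food,
                    "grams_per_day": float(rng.gamma(3.0, 40.0)),
                }
            )
    return pd.DataFrame(rows)


def test_matches_bruteforce_weighted_mean():
    rng = np.random.default_rng(11)
    recalls = _random_survey(rng)
    comp = _composition()
    out = category_intake(recalls, comp)

    merged = recalls.merge(comp, on="food_id")
    merged["mg"] = merged["grams_per_day"] * merged["sodium_mg_per_100g"] / 100.0
    for _, row in out.iterrows():
        persons = recalls[recalls["stratum_id"] == row["stratum_id"]][
            ["person_id", "survey_weight"]
        ].drop_duplicates("person_id")
        num = den = 0.0
        for _, p in persons.iterrows():
            y = merged[
                (merged["person_id"] == p["person_id"])
                & (merged["category_id"] == row["category_id"])
            ]["mg"].sum()
            num += p["survey_weight"] * y
            den += p["survey_weight"]
        assert row["mean_mg"] == pytest.approx(num / den)


def test_duplicating_persons_with_halved_weights_is_invariant():
    rng = np.random.default_rng(5)
    recalls = _random_survey(rng, n=40)
    dup = recalls.copy()
    dup["person_id"] = dup["person_id"] + "_copy"
    doubled = pd.concat([recalls, dup], ignore_index=True)
    doubled["survey_weight"] /= 2.0
    a = category_intake(recalls, _composition()).set_index(["stratum_id", "category_id"])
    b = category_intake(doubled, _composition()).set_index(["stratum_id", "category_id"])
    np.testing.assert_allclose(a["mean_mg"], b["mean_mg"])


def test_unmapped_food_is_a_hard_error():
    recalls = pd.DataFrame(
        {
            "person_id": ["p1"],
            "stratum_id": ["F:25-29"],
            "survey_weight": [1.0],
            "food_id": ["mystery"],
            "grams_per_day": [10.0],
        }
    )
    with pytest.raises(KeyError, match="mystery"):
        category_intake(recalls, _composition())


def _adjustable_intakes():
    # one stratum per sex, two categories, recall totals 2000 mg/d each sex
    return pd.DataFrame(
        {
            "stratum_id": ["F:25-29", "F:25-29", "M:25-29", "M:25-29"],
            "category_id": ["bread", UNTARGETED] * 2,
            "mean_mg": [800.0, 1200.0, 900.0, 1100.0],
            "se_mg": [40.0, 60.0, 45.0, 55.0],
            "weight": [10.0, 10.0, 12.0, 12.0],
        }
    )


def test_adjustment_factor_arithmetic_and_identity():
    strata = _strata_two()
    urinary = {"F": 3200.0, "M": 3200.0}
    adjusted, factors = adjust_underreporting(_adjustable_intakes(), strata, urinary, 0.85)
    # recall total 2000, target 0.85 * 3200 = 2720 -> factor 1.36
    assert factors["F"] == pytest.approx(1.36)
    sex_total = adjusted[adjusted["stratum_id"] == "F:25-29"]["mean_mg"].sum()
    assert sex_total == pytest.approx(0.85 * 3200.0)
    # already-calibrated recall: factor exactly 1
    _, f2 = adjust_underreporting(
        _adjustable_intakes(), strata, {"F": 2000.0 / 0.85, "M": 2000.0 / 0.85}, 0.85
    )
    assert f2["F"] == pytest.approx(1.0)
    assert f2["M"] == pytest.approx(1.0)


def test_lower_share_rescales_uniformly():
    strata = _strata_two()
    urinary = {"F": 3200.0, "M": 4000.0}
    hi, _ = adjust_underreporting(_adjustable_intakes(), strata, urinary, 0.85)
    lo, _ = adjust_underreporting(_adjustable_intakes(), strata, urinary, 0.75)
    np.testing.assert_allclose(lo["mean_mg"], hi["mean_mg"] * 75.0 / 85.0)
    # uniform scaling preserves each category's share within a sex
    for stratum in ("F:25-29", "M:25-29"):
        h = hi[hi["stratum_id"] == stratum].set_index("category_id")["mean_mg"]
        l = lo[lo["stratum_id"] == stratum].set_index("category_id")["mean_mg"]
        np.testing.assert_allclose(h / h.sum(), l / l.sum())


def test_total_intake_sums_categories_and_population_mean():
    totals = total_intake(_adjustable_intakes())
    f = totals[totals["stratum_id"] == "F:25-29"].iloc[0]
    assert f["mean_mg"] == pytest.approx(2000.0)
    assert f["se_mg"] == pytest.approx(np.sqrt(40.0**2 + 60.0**2))
    grand = population_mean(totals)
    assert grand == pytest.approx((2000.0 * 10 + 2000.0 * 12) / 22.0)


def test_generated_survey_recovers_known_total(inputs, synth_config):
    """End-to-end: adjusted sex totals hit share x urinary exactly."""
    raw = category_intake(inputs.recalls, inputs.composition, inputs.strata)
    adjusted, _ = adjust_underreporting(
        raw, inputs.strata, inputs.urinary_mean_by_sex, 0.85
    )
    totals = total_intake(adjusted)
    sex_of = inputs.strata.set_index("stratum_id")["sex"]
    for sex, expect in inputs.urinary_mean_by_sex.items():
        sub = totals[totals["stratum_id"].map(sex_of) == sex]
        got = np.average(sub["mean_mg"], weights=sub["weight"])
        assert got == pytest.approx(0.85 * expect, rel=1e-9)
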