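"""Sales-weighted means, target clamping, weighted quantiles, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sodium_cra.reformulation import (
    TargetSet,
    apply_targets,
    compliance_stats,
    derive_percentile_targets,
    proportional_reduction,
    reformulation_effects,
    sales_weighted_mean,
    scenario_intake_change,
    weighted_quantile,
)


def _supply(densities, kgs, category="snacks", companies=None):
    n = len(densities)
    companies = companies or [f"C{i}" for i in range(n)]
    products = pd.DataFrame(
        {
            "product_id": [f"p{i}" for i in range(n)],
            "company_id": companies,
            "company_type": ["manufacturer"] * n,
            "category_id": [category] * n,
            "sodium_mg_per_100g": densities,
        }
    )
    sales = pd.DataFrame({"product_id": [f"p{i}" for i in range(n)], "kg_per_year": kgs})
    return products, sales


def test_sales_weighted_mean_examples():
    products, sales = _supply([400.0, 800.0], [3.0, 1.0])
    assert sales_weighted_mean(products, sales, "snacks") == pytest.approx(500.0)
    products, sales = _supply([400.0, 800.0], [2.0, 2.0])
    assert sales_weighted_mean(products, sales, "snacks") == pytest.approx(600.0)
    products, sales = _supply([640.0], [5.0])
    assert sales_weighted_mean(products, sales, "snacks") == pytest.approx(640.0)
    with pytest.raises(ValueError):
        sales_weighted_mean(*_supply([400.0], [0.0]), "snacks")


def test_apply_targets_clamps_only_above():
    products, _ = _supply([800.0, 400.0], [1.0, 1.0])
    ts = TargetSet("t", {"snacks": 500.0})
    out = apply_targets(products, ts)
    assert out["sodium_mg_per_100g"].tolist() == [500.0, 400.0]
    # uncovered category untouched
    other = products.assign(category_id="uncovered")
    np.testing.assert_allclose(
        apply_targets(other, ts)["sodium_mg_per_100g"], other["sodium_mg_per_100g"]
    )


def test_post_reformulation_compliance_is_total():
    products, sales = _supply([800.0, 400.0, 650.0], [1.0, 2.0, 3.0])
    ts = TargetSet("t", {"snacks": 500.0})
    post = apply_targets(products, ts)
    stats = compliance_stats(post, sales, ts)
    assert stats["frac_products"].tolist() == [1.0]
    assert stats["frac_sales"].tolist() == [1.0]


def test_proportional_reduction_examples():
    assert proportional_reduction(500.0, 425.0) == pytest.approx(0.15)
    assert proportional_reduction(500.0, 500.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        proportional_reduction(0.0, 0.0)


def test_effects_match_bruteforce_on_random_tables():
    rng = np.random.default_rng(2)
    densities = rng.lognormal(6.0, 0.5, size=12)
    kgs = rng.lognormal(10.0, 1.0, size=12)
    products, sales = _supply(densities.tolist(), kgs.tolist())
    ts = TargetSet("t", {"snacks": float(np.median(densities))})
    eff = reformulation_effects(products, sales, ts).iloc[0]
    clamped = np.minimum(densities, ts.targets["snacks"])
    pre = float((densities * kgs).sum() / kgs.sum())
    post = float((clamped * kgs).sum() / kgs.sum())
    assert eff["pre_mg_per_100g"] == pytest.approx(pre)
    assert eff["post_mg_per_100g"] == pytest.approx(post)
    assert eff["reduction"] == pytest.approx(1.0 - post / pre)
    assert 0.0 <= eff["reduction"] <= 1.0


def test_weighted_quantile_rule_and_invariances():
    # equal sales: cumulative shares 0.25, 0.5, 0.75, 1.0 -> q=0.25 picks 100
    assert weighted_quantile([100, 200, 300, 400], [1, 1, 1, 1], 0.25) == 100.0
    assert weighted_quantile([7.0, 7.0, 7.0], [1, 2, 3], 0.5) == 7.0
    v, w = [300.0, 100.0, 200.0], [1.0, 5.0, 2.0]
    assert weighted_quantile(v, w, 0.25) == weighted_quantile(v, [2 * x for x in w], 0.25)
    with pytest.raises(ValueError):
        weighted_quantile([1.0], [1.0], 1.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(1.0, 2000.0, allow_nan=False),
            st.floats(0.1, 100.0, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    ),
    q=st.floats(0.01, 0.99),
)
def test_weighted_quantile_against_bruteforce_oracle(data, q):
    values = [v for v, _ in data]
    weights = [w for _, w in data]
    got = weighted_quantile(values, weights, q)
    # oracle: scan values in sorted order until cumulative share >= q
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(weights)
    cum = 0.0
    expected = values[order[-1]]
    for i in order:
        cum += weights[i]
        if cum / total >= q:
            expected = values[i]
            break
    assert got == expected
    # the defining property: at least q of the weight lies at or below
    at_or_below = sum(w for v, w in data if v <= got)
    assert at_or_below / total >= q - 1e-12


def test_percentile_targets_sales_compliance_at_least_q():
    rng = np.random.default_rng(9)
    products, sales = _supply(
        rng.lognormal(6.5, 0.4, size=30).tolist(), rng.lognormal(9.0, 1.2, size=30).tolist()
    )
    ts = derive_percentile_targets(products, sales, q=0.25)
    stats = compliance_stats(products, sales, ts)
    assert (stats["frac_sales"] >= 0.25).all()


def _cat_intakes():
    return pd.DataFrame(
        {
            "stratum_id": ["s1", "s1", "s2", "s2"],
            "category_id": ["snacks", "bread", "snacks", "bread"],
            "mean_mg": [1000.0, 500.0, 800.0, 700.0],
            "se_mg": [10.0] * 4,
            "weight": [5.0] * 4,
        }
    )


def test_intake_change_arithmetic_and_errors():
    effects = pd.DataFrame({"category_id": ["snacks"], "reduction": [0.1]})
    per_stratum, per_sc = scenario_intake_change(_cat_intakes(), effects)
    assert per_stratum.set_index("stratum_id")["delta_mg"].loc["s1"] == pytest.approx(100.0)
    null = pd.DataFrame({"category_id": ["snacks", "bread"], "reduction": [0.0, 0.0]})
    zero, _ = scenario_intake_change(_cat_intakes(), null)
    assert (zero["delta_mg"] == 0).all()
    with pytest.raises(KeyError):
        scenario_intake_change(
            _cat_intakes(), pd.DataFrame({"category_id": ["soup"], "reduction": [0.1]})
        )


def test_stricter_targets_never_decrease_reductions():
    rng = np.random.default_rng(4)
    for trial in range(10):
        densities = rng.lognormal(6.3, 0.5, size=15).tolist()
        kgs = rng.lognormal(9.0, 1.0, size=15).tolist()
        products, sales = _supply(densities, kgs)
        lo, hi = np.quantile(densities, [0.2, 0.7])
        lenient = TargetSet("lenient", {"snacks": float(hi)})
        strict = TargetSet("strict", {"snacks": float(lo)})
        r_len = reformulation_effects(products, sales, lenient)["reduction"].iloc[0]
        r_str = reformulation_effects(products, sales, strict)["reduction"].iloc[0]
        assert r_str >= r_len - 1e-12


def test_company_scope_is_additive_and_dominated():
    rng = np.random.default_rng(8)
    n = 16
    densities = rng.lognormal(6.3, 0.5, size=n).tolist()
    kgs = rng.lognormal(9.0, 1.0, size=n).tolist()
    companies = [f"C{i % 4}" for i in range(n)]  # shared category across companies
    products, sales = _supply(densities, kgs, companies=companies)
    ts = TargetSet("t", {"snacks": float(np.quantile(densities, 0.3))})
    intakes = pd.DataFrame(
        {
            "stratum_id": ["s1"],
            "category_id": ["snacks"],
            "mean_mg": [1000.0],
            "se_mg": [10.0],
            "weight": [1.0],
        }
    )
    eff_all = reformulation_effects(products, sales, ts)
    delta_all, _ = scenario_intake_change(intakes, eff_all)
    total = delta_all["delta_mg"].iloc[0]
    parts = []
    for company in sorted(set(companies)):
        eff_c = reformulation_effects(products, sales, ts, company=company)
        d, _ = scenario_intake_change(intakes, eff_c)
        parts.append(d["delta_mg"].iloc[0])
        assert d["delta_mg"].iloc[0] <= total + 1e-9  # single company never exceeds all
    # clamping is per product and the sales-weighted mean is linear, so
    # single-company effects add exactly even within a shared category
    assert sum(parts) == pytest.approx(total)

    # disjoint case: each company in its own category
    products2 = products.assign(
        category_id=[f"cat_{c}" for c in companies]
    )
    ts2 = TargetSet(
        "t2",
        {
            f"cat_{c}": float(
                np.quantile(
                    products2[products2["category_id"] == f"cat_{c}"]["sodium_mg_per_100g"], 0.3
                )
            )
            for c in set(companies)
        },
    )
    intakes2 = pd.DataFrame(
        {
            "stratum_id": ["s1"] * 4,
            "category_id": sorted({f"cat_{c}" for c in companies}),
            "mean_mg": [500.0] * 4,
            "se_mg": [5.0] * 4,
            "weight": [1.0] * 4,
        }
    )
    eff2 = reformulation_effects(products2, sales, ts2)
    total2 = scenario_intake_change(intakes2, eff2)[0]["delta_mg"].iloc[0]
    parts2 = sum(
        scenario_intake_change(
            intakes2, reformulation_effects(products2, sales, ts2, company=c)
        )[0]["delta_mg"].iloc[0]
        for c in sorted(set(companies))
    )
    assert parts2 == pytest.approx(total2)
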