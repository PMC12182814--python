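"""Survival machinery: KM product-limit, log-rank oracle, Cox properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lvmech.survival import cox_fit, forest_table, km_estimate, logrank_pairwise


def records(times, events, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"time_months": times, "event": events})
    for k, v in extra.items():
        df[k] = v
    return df


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    sub = km[km["time"] <= t]
    return float(sub["survival"].iloc[-1])


def logrank_oracle(t1, e1, t2, e2) -> float:
    """Brute-force two-group log-rank via hypergeometric accumulation."""
    df = pd.DataFrame({"t": np.concatenate([t1, t2]),
                       "e": np.concatenate([e1, e2]),
                       "g": [0] * len(t1) + [1] * len(t2)})
    o_minus_e, var = 0.0, 0.0
    for t in np.sort(df.loc[df.e == 1, "t"].unique()):
        at_risk = df[df.t >= t]
        n = len(at_risk)
        n1 = int((at_risk.g == 1).sum())
        d = int(((at_risk.t == t) & (at_risk.e == 1)).sum())
        d1 = int(((at_risk.t == t) & (at_risk.e == 1) & (at_risk.g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return float(stats.chi2.sf(chi2, 1))


def test_km_no_events_is_flat_one():
    km = km_estimate(records([3.0, 5.0, 9.0], [0, 0, 0]))
    assert (km["survival"] == 1.0).all()


def test_km_all_events_closed_form():
    km = km_estimate(records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
    for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
        assert km_survival_at(km, t) == pytest.approx(s)


def test_km_hand_product_with_censoring():
    # times 1, 2+, 3: S(1) = 2/3, unchanged at 2+, S(3) = 2/3 * (1 - 1/1) = 0
    km = km_estimate(records([1.0, 2.0, 3.0], [1, 0, 1]))
    assert km_survival_at(km, 1) == pytest.approx(2.0 / 3.0)
    assert km_survival_at(km, 2) == pytest.approx(2.0 / 3.0)
    assert km_survival_at(km, 3) == pytest.approx(0.0)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(10.0, size=40)
    km = km_estimate(records(t, np.ones(40, dtype=int)))
    for q in [np.quantile(t, x) for x in (0.2, 0.5, 0.8)]:
        assert km_survival_at(km, q) == pytest.approx((t > q).mean())


def test_km_monotone_and_grouped():
    rng = np.random.default_rng(1)
    df = records(rng.exponential(10, 60), rng.integers(0, 2, 60),
                 cluster=np.repeat([1, 2, 3], 20))
    km = km_estimate(df, group_col="cluster")
    for _, sub in km.groupby("group"):
        assert (np.diff(sub.sort_values("time")["survival"]) <= 1e-12).all()
    assert set(km["group"]) == {1, 2, 3}


def test_logrank_identical_groups_p_one():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 1])
    df = records(np.tile(t, 2), np.tile(e, 2), cluster=np.repeat([1, 2], 4))
    p = logrank_pairwise(df)
    assert p.loc[1, 2] == pytest.approx(1.0)
    assert p.loc[2, 1] == p.loc[1, 2]
    assert np.isnan(p.loc[1, 1])


def test_logrank_matches_hypergeometric_oracle():
    rng = np.random.default_rng(5)
    t1, t2 = rng.exponential(10, 30), rng.exponential(20, 25)
    e1, e2 = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
    df = records(np.concatenate([t1, t2]), np.concatenate([e1, e2]),
                 cluster=np.concatenate([np.ones(30, int), 2 * np.ones(25, int)]))
    p = logrank_pairwise(df)
    assert p.loc[1, 2] == pytest.approx(logrank_oracle(t1, e1, t2, e2), rel=1e-6)


def test_logrank_pair_count_for_k_groups():
    rng = np.random.default_rng(2)
    df = records(rng.exponential(10, 80), rng.integers(0, 2, 80),
                 cluster=np.repeat([1, 2, 3, 4], 20))
    p = logrank_pairwise(df)
    off_diag = p.to_numpy()[~np.eye(4, dtype=bool)]
    assert np.isfinite(off_diag).sum() == 12  # k(k-1)/2 unordered pairs, mirrored


def test_cox_null_covariate_near_zero():
    rng = np.random.default_rng(3)
    n = 500
    df = records(rng.exponential(20, n), np.ones(n, int),
                 x=rng.normal(size=n))
    fit = cox_fit(df, ["x"], scale="per_unit")
    assert abs(fit.summary.loc["x", "coef"]) < 3 * fit.summary.loc["x", "se"]


def test_cox_matches_closed_form_exponential_mle():
    rng = np.random.default_rng(7)
    n = 1000
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
    assert len(np.unique(t)) == n  # tie-free
    fit = cox_fit(records(t, np.ones(n, int), x=x), ["x"], scale="per_unit")
    d1, d0 = int((x == 1).sum()), int((x == 0).sum())
    mle = np.log((d1 / t[x == 1].sum()) / (d0 / t[x == 0].sum()))
    assert fit.summary.loc["x", "coef"] == pytest.approx(mle, rel=0.05)


def test_cox_agrees_with_independent_breslow_fit():
    # tie-free sample: Breslow, Efron, and exact partial likelihoods coincide;
    # cross-check against statsmodels PHReg as an independent implementation
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    n = 300
    x = rng.normal(size=(n, 2))
    t = rng.exponential(1.0 / (0.05 * np.exp(x @ [0.5, -0.3])))
    e = (rng.random(n) < 0.8).astype(int)
    df = records(t, e, a=x[:, 0], b=x[:, 1])
    fit = cox_fit(df, ["a", "b"], scale="per_unit")
    ref = sm.PHReg(t, x, status=e, ties="breslow").fit()
    assert fit.summary["coef"].to_numpy() == pytest.approx(ref.params, abs=1e-4)


def test_cox_scaling_and_ci_consistency():
    rng = np.random.default_rng(9)
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * x)))
    df = records(t, np.ones(n, int), x=x, x10=10 * x)
    f1 = cox_fit(df, ["x"], scale="per_unit")
    f10 = cox_fit(df, ["x10"], scale="per_unit")
    assert f10.summary.loc["x10", "coef"] == pytest.approx(
        f1.summary.loc["x", "coef"] / 10.0)
    assert f10.log_likelihood == pytest.approx(f1.log_likelihood)
    row = f1.summary.loc["x"]
    assert row["ci_lower"] == pytest.approx(np.exp(row["coef"] - 1.96 * row["se"]))
    assert row["hazard_ratio"] == pytest.approx(np.exp(row["coef"]))


def test_cox_input_validation():
    df = records([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 2.0, 3.0])
    df["y"] = 2 * df["x"]
    with pytest.raises(ValueError, match="collinear"):
        cox_fit(df, ["x", "y"])
    with pytest.raises(ValueError, match="event"):
        cox_fit(records([1.0, 2.0], [0, 0], x=[0.0, 1.0]), ["x"])
    with pytest.raises(ValueError, match="positive"):
        cox_fit(records([0.0, 2.0], [1, 1], x=[0.0, 1.0]), ["x"])


def test_forest_table_sorted_and_order_invariant():
    rng = np.random.default_rng(13)
    n = 300
    x = rng.normal(size=(n, 3))
    t = rng.exponential(1.0 / (0.05 * np.exp(x @ [0.6, 0.0, -0.4])))
    df = records(t, np.ones(n, int), a=x[:, 0], b=x[:, 1], c=x[:, 2])
    tab1 = forest_table(cox_fit(df, ["a", "b", "c"]))
    tab2 = forest_table(cox_fit(df, ["c", "b", "a"]))
    assert (tab1["hazard_ratio"].diff().dropna() <= 0).all()
    assert tab1["covariate"].to_list() == tab2["covariate"].to_list()
    assert tab1["hazard_ratio"].to_numpy() == pytest.approx(
        tab2["hazard_ratio"].to_numpy())
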