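"""Statistical machinery: CIs, sphericity, RM-ANOVA, factorial effects, Sidak."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thermosih.sih_stats import (
    StatsError,
    between_anova,
    delta_t,
    gg_epsilon,
    mauchly_w,
    mean_ci,
    rm_time_anova,
    sidak,
)
from thermosih.sih_stats import testing_order_contrast as order_contrast
from thermosih.synthetic import ScenarioConfig, simulate_latent_table


# -- mean_ci ---------------------------------------------------------------


def test_mean_ci_matches_t_formula():
    m, lo, hi = mean_ci([1.0, 2.0, 3.0, 4.0])
    sd = np.std([1, 2, 3, 4], ddof=1)
    half = sps.t.ppf(0.975, 3) * sd / 2.0
    assert m == pytest.approx(2.5)
    assert hi - m == pytest.approx(half)
    assert m - lo == pytest.approx(half)


def test_mean_ci_constant_zero_width():
    m, lo, hi = mean_ci([5.0] * 6)
    assert lo == hi == m == 5.0


def test_mean_ci_requires_two_values():
    with pytest.raises(StatsError):
        mean_ci([1.0])


# -- delta_t ---------------------------------------------------------------


def test_delta_sign_convention():
    assert delta_t({0: 37.37, 120: 37.96}, "T_sc") == pytest.approx(0.59)
    assert delta_t({0: 24.55, 60: 24.24, 120: 24.13}, "T_tail") == pytest.approx(-0.42)
    assert delta_t({0: 29.0, 120: 29.0}, "T_body") == 0.0


def test_delta_requires_two_endpoints():
    with pytest.raises(StatsError):
        delta_t({0: 37.0}, "T_sc")


# -- Greenhouse-Geisser epsilon and Mauchly --------------------------------


def _helmert_contrasts(k):
    """Independent orthonormal basis (Helmert), distinct from the implementation's."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def gg_oracle(x):
    k = x.shape[1]
    c = _helmert_contrasts(k)
    lam = np.linalg.eigvalsh(c.T @ np.cov(x, rowvar=False) @ c)
    return float(np.clip(lam.sum() ** 2 / ((k - 1) * (lam**2).sum()), 1 / (k - 1), 1.0))


def mauchly_oracle(x):
    k = x.shape[1]
    c = _helmert_contrasts(k)
    sc = c.T @ np.cov(x, rowvar=False) @ c
    return float(np.linalg.det(sc) / (np.trace(sc) / (k - 1)) ** (k - 1))


def test_epsilon_is_one_for_two_timepoints(rng):
    assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0


def test_epsilon_is_one_under_compound_symmetry():
    # exact compound symmetry: equal variances, equal covariances
    k, n = 4, 2000
    rng = np.random.default_rng(0)
    subj = rng.normal(0, 1.0, (n, 1))
    x = subj + rng.normal(0, 1.0, (n, k))
    # construct the *population* CS covariance directly for exactness
    s = np.full((k, k), 1.0) + np.eye(k)
    lam = np.linalg.eigvalsh(_helmert_contrasts(k).T @ s @ _helmert_contrasts(k))
    assert np.allclose(lam, lam[0])
    assert gg_epsilon(x) > 0.95  # sample estimate near 1


def test_epsilon_matches_eigen_oracle_to_1e10(rng):
    for _ in range(25):
        n, k = int(rng.integers(8, 30)), int(rng.integers(3, 6))
        x = rng.normal(size=(n, k)) @ rng.normal(size=(k, k))
        assert gg_epsilon(x) == pytest.approx(gg_oracle(x), abs=1e-10)


def test_epsilon_bounded(rng):
    for _ in range(50):
        n, k = int(rng.integers(5, 20)), int(rng.integers(3, 6))
        x = rng.normal(size=(n, k))
        e = gg_epsilon(x)
        assert 1.0 / (k - 1) - 1e-12 <= e <= 1.0 + 1e-12


def test_mauchly_matches_det_trace_oracle(rng):
    x = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4))
    w, chi2, df, p = mauchly_w(x)
    assert w == pytest.approx(mauchly_oracle(x), abs=1e-10)
    assert df == 4 * 3 // 2 - 1


def test_mauchly_vacuous_for_two_timepoints(rng):
    assert mauchly_w(rng.normal(size=(10, 2))) == (1.0, 0.0, 0, 1.0)


def test_sphericity_stats_match_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    x = rng.normal(size=(15, 4)) + rng.normal(size=(15, 1))
    w, chi2, df, _ = mauchly_w(x)
    ref = pg.sphericity(pd.DataFrame(x))
    assert w == pytest.approx(float(ref.W), abs=1e-10)
    assert chi2 == pytest.approx(float(ref.chi2), abs=1e-10)
    assert gg_epsilon(x) == pytest.approx(float(pg.epsilon(pd.DataFrame(x), correction="gg")), abs=1e-10)


# -- repeated-measures ANOVA ----------------------------------------------


def test_rm_anova_equals_squared_paired_t(rng):
    x = rng.normal(size=(10, 2))
    res = rm_time_anova(x)
    t = sps.ttest_rel(x[:, 1], x[:, 0])
    assert res.f == pytest.approx(t.statistic**2, abs=1e-10)
    assert res.p_uncorrected == pytest.approx(t.pvalue, abs=1e-12)


def test_rm_anova_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    x = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
    long = pd.DataFrame(
        {
            "y": x.ravel(),
            "subj": np.repeat(np.arange(12), 4),
            "time": np.tile(np.arange(4), 12),
        }
    )
    ref = pg.rm_anova(data=long, dv="y", within="time", subject="subj", correction=True)
    res = rm_time_anova(x)
    assert res.f == pytest.approx(float(ref["F"][0]), abs=1e-8)
    assert res.p_gg == pytest.approx(float(ref["p_GG_corr"][0]), abs=1e-8)


def test_rm_anova_null_calibration_quick():
    """GG-corrected rejection rate near alpha under a spherical null (500 reps)."""
    rng = np.random.default_rng(123)
    rejections = 0
    reps = 500
    for _ in range(reps):
        x = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
        if rm_time_anova(x).p_gg < 0.05:
            rejections += 1
    assert 0.02 <= rejections / reps <= 0.08


def test_rm_anova_detects_time_effect_on_latent_dh_cohort():
    table = simulate_latent_table(ScenarioConfig(test="DH", n_animals=64), seed=5)
    wide = table.pivot_table(index="animal_id", columns="timepoint_s", values="t_sc_c")
    res = rm_time_anova(wide.dropna().to_numpy())
    assert res.p_gg < 0.001


# -- Sidak -----------------------------------------------------------------


def test_sidak_formula_and_identities():
    assert sidak(0.01, 3) == pytest.approx(0.029701)
    assert sidak(0.2, 1) == pytest.approx(0.2)
    assert sidak(0.0, 10) == 0.0
    assert sidak(1.0, 2) == 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    p1=st.floats(0.0, 1.0),
    p2=st.floats(0.0, 1.0),
    m1=st.integers(1, 50),
    m2=st.integers(1, 50),
)
def test_sidak_monotone_and_bounded(p1, p2, m1, m2):
    lo_p, hi_p = sorted((p1, p2))
    lo_m, hi_m = sorted((m1, m2))
    assert 0.0 <= sidak(p1, m1) <= 1.0
    assert sidak(lo_p, m1) <= sidak(hi_p, m1)
    assert sidak(p1, lo_m) <= sidak(p1, hi_m)
    assert sidak(p1, m1) >= p1


# -- factorial between-animal ANOVA ---------------------------------------


def _per_animal_baseline(table, column="t_sc_c"):
    at0 = table[table["timepoint_s"] == 0]
    return at0.rename(columns={column: "baseline"})[
        ["animal_id", "baseline", "strain", "sex", "handling", "period", "drug", "testing_order"]
    ]


def test_between_anova_single_factor_equals_squared_t(rng):
    y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)])
    df = pd.DataFrame({"y": y, "g": ["a"] * 20 + ["b"] * 20})
    res = between_anova(df, "y", ["g"], include_interactions=False)
    t = sps.ttest_ind(y[20:], y[:20], equal_var=True)
    assert float(res.table.loc[res.table["term"] == "g", "F"].iloc[0]) == pytest.approx(
        t.statistic**2, abs=1e-8
    )


def test_between_anova_detects_period_effect():
    # testing_order is included as a design factor so the within-cage order
    # deviation does not inflate the residual of the period test
    table = simulate_latent_table(ScenarioConfig(test="DH", n_animals=64), seed=6)
    res = between_anova(
        _per_animal_baseline(table), "baseline",
        ["strain", "sex", "handling", "period", "testing_order"],
    )
    p = float(res.table.loc[res.table["term"] == "period", "p"].iloc[0])
    assert p < 0.001
    assert res.estimates["period"].estimate == pytest.approx(0.49, abs=0.25)


def test_between_anova_reports_aliased_interactions():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "y": rng.normal(size=30),
            "a": ["x"] * 15 + ["y"] * 15,
            "b": ["u"] * 15 + ["v"] * 15,  # fully confounded with a -> empty cells
        }
    )
    res = between_anova(df, "y", ["a", "b"])
    assert "a:b" in res.aliased
    assert (res.table.loc[res.table["term"] == "a:b", "note"] == "aliased/empty cells").all()


def test_null_effects_control_type_one_error():
    """With all effects zeroed, factor tests reject at ~alpha (100 replicate cohorts)."""
    config = ScenarioConfig(
        test="DH", n_animals=32, effects={"T_sc": {}, "T_body": {}, "T_tail": {}}
    )
    false_hits = 0
    reps = 100
    for i in range(reps):
        table = simulate_latent_table(config, seed=10_000 + i)
        res = between_anova(
            _per_animal_baseline(table), "baseline", ["strain", "sex", "handling", "period"],
            include_interactions=False,
        )
        pvals = res.table["p"].dropna()
        if (pvals < 1 - (1 - 0.05) ** (1 / len(pvals))).any():  # Sidak-adjusted alpha
            false_hits += 1
    assert false_hits / reps <= 0.07 + 0.06  # >=93% of replicates clean (binomial slack)


def test_testing_order_contrast_recovers_configured_offset():
    table = simulate_latent_table(ScenarioConfig(test="DH", n_animals=64), seed=8)
    c = order_contrast(table, "T_sc", 0)
    assert c.estimate == pytest.approx(0.75, abs=0.25)
    assert c.p_sidak >= c.p_raw
    tail = order_contrast(table, "T_tail", 0)
    assert tail.estimate == pytest.approx(-0.97, abs=0.3)


def test_testing_order_contrast_null_when_disabled():
    config = ScenarioConfig(test="DH", n_animals=64, effects={"T_sc": {}, "T_body": {}, "T_tail": {}})
    ests = []
    for i in range(20):
        table = simulate_latent_table(config, seed=300 + i)
        ests.append(order_contrast(table, "T_sc", 0).estimate)
    assert abs(np.mean(ests)) < 0.1
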