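"""ABC machinery: priors, summary statistics, rejection, model choice,
local-linear adjustment and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fursealpop.abc import (
    ABCError,
    ABCPosterior,
    DemographicABC,
    PriorSpec,
    ReferenceTable,
    STAT_NAMES,
    SummaryStatVector,
    TWO_DECLINE_PRIOR_BOUNDS,
    abc_reject,
    adjust_posterior,
    build_reference_table,
    model_choice,
    null_spec,
    posterior_summary,
    sample_priors,
    summary_stats,
    summary_stats_from_derived,
    two_decline_spec,
)
from fursealpop.coalsim import SimConfig
from fursealpop.genotypes import PopulationMap

from conftest import make_matrix


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def test_prior_draws_respect_conditions_and_bounds():
    spec = two_decline_spec(10, 10).prior
    draws = sample_priors(spec, 500, seed=1)
    assert (draws.t_Europeans > draws.t_post_seal).all()
    assert (draws.Ne_pre_historical > draws.Ne_NZ_N).all()
    assert (draws.t_Polynesian > draws.t_Europeans).all()
    for name, (lo, hi) in TWO_DECLINE_PRIOR_BOUNDS.items():
        assert draws[name].between(lo, hi).all()


def test_prior_marginal_unaffected_by_rare_condition():
    """t_post_seal stays ~U[1,25]: the t_E > t_ps condition rarely binds."""
    spec = two_decline_spec(10, 10).prior
    draws = sample_priors(spec, 4000, seed=2)
    _, p = stats.kstest(draws.t_post_seal, stats.uniform(1, 24).cdf)
    assert p > 0.01


def test_prior_determinism_and_validation():
    spec = two_decline_spec(10, 10).prior
    assert sample_priors(spec, 50, seed=3).equals(sample_priors(spec, 50, seed=3))
    with pytest.raises(ABCError):
        PriorSpec({"x": (2.0, 1.0)}).sample(5, np.random.default_rng(0))


def test_impossible_conditions_raise():
    spec = PriorSpec({"a": (0.0, 1.0), "b": (5.0, 6.0)}, conditions=[("a", "b")])
    with pytest.raises(ABCError, match="reject"):
        spec.sample(10, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _two_pop_matrix(calls_a, calls_b):
    calls = np.vstack([calls_a, calls_b]).astype(np.int8)
    g = make_matrix(calls)
    colony_of = {ind: ("NZ-N" if i < len(calls_a) else "NZ-S")
                 for i, ind in enumerate(g.individuals)}
    pops = PopulationMap(colony_of, {"NZ-N": "n", "NZ-S": "s"})
    return g, pops


def test_summary_stats_identical_samples_give_zero_distances():
    block = np.array([[0, 1], [1, 1], [2, 0], [1, 2]])
    g, pops = _two_pop_matrix(block, block)
    s = summary_stats(g, pops, ("NZ-N", "NZ-S")).as_series()
    assert s.NeiD_all == pytest.approx(0.0, abs=1e-12)
    assert abs(s.Fst_all) < 0.2  # identical compositions: noise around zero


def test_summary_stats_monomorphic_sample_flagged_zero():
    a = np.zeros((4, 3), dtype=int)
    b = np.array([[0, 1, 2]] * 4)
    g, pops = _two_pop_matrix(a, b)
    s = summary_stats(g, pops, ("NZ-N", "NZ-S"))
    ser = s.as_series()
    assert ser.He_all_1 == 0.0
    assert ser.He_poly_1 == 0.0
    assert "He_poly_1" in s.flags


def test_summary_stats_nei_distance_hand_formula():
    # frequencies: p1 = 0.25 (2/8), p2 = 0.75 -> known J terms per locus
    a = np.array([[0], [0], [1], [1]])
    b = np.array([[2], [2], [1], [1]])
    g, pops = _two_pop_matrix(a, b)
    s = summary_stats(g, pops, ("NZ-N", "NZ-S")).as_series()
    j1 = 0.25**2 + 0.75**2
    j2 = j1
    j12 = 0.25 * 0.75 + 0.75 * 0.25
    assert s.NeiD_all == pytest.approx(-np.log(j12 / np.sqrt(j1 * j2)))


def test_fast_path_matches_genotype_path():
    rng = np.random.default_rng(4)
    derived = (rng.random((2 * (7 + 5), 40)) < 0.4).astype(np.uint8)
    fast = summary_stats_from_derived(derived, 7, 5)
    d1 = (derived[:14:2] + derived[1:14:2]).astype(np.int8)
    d2 = (derived[14::2] + derived[15::2]).astype(np.int8)
    g, pops = _two_pop_matrix(d1, d2)
    slow = summary_stats(g, pops, ("NZ-N", "NZ-S"))
    assert fast.values == pytest.approx(slow.values, abs=1e-12)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_table():
    specs = [two_decline_spec(12, 10), null_spec(12, 10)]
    return specs, build_reference_table(specs, SimConfig(n_loci=80), 100, seed=6,
                                        n_dip=(12, 10))


def test_reference_table_shape_and_finiteness(mini_table):
    specs, table = mini_table
    assert len(table.df) == 200
    assert np.isfinite(table.stats).all()
    assert set(table.df.scenario) == {"two_decline", "null"}


def test_reference_table_roundtrip(tmp_path, mini_table):
    _, table = mini_table
    table.to_tsv(tmp_path / "t.tsv")
    back = ReferenceTable.from_tsv(tmp_path / "t.tsv")
    assert np.allclose(back.stats, table.stats)


def test_scenarios_differ_in_stats():
    """A hard-bottleneck scenario and a big-N null separate in diversity."""
    from fursealpop.abc import ScenarioSpec
    from fursealpop.coalsim import ScenarioParams, build_two_decline_scenario, build_null_scenario

    bot = PriorSpec({"Ne_refugium": (80.0, 120.0)})
    spec_b = ScenarioSpec(
        "bottleneck", bot,
        lambda p: build_two_decline_scenario(
            ScenarioParams(800, 800, p["Ne_refugium"], 5e5, 5e6, 106, 49.2, 20.3), 15, 15),
    )
    nul = PriorSpec({"Ne_constant": (1e5, 1e6)})
    spec_n = ScenarioSpec(
        "null", nul,
        lambda p: build_null_scenario(p["Ne_constant"], 800, 800, 20.3, 15, 15),
    )
    table = build_reference_table([spec_b, spec_n], SimConfig(n_loci=150), 60, seed=8)
    he = table.df.groupby("scenario").He_all_1.mean()
    _, p = stats.ttest_ind(
        table.df[table.df.scenario == "bottleneck"].He_all_1,
        table.df[table.df.scenario == "null"].He_all_1,
    )
    assert p < 1e-4 and he["bottleneck"] != pytest.approx(he["null"], abs=1e-3)


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

def _toy_table(n=200, seed=0, scenario=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(STAT_NAMES))), columns=STAT_NAMES)
    df.insert(0, "scenario", scenario or np.where(rng.random(n) < 0.5, "s1", "s2"))
    df["theta"] = rng.uniform(0, 1, size=n)
    return ReferenceTable(df, scenario_names=["s1", "s2"])


def test_reject_tolerance_one_keeps_all():
    table = _toy_table()
    obs = SummaryStatVector(np.zeros(len(STAT_NAMES)))
    idx, d = abc_reject(table, obs, 1.0)
    assert len(idx) == len(table.df)


def test_reject_exact_row_always_retained():
    table = _toy_table()
    obs = SummaryStatVector(table.stats[17].copy())
    idx, d = abc_reject(table, obs, 0.01)
    assert 17 in idx and d.min() == 0.0


def test_reject_count_is_ceiling():
    table = _toy_table(n=1000)
    obs = SummaryStatVector(np.zeros(len(STAT_NAMES)))
    idx, _ = abc_reject(table, obs, 0.0101)
    assert len(idx) == int(np.ceil(0.0101 * 1000))


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def test_model_choice_symmetric_scenarios_near_half():
    table = _toy_table(n=2000, seed=3)  # identical stat distributions
    obs = SummaryStatVector(np.zeros(len(STAT_NAMES)))
    idx, d = abc_reject(table, obs, 0.2)
    mc = model_choice(table, idx, obs, d)
    assert mc.direct["s1"] == pytest.approx(0.5, abs=0.12)
    assert mc.logistic["s1"] == pytest.approx(0.5, abs=0.15)
    assert sum(mc.direct.values()) == pytest.approx(1.0)
    assert sum(mc.logistic.values()) == pytest.approx(1.0)


def test_model_choice_direct_equals_counted_frequencies():
    table = _toy_table(n=100, seed=4)
    obs = SummaryStatVector(np.zeros(len(STAT_NAMES)))
    idx, d = abc_reject(table, obs, 0.3)
    mc = model_choice(table, idx, obs, d)
    labels = table.scenario_labels[idx]
    assert mc.direct["s1"] == pytest.approx((labels == "s1").mean())


# ---------------------------------------------------------------------------
# posterior adjustment and summaries
# ---------------------------------------------------------------------------

def test_adjustment_recovers_linear_relation():
    """theta = 0.5 + slope * stat (+ tiny noise): the local-linear adjustment
    concentrates draws at the regression value for the observed stat."""
    rng = np.random.default_rng(5)
    n = 400
    stats_mat = np.zeros((n, len(STAT_NAMES)))
    stats_mat[:, 0] = rng.normal(size=n)
    theta = 0.5 + 0.1 * stats_mat[:, 0] + rng.normal(scale=1e-3, size=n)
    df = pd.DataFrame(stats_mat, columns=STAT_NAMES)
    df.insert(0, "scenario", "s1")
    df["t_x"] = np.clip(theta, 0.01, 0.99)
    table = ReferenceTable(df, scenario_names=["s1"])
    prior = PriorSpec({"t_x": (0.0, 1.0)})
    obs = SummaryStatVector(np.zeros(len(STAT_NAMES)))
    idx, d = abc_reject(table, obs, 0.5)
    post = adjust_posterior(table, idx, d, obs, prior)
    assert np.average(post.draws.t_x, weights=post.weights) == pytest.approx(0.5, abs=0.02)
    assert post.draws.t_x.std() < df.t_x.std() / 3  # adjustment sharpens
    assert post.draws.t_x.between(0, 1).all()  # logit keeps prior bounds


def test_adjustment_near_identity_when_stats_uninformative():
    rng = np.random.default_rng(6)
    n = 300
    df = pd.DataFrame(rng.normal(size=(n, len(STAT_NAMES))), columns=STAT_NAMES)
    df.insert(0, "scenario", "s1")
    df["Ne_x"] = rng.uniform(100, 200, size=n)
    table = ReferenceTable(df, scenario_names=["s1"])
    prior = PriorSpec({"Ne_x": (100.0, 200.0)})
    obs = SummaryStatVector(df[STAT_NAMES].mean().to_numpy())
    idx, d = abc_reject(table, obs, 0.5)
    post = adjust_posterior(table, idx, d, obs, prior)
    raw = table.df.iloc[idx]["Ne_x"].to_numpy()
    assert np.corrcoef(post.draws.Ne_x, raw)[0, 1] > 0.9


def test_posterior_summary_point_mass_and_uniform():
    point = ABCPosterior(pd.DataFrame({"Ne_refugium": np.full(100, 110.0)}),
                         np.ones(100), ["Ne_refugium"])
    s = point.summary()
    assert s.loc["Ne_refugium", "mode"] == 110.0
    assert s.loc["Ne_refugium", "q05"] == 110.0 == s.loc["Ne_refugium", "q95"]

    rng = np.random.default_rng(7)
    u = ABCPosterior(pd.DataFrame({"x": rng.uniform(0, 1, 5000)}),
                     np.ones(5000), ["x"])
    su = posterior_summary(u)
    assert su.loc["x", "q05"] == pytest.approx(0.05, abs=0.02)
    assert su.loc["x", "q95"] == pytest.approx(0.95, abs=0.02)


def test_posterior_weights_validated():
    with pytest.raises(ABCError):
        ABCPosterior(pd.DataFrame({"x": [1.0, 2.0]}), np.array([-1.0, 2.0]), ["x"])


def test_rejection_posterior_converges_to_prior_at_full_tolerance(mini_table):
    specs, table = mini_table
    obs = SummaryStatVector(table.stats.mean(axis=0))
    idx, d = abc_reject(table, obs, 1.0)
    sub = table.df.iloc[idx]
    kept = sub[sub.scenario == "two_decline"].t_post_seal
    _, p = stats.kstest(kept, stats.uniform(1, 24).cdf)
    assert p > 0.01  # retained-at-tolerance-1 draws are the prior itself


# ---------------------------------------------------------------------------
# Model/Results surface
# ---------------------------------------------------------------------------

def test_model_results_summary_smoke(mini_table):
    specs, table = mini_table
    obs = SummaryStatVector(table.stats[0].copy())
    model = DemographicABC(obs, (12, 10), scenarios=specs,
                           sim_config=SimConfig(n_loci=80))
    res = model.fit(tolerance=0.5, reference_table=table)
    text = res.summary()
    assert "Scenario posterior probabilities" in text
    assert res.best_scenario in {"two_decline", "null"}
    if res.posterior is not None:
        ci = res.conf_int()
        assert (ci.q05 <= ci.q95).all()
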