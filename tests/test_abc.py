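import numpy as np
import pandas as pd
import pytest

from anole_admix import abc as abc_mod
from anole_admix.io import PopulationMap
from anole_admix.sumstats import SUMMARY_STAT_NAMES


@pytest.fixture(scope="module")
def small_samples():
    return PopulationMap(["SFL", "MIA", "WCU"],
                         {"SFL": 8, "MIA": 12, "WCU": 8})


@pytest.fixture(scope="module")
def small_table(small_samples):
    return abc_mod.build_reference_table(
        abc_mod.default_priors(), small_samples, n_loci=6, n_sims=150, seed=2)


def hand_table(stat_values, params=None):
    """A minimal SimulationTable with one varying statistic column."""
    n = len(stat_values)
    stats = pd.DataFrame(
        {name: [0.5] * n for name in SUMMARY_STAT_NAMES})
    stats["fst_p1_p2"] = stat_values
    prior = abc_mod.default_priors()
    p = params if params is not None else abc_mod.sample_prior(prior, n, 0)
    return abc_mod.SimulationTable(p, stats, seed=0, prior=prior)


# ------------------------------------------------------------- priors

def test_prior_draws_within_bounds_and_deterministic():
    spec = abc_mod.default_priors()
    draws = abc_mod.sample_prior(spec, 2_000, seed=5)
    for name, (family, lo, hi) in spec.params.items():
        assert draws[name].between(lo, hi).all()
    again = abc_mod.sample_prior(spec, 2_000, seed=5)
    pd.testing.assert_frame_equal(draws, again)


def test_uniform_prior_mean():
    spec = abc_mod.PriorSpec({"t_admix": ("uniform", 1, 4000)})
    draws = abc_mod.sample_prior(spec, 100_000, seed=1)["t_admix"]
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - 2000.5) < 3 * se


def test_loguniform_prior_support():
    spec = abc_mod.PriorSpec({"n_sfl": ("loguniform", 100, 10_000)})
    draws = abc_mod.sample_prior(spec, 5_000, seed=3)["n_sfl"]
    assert draws.between(100, 10_000).all()
    # log-uniform median is the geometric mean of the bounds
    assert np.median(draws) == pytest.approx(1000, rel=0.1)


def test_prior_validation():
    with pytest.raises(ValueError):
        abc_mod.PriorSpec({"x": ("uniform", 5, 5)})
    with pytest.raises(ValueError):
        abc_mod.PriorSpec({"x": ("loguniform", 0, 10)})
    with pytest.raises(ValueError):
        abc_mod.PriorSpec({"x": ("normal", 0, 1)})


# ------------------------------------------------------------- table

def test_reference_table_complete_and_nondegenerate(small_table):
    assert len(small_table) == 150
    assert not small_table.stats.isna().any().any()
    assert (small_table.stats.std(ddof=1) > 0).all()


def test_reference_table_csv_round_trip(small_table, tmp_path):
    path = tmp_path / "table.csv"
    small_table.to_csv(path)
    back = abc_mod.SimulationTable.from_csv(path)
    pd.testing.assert_frame_equal(back.stats, small_table.stats)
    pd.testing.assert_frame_equal(back.params, small_table.params)


def test_more_loci_reduce_mean_allele_noise(small_samples):
    """With the same prior draws, more loci average out locus noise."""
    few = abc_mod.build_reference_table(
        abc_mod.default_priors(), small_samples, n_loci=4, n_sims=120, seed=9)
    many = abc_mod.build_reference_table(
        abc_mod.default_priors(), small_samples, n_loci=16, n_sims=120, seed=9)
    resid_sd = {}
    for tab in (few, many):
        col = tab.stats["mean_alleles_p2"]
        # regress out the prior-driven trend on the (identical) draws
        x = np.log(tab.params["n_mia"])
        beta = np.polyfit(x, col, 2)
        resid_sd[id(tab)] = (col - np.polyval(beta, x)).std(ddof=1)
    assert resid_sd[id(many)] < resid_sd[id(few)]


# ------------------------------------------------------------- rejection

def test_reject_recovers_exact_row(small_table):
    obs = small_table.stats.iloc[37]
    post = abc_mod.reject(small_table, obs, n_keep=10)
    assert post.distances[0] == 0.0
    assert post.accepted.iloc[0].equals(small_table.params.iloc[37])


def test_reject_keep_all(small_table):
    obs = small_table.stats.iloc[0]
    post = abc_mod.reject(small_table, obs, n_keep=len(small_table))
    assert len(post) == len(small_table)


def test_reject_hand_distances():
    table = hand_table([1.0, 2.0, 4.0])
    obs = table.stats.iloc[0].copy()
    obs["fst_p1_p2"] = 2.0
    post = abc_mod.reject(table, obs, n_keep=3)
    # MAD of {1,2,4} is 1 -> scale 1.4826; |x-2|/1.4826 = {0.6745, 0, 1.349}
    np.testing.assert_allclose(
        np.sort(post.distances), np.array([0.0, 1.0, 2.0]) / 1.4826,
        rtol=1e-4)


def test_reject_affine_invariance(small_table):
    obs = small_table.stats.iloc[3]
    keep_a = abc_mod.reject(small_table, obs, n_keep=20).accepted
    scaled = small_table.stats.copy()
    scaled["gene_diversity_p1"] = scaled["gene_diversity_p1"] * 40 - 7
    obs2 = obs.copy()
    obs2["gene_diversity_p1"] = obs2["gene_diversity_p1"] * 40 - 7
    table2 = abc_mod.SimulationTable(small_table.params, scaled, 0,
                                     small_table.prior)
    keep_b = abc_mod.reject(table2, obs2, n_keep=20).accepted
    pd.testing.assert_frame_equal(keep_a, keep_b)


def test_reject_rejects_undefined_observed(small_table):
    obs = small_table.stats.iloc[0].copy()
    obs["lambda_admixture"] = np.nan
    with pytest.raises(ValueError, match="lambda_admixture"):
        abc_mod.reject(small_table, obs, n_keep=5)


def test_posterior_concentrates_on_informative_stats(small_table):
    obs = small_table.stats.iloc[11]
    post = abc_mod.reject(small_table, obs, n_keep=30)
    prior_sd = small_table.params["r_admix"].std(ddof=1)
    assert post.accepted["r_admix"].std(ddof=1) < prior_sd


# ------------------------------------------------------------- summaries

def test_posterior_summary_quantile_arithmetic():
    draws = pd.DataFrame({"t_admix": np.arange(1.0, 102.0)})
    summ = abc_mod.posterior_summary(draws)
    row = summ.loc["t_admix"]
    assert row["median"] == 51
    assert row["ci_low"] == pytest.approx(3.5)
    assert row["ci_high"] == pytest.approx(98.5)


def test_posterior_summary_degenerate_draws():
    draws = pd.DataFrame({"x": np.full(25, 7.0)})
    row = abc_mod.posterior_summary(draws).loc["x"]
    assert row["median"] == row["mode"] == 7.0
    assert row["ci_high"] - row["ci_low"] == 0.0


def test_posterior_summary_kde_mode_consistency():
    modes = []
    for seed in range(5):
        draws = pd.DataFrame({"x": np.random.default_rng(seed).normal(0, 1, 10_000)})
        modes.append(abc_mod.posterior_summary(draws).loc["x", "mode"])
    assert abs(np.mean(modes)) < 0.1


def test_posterior_summary_needs_enough_draws():
    with pytest.raises(ValueError):
        abc_mod.posterior_summary(pd.DataFrame({"x": np.arange(5.0)}))


# ------------------------------------------------------------- PPC

def test_ppc_extreme_observed_gives_floor_pvalue(small_table, small_samples):
    obs = small_table.stats.iloc[4].copy()
    post = abc_mod.reject(small_table, obs, n_keep=40)
    post.observed["gene_diversity_p1"] = 50.0  # far outside the support
    n_draws = 25
    ppc = abc_mod.posterior_predictive_check(post, small_samples, n_loci=6,
                                             n_draws=n_draws, seed=8)
    assert ppc.loc["gene_diversity_p1", "p_value"] == pytest.approx(
        2 / (n_draws + 1))


def test_ppc_reproducible(small_table, small_samples):
    obs = small_table.stats.iloc[4]
    post = abc_mod.reject(small_table, obs, n_keep=40)
    a = abc_mod.posterior_predictive_check(post, small_samples, 6, 15, seed=3)
    b = abc_mod.posterior_predictive_check(post, small_samples, 6, 15, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_regression_adjustment_stays_in_prior_support(small_table):
    obs = small_table.stats.iloc[8]
    post = abc_mod.reject(small_table, obs, n_keep=40, regression_adjust=True)
    for name, (fam, lo, hi) in small_table.prior.params.items():
        assert post.accepted[name].between(lo, hi).all()
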