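import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from anole_admix import sumstats as ss
from anole_admix.io import GenotypeTable


def table_from_calls(calls, pops=None, loci=1):
    """calls: list per individual of list-of-(a1,a2) per locus."""
    n = len(calls)
    pops = pops or ["A"] * n
    arr = np.array(calls, np.int32).reshape(n, loci, 2)
    return GenotypeTable([f"i{k}" for k in range(n)], pops,
                         [f"L{j}" for j in range(loci)], arr)


def counts_to_table(pop_counts, pops=("A", "B")):
    """Build a two-pop table from genotype->count dicts per population."""
    calls, labels = [], []
    for pop, cc in zip(pops, pop_counts):
        for (a1, a2), k in cc.items():
            calls.extend([[(a1, a2)]] * k)
            labels.extend([pop] * k)
    return table_from_calls(calls, labels)


# ---------------------------------------------------------------- diversity

def test_observed_heterozygosity_hand_counts(toys):
    _, mean = ss.observed_heterozygosity(toys["one_het"], "A")
    assert mean == pytest.approx(0.25)
    _, all_hom = ss.observed_heterozygosity(toys["monomorphic"], "A")
    assert all_hom == 0.0
    _, all_het = ss.observed_heterozygosity(toys["two_allele"], "A")
    assert all_het == 1.0


def test_expected_heterozygosity_unbiased_formula(toys):
    _, he = ss.expected_heterozygosity(toys["two_allele"], "A")
    assert he == pytest.approx((4 / 3) * 0.5)  # n=2, two alleles at 0.5
    _, mono = ss.expected_heterozygosity(toys["monomorphic"], "A")
    assert mono == 0.0


def test_expected_heterozygosity_plugin_large_n():
    # frequencies {0.5, 0.3, 0.2} at n=1000: correction factor ~1.0005
    calls = ([[(1, 1)]] * 250 + [[(1, 2)]] * 300 + [[(1, 3)]] * 200
             + [[(2, 2)]] * 150 + [[(3, 3)]] * 100)
    table = table_from_calls(calls)
    _, he = ss.expected_heterozygosity(table, "A")
    assert he == pytest.approx(1 - (0.25 + 0.09 + 0.04), abs=1e-3)


def test_allelic_richness_endpoints(toys):
    table = toys["two_allele"]
    _, at_full = ss.allelic_richness(table, "A", g=4)
    assert at_full == pytest.approx(2.0)
    _, at_one = ss.allelic_richness(table, "A", g=1)
    assert at_one == pytest.approx(1.0)


def test_allelic_richness_matches_subset_enumeration():
    # N = 6 gene copies with allele counts 3/2/1, rarefied to g = 4
    calls = [[(1, 1)], [(1, 2)], [(2, 3)]]
    table = table_from_calls(calls)
    copies = [1, 1, 1, 2, 2, 3]
    g = 4
    expected = np.mean([len(set(sub))
                        for sub in itertools.combinations(copies, g)])
    _, ar = ss.allelic_richness(table, "A", g=g)
    assert ar == pytest.approx(expected, abs=1e-12)


def test_allelic_richness_depth_validation(toys):
    with pytest.raises(ValueError):
        ss.allelic_richness(toys["two_allele"], "A", g=0)
    with pytest.raises(ValueError):
        ss.allelic_richness(toys["two_allele"], "A", g=5)


def test_m_ratio_formula():
    saturated = table_from_calls([[(10, 11)], [(11, 12)], [(10, 12)]])
    _, m = ss.m_ratio(saturated, "A")
    assert m == pytest.approx(1.0)
    gapped = table_from_calls([[(10, 10)], [(12, 12)]])
    _, m = ss.m_ratio(gapped, "A")
    assert m == pytest.approx(2 / 3)
    mono = table_from_calls([[(10, 10)]] * 3)
    _, m = ss.m_ratio(mono, "A")
    assert m == pytest.approx(1.0)


def test_m_ratio_repeat_length_rescaling():
    # fragment sizes 100/104/108 at tetranucleotide repeats: sizes 25/26/27
    table = table_from_calls([[(100, 104)], [(108, 108)]])
    _, m = ss.m_ratio(table, "A", repeat_length=4)
    assert m == pytest.approx(1.0)


# ---------------------------------------------------------------- F_ST

def _wc_theta_anova(table, pop_a, pop_b):
    """Independent transcription: ANOVA variance components on allele
    indicators (copies within individuals within populations)."""
    j = 0
    groups = []
    for pop in (pop_a, pop_b):
        sub = table.alleles[table.pop_mask(pop), j, :]
        groups.append(sub[sub[:, 0] != 0])
    states = np.unique(np.concatenate([g.ravel() for g in groups]))
    num = den = 0.0
    r = 2
    n_i = np.array([len(g) for g in groups], float)
    nbar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    for s in states:
        y = [(g == s).astype(float) for g in groups]          # (n_i, 2)
        ybar_i = [yi.mean() for yi in y]
        ybar = np.concatenate([yi.ravel() for yi in y]).mean()
        ss_p = sum(2 * n * (bi - ybar) ** 2 for n, bi in zip(n_i, ybar_i))
        ss_i = sum(2 * ((yi.mean(axis=1) - bi) ** 2).sum()
                   for yi, bi in zip(y, ybar_i))
        ss_g = sum(((yi - yi.mean(axis=1, keepdims=True)) ** 2).sum()
                   for yi in y)
        ms_p = ss_p / (r - 1)
        ms_i = ss_i / (n_i.sum() - r)
        ms_g = ss_g / n_i.sum()
        sig_g = ms_g
        sig_i = (ms_i - ms_g) / 2
        sig_p = (ms_p - ms_i) / (2 * n_c)
        num += sig_p
        den += sig_p + sig_i + sig_g
    return num / den


def test_wc_fst_matches_independent_anova_transcription():
    table = counts_to_table([
        {(1, 1): 4, (1, 2): 4, (2, 2): 2},
        {(1, 1): 1, (1, 2): 3, (2, 2): 6},
    ])
    _, theta = ss.wc_fst(table, "A", "B")
    assert theta == pytest.approx(_wc_theta_anova(table, "A", "B"), abs=1e-12)


def test_wc_fst_multiallelic_matches_anova():
    rng = np.random.default_rng(3)
    calls, labels = [], []
    for pop, probs in (("A", [0.5, 0.3, 0.2]), ("B", [0.2, 0.2, 0.6])):
        for _ in range(30):
            calls.append([tuple(rng.choice([1, 2, 3], 2, p=probs))])
            labels.append(pop)
    table = table_from_calls(calls, labels)
    _, theta = ss.wc_fst(table, "A", "B")
    assert theta == pytest.approx(_wc_theta_anova(table, "A", "B"), abs=1e-12)


def test_wc_fst_fixed_difference_is_one(toys):
    _, theta = ss.wc_fst(toys["fixed_pair"], "A", "B")
    assert theta == pytest.approx(1.0)


def test_wc_fst_panmictic_near_zero():
    rng = np.random.default_rng(11)
    calls = [[tuple(rng.choice([1, 2, 3, 4], 2, p=[0.4, 0.3, 0.2, 0.1]))]
             for _ in range(1000)]
    labels = ["A"] * 500 + ["B"] * 500
    table = table_from_calls(calls, labels)
    _, theta = ss.wc_fst(table, "A", "B")
    assert abs(theta) < 0.01


def test_wc_fst_invariant_to_locus_order_and_relabeling(study_dataset):
    table = study_dataset.genotypes
    _, theta = ss.wc_fst(table, "SFL", "WCU")
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(table.loci))
    shuffled = GenotypeTable(table.individuals, table.pops,
                             [table.loci[k] for k in perm],
                             table.alleles[:, perm, :])
    _, theta2 = ss.wc_fst(shuffled, "SFL", "WCU")
    relabeled = GenotypeTable(table.individuals, table.pops, table.loci,
                              table.alleles + 1000)
    _, theta3 = ss.wc_fst(relabeled, "SFL", "WCU")
    assert theta2 == pytest.approx(theta, abs=1e-12)
    assert theta3 == pytest.approx(theta, abs=1e-12)


# ---------------------------------------------------------------- HWE

def _hwe_exact_enumeration(calls):
    """Exact p by enumerating all perfect matchings of the gene copies."""
    from anole_admix.sumstats import _log_genotype_prob

    copies = list(np.sort(calls.ravel()))

    def matchings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k in range(len(rest)):
            pair = (first, rest[k])
            remaining = rest[:k] + rest[k + 1:]
            for m in matchings(remaining):
                yield [pair] + m

    obs = _log_genotype_prob(calls)
    total = hits = 0
    for m in matchings(copies):
        arr = np.array(m)
        lp = _log_genotype_prob(arr)
        total += 1
        if lp <= obs + 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize("genotypes", [
    [(1, 1), (1, 2), (2, 2)],
    [(1, 2), (1, 2), (1, 2)],
    [(1, 1), (2, 2), (3, 3), (1, 2)],
])
def test_hwe_monte_carlo_matches_enumeration(genotypes):
    table = table_from_calls([[g] for g in genotypes])
    p_mc = ss.hwe_exact_test(table, "A", "L0", reps=100_000, seed=1)
    p_exact = _hwe_exact_enumeration(table.alleles[:, 0, :])
    assert p_mc == pytest.approx(p_exact, abs=0.01)


def test_hwe_monomorphic_returns_one():
    table = table_from_calls([[(1, 1)]] * 5)
    assert ss.hwe_exact_test(table, "A", "L0", reps=100, seed=0) == 1.0


def test_hwe_requires_seed(toys):
    with pytest.raises(ValueError, match="seed"):
        ss.hwe_exact_test(toys["one_het"], "A", "L1", reps=10)


def test_hwe_pvalues_uniform_under_null():
    rng = np.random.default_rng(99)
    pvals = []
    probs = np.array([0.4, 0.3, 0.2, 0.1])
    for _ in range(200):
        copies = rng.choice([1, 2, 3, 4], size=(30, 2), p=probs)
        table = table_from_calls([[tuple(c)] for c in copies])
        pvals.append(ss.hwe_exact_test(table, "A", "L0", reps=1_000,
                                       seed=int(rng.integers(2**31))))
    assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- lambda

def _three_pop_table(rng, lam, n_hybrid=400, n_parent=400):
    """Parents with distinct frequency profiles; hybrid an exact mixture."""
    p1 = {1: 0.6, 2: 0.3, 3: 0.1}
    p2 = {1: 0.1, 2: 0.2, 3: 0.7}
    mix = {a: (1 - lam) * p1[a] + lam * p2[a] for a in p1}

    def draw(freqs, n, pop):
        alleles = rng.choice(list(freqs), size=(n, 2),
                             p=list(freqs.values()))
        return [[tuple(a)] for a in alleles], [pop] * n

    calls, labels = [], []
    for freqs, n, pop in ((p1, n_parent, "P1"), (mix, n_hybrid, "H"),
                          (p2, n_parent, "P2")):
        c, l = draw(freqs, n, pop)
        calls += c
        labels += l
    return table_from_calls(calls, labels)


def test_lambda_endpoints():
    rng = np.random.default_rng(0)
    table = _three_pop_table(rng, lam=0.0)
    assert ss.lambda_admixture(table, "P1", "P2", "H") <= 0.05
    table = _three_pop_table(np.random.default_rng(1), lam=1.0)
    assert ss.lambda_admixture(table, "P1", "P2", "H") >= 0.95


def test_lambda_even_mixture_matches_grid_oracle():
    table = _three_pop_table(np.random.default_rng(2), lam=0.5,
                             n_hybrid=4000, n_parent=4000)
    lam_hat = ss.lambda_admixture(table, "P1", "P2", "H")
    lam_grid = ss.lambda_admixture(table, "P1", "P2", "H", grid=1001)
    assert lam_hat == pytest.approx(0.5, abs=0.02)
    assert lam_hat == pytest.approx(lam_grid, abs=1e-3)


def test_lambda_optimum_beats_grid(study_dataset):
    table = study_dataset.genotypes
    lam_hat = ss.lambda_admixture(table, "SFL", "WCU", "MIA")
    best = ss.lambda_loglik(table, "SFL", "WCU", "MIA", lam_hat)
    for lam in np.linspace(0, 1, 1001):
        assert best >= ss.lambda_loglik(table, "SFL", "WCU", "MIA", lam) - 1e-9


# ---------------------------------------------------------------- delta K

def test_delta_k_zero_for_linear_likelihoods():
    L = {k: [(-50.0 * k) + eps for eps in (0.0, 0.1, -0.1)]
         for k in range(1, 6)}
    frame = ss.delta_k(L)
    inner = frame["delta_k"].dropna()
    assert (inner < 1e-9).all()


def test_delta_k_affine_invariance():
    rng = np.random.default_rng(4)
    L = {k: list(-1000 + 50 * k + rng.normal(0, 5, 4)) for k in range(1, 6)}
    base = ss.delta_k(L)["delta_k"]
    scaled = ss.delta_k({k: [3.5 * v + 200 for v in vals]
                         for k, vals in L.items()})["delta_k"]
    np.testing.assert_allclose(base.dropna(), scaled.dropna(), rtol=1e-9)


def test_delta_k_hand_table():
    L = {2: [-100, -102], 3: [-90, -92], 4: [-89, -91]}
    frame = ss.delta_k(L)
    # per-run second differences at K=3: |-89 + 180 - 100| = 9 and
    # |-91 + 184 - 102| = 9; sd of L(3) runs = sqrt(2)
    assert frame.loc[3, "delta_k"] == pytest.approx(9 / math.sqrt(2))
    assert np.isnan(frame.loc[2, "delta_k"])
    assert ss.best_k(L) == 3


def test_delta_k_zero_sd_reported_undefined():
    L = {2: [-100, -100], 3: [-90, -90], 4: [-89, -89]}
    assert np.isnan(ss.delta_k(L).loc[3, "delta_k"])


def test_delta_k_input_validation():
    with pytest.raises(ValueError):
        ss.delta_k({2: [1, 2], 4: [1, 2], 5: [1, 2]})   # not consecutive
    with pytest.raises(ValueError):
        ss.delta_k({2: [1], 3: [1], 4: [1]})            # <2 runs


# ---------------------------------------------------------------- reporting

def test_aggregate_mean_sd():
    mean, sd = ss.aggregate_mean_sd([1.0, 1.0, 1.0])
    assert (mean, sd) == (1.0, 0.0)
    mean, sd = ss.aggregate_mean_sd([2.0])
    assert math.isnan(sd)
    with pytest.raises(ValueError):
        ss.aggregate_mean_sd([])


def test_summary_stat_vector_shape_and_order(study_dataset):
    vec = ss.summary_stat_vector(study_dataset.genotypes, "SFL", "WCU", "MIA")
    series = vec.as_series()
    assert list(series.index) == list(ss.SUMMARY_STAT_NAMES)
    assert 0 <= series["lambda_admixture"] <= 1
    assert (series[:6] > 0).all()
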