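"""Nuclear-marker summary statistics for microsatellite genotype tables.

Implements the per-population diversity statistics (observed/expected
heterozygosity, rarefied allelic richness, M-ratio), pairwise Weir–Cockerham
F_ST, a Monte-Carlo Hardy–Weinberg exact test, the maximum-likelihood
admixture coefficient lambda for a hybrid population between two parental
populations, the Evanno delta-K statistic on clustering log-likelihoods, and
the fixed 10-element summary-statistic vector used by the ABC stage.

All per-locus statistics skip loci that are undefined for the requested
population (all calls missing, or fewer than the minimum sample size) and
log a warning rather than failing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allelic_richness",
    "m_ratio",
    "wc_fst",
    "hwe_exact_test",
    "lambda_admixture",
    "delta_k",
    "aggregate_mean_sd",
    "summary_stat_vector",
    "SummaryStatVector",
    "pop_stats",
]

SUMMARY_STAT_NAMES = (
    "mean_alleles_p1", "mean_alleles_p2", "mean_alleles_p3",
    "gene_diversity_p1", "gene_diversity_p2", "gene_diversity_p3",
    "fst_p1_p2", "fst_p1_p3", "fst_p2_p3",
    "lambda_admixture",
)


@dataclass(frozen=True)
class SummaryStatVector:
    """Fixed-order statistic vector: mean alleles per population (3),
    mean gene diversity per population (3), pairwise F_ST (3), lambda (1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.shape != (10,):
            raise ValueError("summary-statistic vector must have 10 entries")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(SUMMARY_STAT_NAMES))


# ---------------------------------------------------------------------------
# allele bookkeeping

def _locus_calls(table: GenotypeTable, pop: str, locus_idx: int) -> np.ndarray:
    """Non-missing diploid calls (m, 2) for one population and locus."""
    sub = table.alleles[table.pop_mask(pop), locus_idx, :]
    return sub[sub[:, 0] != MISSING]

def allele_counts(table: GenotypeTable, pop: str, locus_idx: int) -> dict[int, int]:
    """Gene-copy counts per allele state at one locus in one population."""
    calls = _locus_calls(table, pop, locus_idx)
    states, counts = np.unique(calls.ravel(), return_counts=True)
    return dict(zip(states.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# per-population diversity

def observed_heterozygosity(table: GenotypeTable, pop: str) -> tuple[pd.Series, float]:
    """Per-locus fraction of heterozygous (non-missing) individuals + mean."""
    vals = {}
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, pop, j)
        if len(calls) == 0:
            logger.warning("locus %s all-missing in %s; excluded", locus, pop)
            continue
        vals[locus] = float(np.mean(calls[:, 0] != calls[:, 1]))
    series = pd.Series(vals, dtype=float)
    return series, float(series.mean())


def expected_heterozygosity(table: GenotypeTable, pop: str) -> tuple[pd.Series, float]:
    """Unbiased gene diversity (2n/(2n-1))(1 - sum p_i^2) per locus + mean."""
    vals = {}
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, pop, j)
        n = len(calls)
        if n <= 1:
            logger.warning("locus %s has n<=1 in %s; He undefined, excluded",
                           locus, pop)
            continue
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / (2 * n)
        vals[locus] = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p * p)))
    series = pd.Series(vals, dtype=float)
    return series, float(series.mean())


def allelic_richness(table: GenotypeTable, pop: str, g: int) -> tuple[pd.Series, float]:
    """Rarefied allelic richness at ``g`` gene copies per locus + mean.

    Expected number of distinct alleles in a random subsample of ``g`` gene
    copies: sum over alleles of 1 - C(N - N_a, g)/C(N, g).
    """
    if g < 1:
        raise ValueError("rarefaction depth g must be >= 1")
    vals = {}
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, pop, j)
        N = 2 * len(calls)
        if N == 0:
            logger.warning("locus %s all-missing in %s; excluded", locus, pop)
            continue
        if g > N:
            raise ValueError(
                f"rarefaction depth g={g} exceeds {N} gene copies at "
                f"locus {locus} in {pop}"
            )
        _, counts = np.unique(calls.ravel(), return_counts=True)
        denom = math.comb(N, g)
        vals[locus] = float(sum(1.0 - math.comb(N - c, g) / denom for c in counts))
    series = pd.Series(vals, dtype=float)
    return series, float(series.mean())


def default_rarefaction_depth(table: GenotypeTable) -> int:
    """Smallest per-population, per-locus non-missing gene-copy count."""
    best = None
    for pop in table.pop_labels:
        for j in range(len(table.loci)):
            n = 2 * len(_locus_calls(table, pop, j))
            if n and (best is None or n < best):
                best = n
    if best is None:
        raise ValueError("table has no non-missing calls")
    return best


def m_ratio(table: GenotypeTable, pop: str,
            repeat_length: int = 1) -> tuple[pd.Series, float]:
    """Garza–Williamson M = k/(r+1) per locus + mean.

    ``k`` is the number of distinct alleles and ``r`` the allele-size range
    in repeat units.  Allele states are assumed to be repeat counts already;
    pass ``repeat_length`` to convert raw fragment sizes first.  A
    monomorphic locus has M = 1 by convention.
    """
    vals = {}
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, pop, j)
        if len(calls) == 0:
            logger.warning("locus %s all-missing in %s; excluded", locus, pop)
            continue
        states = np.unique(calls.ravel()) // repeat_length
        k = len(np.unique(states))
        r = int(states.max() - states.min())
        vals[locus] = k / (r + 1)
    series = pd.Series(vals, dtype=float)
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta for a pair of populations

def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, float, float]:
    """Summed per-allele variance components (a, b, c) for one locus."""
    n1, n2 = len(calls_a), len(calls_b)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    states = np.unique(np.concatenate([calls_a.ravel(), calls_b.ravel()]))
    # per-individual copy counts of each allele state, vectorised over states
    cnt1 = (calls_a[:, :, None] == states).sum(axis=1)  # (n1, k)
    cnt2 = (calls_b[:, :, None] == states).sum(axis=1)
    p1 = cnt1.mean(axis=0) / 2.0
    p2 = cnt2.mean(axis=0) / 2.0
    h1 = (cnt1 == 1).mean(axis=0)  # frequency of heterozygotes carrying s
    h2 = (cnt2 == 1).mean(axis=0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
        )
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> tuple[pd.Series, float]:
    """Weir–Cockerham theta per locus and the multilocus ratio-of-sums.

    Loci monomorphic across both populations (or with fewer than two
    non-missing diploids in either) are excluded from both the per-locus
    report and the multilocus sums.
    """
    per_locus = {}
    sum_a = sum_abc = 0.0
    for j, locus in enumerate(table.loci):
        ca = _locus_calls(table, pop_a, j)
        cb = _locus_calls(table, pop_b, j)
        if len(ca) < 2 or len(cb) < 2:
            logger.warning("locus %s: <2 diploids in a population; excluded", locus)
            continue
        if len(np.unique(np.concatenate([ca.ravel(), cb.ravel()]))) < 2:
            logger.warning("locus %s monomorphic across %s/%s; excluded",
                           locus, pop_a, pop_b)
            continue
        a, b, c = _wc_components(ca, cb)
        denom = a + b + c
        if denom != 0:
            per_locus[locus] = a / denom
        sum_a += a
        sum_abc += denom
    if sum_abc == 0:
        raise ValueError(f"no informative loci between {pop_a} and {pop_b}")
    return pd.Series(per_locus, dtype=float), float(sum_a / sum_abc)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)

def _log_genotype_prob(calls: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene (1949): P = n! 2^h prod_a m_a! / ((2n)! prod_g f_g!) with n
    diploids, h heterozygotes, m_a allele counts and f_g genotype counts.
    """
    n = len(calls)
    pairs = np.sort(calls, axis=1)
    _, f = np.unique(pairs, axis=0, return_counts=True)
    _, m = np.unique(pairs.ravel(), return_counts=True)
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    lg = math.lgamma
    logp = lg(n + 1) + h * math.log(2.0) + sum(lg(c + 1) for c in m)
    logp -= lg(2 * n + 1) + sum(lg(c + 1) for c in f)
    return logp


def hwe_exact_test(table: GenotypeTable, pop: str, locus: str,
                   reps: int = 10_000, seed: int | None = None) -> float:
    """Monte-Carlo exact Hardy–Weinberg test p-value for one locus.

    The test statistic is the conditional probability of the observed
    genotype array given its allele counts; ``reps`` random re-pairings of
    the allele vector estimate the null tail, with the plus-one correction
    p = (b + 1)/(reps + 1).  Monomorphic loci return 1.0 by convention.
    """
    if seed is None:
        raise ValueError("hwe_exact_test requires an explicit seed")
    j = table.loci.index(locus)
    calls = _locus_calls(table, pop, j)
    if len(calls) < 3:
        raise ValueError(f"need >=3 genotyped individuals at {locus} in {pop}")
    copies = calls.ravel().copy()
    if len(np.unique(copies)) < 2:
        return 1.0
    obs = _log_genotype_prob(calls)
    rng = np.random.default_rng(seed)
    b = 0
    tol = 1e-9
    for _ in range(reps):
        rng.shuffle(copies)
        if _log_genotype_prob(copies.reshape(-1, 2)) <= obs + tol:
            b += 1
    return (b + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# maximum-likelihood admixture coefficient

def lambda_admixture(table: GenotypeTable, parent1: str, parent2: str,
                     hybrid: str, grid: int | None = None) -> float:
    """ML admixture coefficient of the hybrid population.

    lambda is the proportion of the hybrid gene pool drawn from ``parent2``
    under the per-locus mixture p_H = (1 - lambda) p1 + lambda p2, with
    parental frequencies plugged in from their samples.  Alleles observed in
    the hybrid but unseen in a parent are floored at 1/(2n + 1) in that
    parent (then renormalised) so the likelihood stays finite.  The
    multinomial log-likelihood is concave in lambda, so the bounded scalar
    search returns the global optimum; pass ``grid`` to use an explicit
    grid search instead.
    """
    loglik_terms: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for j in range(len(table.loci)):
        ch = allele_counts(table, hybrid, j)
        if not ch:
            continue
        c1 = allele_counts(table, parent1, j)
        c2 = allele_counts(table, parent2, j)
        n1, n2 = sum(c1.values()), sum(c2.values())
        if n1 == 0 or n2 == 0:
            continue
        states = sorted(set(ch) | set(c1) | set(c2))
        floor1, floor2 = 1.0 / (n1 + 1), 1.0 / (n2 + 1)
        p1 = np.array([max(c1.get(s, 0) / n1, floor1) for s in states])
        p2 = np.array([max(c2.get(s, 0) / n2, floor2) for s in states])
        p1 /= p1.sum()
        p2 /= p2.sum()
        nh = np.array([ch.get(s, 0) for s in states], dtype=float)
        loglik_terms.append((nh, p1, p2))
    if not loglik_terms:
        raise ValueError("no loci informative for lambda")

    def negll(lam: float) -> float:
        total = 0.0
        for nh, p1, p2 in loglik_terms:
            mix = (1.0 - lam) * p1 + lam * p2
            total += float(np.dot(nh, np.log(mix)))
        return -total

    if grid is not None:
        lams = np.linspace(0.0, 1.0, grid)
        return float(lams[np.argmin([negll(l) for l in lams])])
    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def lambda_loglik(table: GenotypeTable, parent1: str, parent2: str,
                  hybrid: str, lam: float) -> float:
    """Mixture log-likelihood at a given lambda (same terms as the estimator)."""
    total = 0.0
    for j in range(len(table.loci)):
        ch = allele_counts(table, hybrid, j)
        if not ch:
            continue
        c1 = allele_counts(table, parent1, j)
        c2 = allele_counts(table, parent2, j)
        n1, n2 = sum(c1.values()), sum(c2.values())
        if n1 == 0 or n2 == 0:
            continue
        states = sorted(set(ch) | set(c1) | set(c2))
        p1 = np.array([max(c1.get(s, 0) / n1, 1.0 / (n1 + 1)) for s in states])
        p2 = np.array([max(c2.get(s, 0) / n2, 1.0 / (n2 + 1)) for s in states])
        p1 /= p1.sum()
        p2 /= p2.sum()
        nh = np.array([ch.get(s, 0) for s in states], dtype=float)
        mix = (1.0 - lam) * p1 + lam * p2
        total += float(np.dot(nh, np.log(mix)))
    return total


# ---------------------------------------------------------------------------
# Evanno delta-K

def delta_k(likelihoods: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    """Evanno delta-K from per-K replicate clustering log-likelihoods.

    For each interior K on a consecutive grid with runs paired by index,
    delta K = mean_runs |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_runs L(K)
    with the sample (n-1) standard deviation.  Endpoints and K with zero
    run-to-run sd have no delta K (NaN).  Returns a frame indexed by K with
    columns ``mean_L``, ``sd_L``, ``delta_k``; the best K is the argmax of
    the defined delta-K values.
    """
    ks = sorted(likelihoods)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >=3 consecutive K values")
    n_runs = {len(likelihoods[k]) for k in ks}
    if len(n_runs) != 1 or min(n_runs) < 2:
        raise ValueError("need the same number (>=2) of runs at every K")
    L = np.array([np.asarray(likelihoods[k], float) for k in ks])  # (K, runs)
    sd = L.std(axis=1, ddof=1)
    dk = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        second = np.abs(L[i + 1] - 2 * L[i] + L[i - 1])
        if sd[i] > 0:
            dk[i] = second.mean() / sd[i]
    return pd.DataFrame(
        {"mean_L": L.mean(axis=1), "sd_L": sd, "delta_k": dk},
        index=pd.Index(ks, name="K"),
    )


def best_k(likelihoods: Mapping[int, Sequence[float]]) -> int:
    """K maximising the Evanno delta-K statistic."""
    frame = delta_k(likelihoods)
    if frame["delta_k"].isna().all():
        raise ValueError("delta K undefined for every interior K")
    return int(frame["delta_k"].idxmax())


# ---------------------------------------------------------------------------
# reporting helpers

def aggregate_mean_sd(values: Iterable[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) sd; sd is NaN for fewer than 2 values."""
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return mean, sd


def pop_stats(table: GenotypeTable, rarefaction_g: int | None = None,
              repeat_length: int = 1) -> pd.DataFrame:
    """Per-population summary table: N, A_R, H_o, H_e, M-ratio."""
    g = rarefaction_g or default_rarefaction_depth(table)
    rows = {}
    for pop in table.pop_labels:
        n = int(table.pop_mask(pop).sum())
        _, ar = allelic_richness(table, pop, g)
        _, ho = observed_heterozygosity(table, pop)
        _, he = expected_heterozygosity(table, pop)
        _, mr = m_ratio(table, pop, repeat_length=repeat_length)
        rows[pop] = {"N": n, "A_R": ar, "H_o": ho, "H_e": he, "M_ratio": mr}
    return pd.DataFrame.from_dict(rows, orient="index")


def summary_stat_vector(table: GenotypeTable, parent1: str, parent2: str,
                        hybrid: str) -> SummaryStatVector:
    """The fixed 10-element ABC summary-statistic vector.

    Order: mean number of alleles per population, mean gene diversity
    (unbiased expected heterozygosity) per population, the three pairwise
    F_ST values, and the ML admixture coefficient lambda (proportion of the
    hybrid gene pool from ``parent2``).  Population order is (parent1,
    hybrid, parent2) ordered as they appear in the table.
    """
    pops = table.pop_labels
    mean_alleles = []
    diversity = []
    for pop in pops:
        ks = []
        for j in range(len(table.loci)):
            counts = allele_counts(table, pop, j)
            if counts:
                ks.append(len(counts))
        mean_alleles.append(float(np.mean(ks)))
        diversity.append(expected_heterozygosity(table, pop)[1])
    fsts = [
        wc_fst(table, a, b)[1]
        for a, b in ((pops[0], pops[1]), (pops[0], pops[2]), (pops[1], pops[2]))
    ]
    lam = lambda_admixture(table, parent1, parent2, hybrid)
    return SummaryStatVector(np.array(mean_alleles + diversity + fsts + [lam]))
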