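"""Fixed-topology allele-frequency covariance model with one migration edge.

Populations drift away from a shared ancestral (root) allele frequency
along the rooted tree ((SFL, MIA), WCU); each branch contributes an
independent drift variance.  A single weighted migration edge from WCU
into MIA makes MIA's frequency a mixture of the two parental paths.  In
deviations from the root frequency ``x0``:

    x_SFL = x0 + e1 + e2
    x_WCU = x0 + e4
    x_MIA = x0 + (1 - w) e1 + w e4 + e3

with independent drift increments ``e_i`` of variance ``c_i``.  Across
allele columns the root frequency itself varies with variance ``v0``, so
the across-column covariance of population frequencies is

    C[i, j] = v0 + V[i, j](c, w)

    Var(SFL)      = c1 + c2          Cov(SFL, MIA) = (1 - w) c1
    Var(WCU)      = c4               Cov(WCU, MIA) = w c4
    Var(MIA)      = (1-w)^2 c1 + w^2 c4 + c3       Cov(SFL, WCU) = 0

(the ``v0`` intercept entering every entry).  Because the root frequency
is common to all populations, only this shared-intercept structure — not
any per-column centering — preserves the information that identifies the
migration weight with three populations; see the methods note.

Parameters are fit by maximising a Gaussian likelihood over the six unique
covariance entries with a common error variance (profile-estimated,
optionally floored by a jackknife estimate of the entries' sampling error)
via multi-start box-constrained optimisation.  ``w = 0`` recovers the
strictly bifurcating tree, giving a nested pair for a likelihood-ratio
test of the migration edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FreqMatrix",
    "MigrationGraphFit",
    "allele_frequencies",
    "covariance_matrix",
    "covariance_entry_sd",
    "fit_graph",
    "likelihood_ratio_test",
    "variance_explained",
]

_N_ENTRIES = 6  # unique entries of a symmetric 3x3
_TRIU = np.triu_indices(3)


@dataclass
class FreqMatrix:
    """Per-population allele-indicator frequencies.

    ``freqs`` has one row per population and one column per (locus, allele)
    indicator; ``columns`` records the locus name and allele state;
    ``copies`` the non-missing gene-copy counts behind each entry.
    """

    pops: list[str]
    freqs: np.ndarray
    columns: pd.DataFrame        # columns: locus, allele
    copies: np.ndarray           # (n_pops, n_cols) gene-copy counts

    def __post_init__(self) -> None:
        if self.freqs.shape[0] != len(self.pops):
            raise ValueError("one frequency row per population required")


@dataclass
class MigrationGraphFit:
    """Fitted drift parameters, migration weight and diagnostics."""

    pops: list[str]
    root_var: float              # v0: across-column variance of root frequency
    drift: dict[str, float]      # c1..c4 keyed by branch name
    w: float
    loglik: float
    fitted_cov: np.ndarray
    residuals: np.ndarray
    sse: float
    allow_migration: bool
    error_sd: float | None = None
    n_restarts_converged: int = 0
    topology: str = "((SFL,MIA),WCU);"


def allele_frequencies(table: GenotypeTable,
                       pops: list[str] | None = None) -> FreqMatrix:
    """Sample allele-indicator frequencies per population.

    Microsatellite alleles enter as one indicator column per distinct
    allele state per locus.  Loci monomorphic in the pooled sample carry no
    frequency variation and are dropped; loci with no non-missing calls in
    some population are dropped with a warning.
    """
    pops = pops or table.pop_labels
    cols: list[tuple[str, int]] = []
    freq_rows: list[list[float]] = [[] for _ in pops]
    copy_rows: list[list[int]] = [[] for _ in pops]
    for j, locus in enumerate(table.loci):
        per_pop = []
        ok = True
        for p in pops:
            calls = table.alleles[table.pop_mask(p), j, :]
            calls = calls[calls[:, 0] != MISSING]
            if len(calls) == 0:
                logger.warning("locus %s has no calls in %s; dropped", locus, p)
                ok = False
                break
            per_pop.append(calls.ravel())
        if not ok:
            continue
        pooled = np.concatenate(per_pop)
        states = np.unique(pooled)
        if len(states) < 2:
            continue  # pooled-monomorphic locus carries no signal
        for s in states:
            for k, copies in enumerate(per_pop):
                freq_rows[k].append(float(np.mean(copies == s)))
                copy_rows[k].append(len(copies))
            cols.append((locus, int(s)))
    if not cols:
        raise ValueError("no polymorphic loci available")
    columns = pd.DataFrame(cols, columns=["locus", "allele"])
    return FreqMatrix(list(pops), np.array(freq_rows), columns,
                      np.array(copy_rows))


def covariance_matrix(freq: FreqMatrix) -> np.ndarray:
    """Across-column covariance of the population frequency rows.

    Treats allele columns as observations: each population's row is
    centered by its own mean across columns and the covariance is the mean
    over columns of the outer products.  The shared component contributed
    by the varying root frequency is retained (it appears as a common
    offset on every entry and is absorbed by the model's ``v0``); centering
    columns across populations instead would destroy the information that
    identifies the migration weight.
    """
    m = freq.freqs.shape[1]
    if m < 10:
        logger.warning("only %d allele columns; covariance will be noisy", m)
    centered = freq.freqs - freq.freqs.mean(axis=1, keepdims=True)
    return centered @ centered.T / m


def covariance_entry_sd(freq: FreqMatrix) -> float:
    """Delete-one-column jackknife sd of the covariance entries (pooled).

    Returns the root-mean-square of the per-entry jackknife standard
    errors — a single sampling-noise scale for the six unique entries,
    suitable as ``error_sd`` for :func:`fit_graph`.
    """
    x = freq.freqs
    m = x.shape[1]
    if m < 3:
        raise ValueError("need at least 3 allele columns for the jackknife")
    xc = x - x.mean(axis=1, keepdims=True)
    full = xc @ xc.T
    jack = np.empty((m, _N_ENTRIES))
    for c in range(m):
        mask = np.ones(m, bool)
        mask[c] = False
        xm = x[:, mask]
        xmc = xm - xm.mean(axis=1, keepdims=True)
        jack[c] = ((xmc @ xmc.T) / (m - 1))[_TRIU]
    var = (m - 1) / m * ((jack - jack.mean(axis=0)) ** 2).sum(axis=0)
    return float(np.sqrt(var.mean()))


def _model_cov(theta: np.ndarray) -> np.ndarray:
    v0, c1, c2, c3, c4, w = theta
    v = np.empty((3, 3))
    v[0, 0] = c1 + c2
    v[1, 1] = (1 - w) ** 2 * c1 + w ** 2 * c4 + c3
    v[2, 2] = c4
    v[0, 1] = v[1, 0] = (1 - w) * c1
    v[0, 2] = v[2, 0] = 0.0
    v[1, 2] = v[2, 1] = w * c4
    return v + v0


def _sse(theta: np.ndarray, cov: np.ndarray) -> float:
    diff = (_model_cov(theta) - cov)[_TRIU]
    return float(diff @ diff)


def _loglik(sse: float, floor_var: float) -> float:
    m = _N_ENTRIES
    sigma2 = max(sse / m, floor_var)
    return -0.5 * m * np.log(2 * np.pi * sigma2) - sse / (2 * sigma2)


def fit_graph(cov: np.ndarray, allow_migration: bool = True,
              restarts: int = 8, seed: int = 0,
              error_sd: float | None = None) -> MigrationGraphFit:
    """Fit the drift/migration model to a 3x3 frequency covariance.

    Population order is (SFL, MIA, WCU) — native, hybrid, donor.  The
    Gaussian likelihood over the six unique entries is maximised
    (equivalently, entry-wise least squares) by L-BFGS-B from a
    method-of-moments start plus ``restarts`` seeded random starts; with
    ``allow_migration=False`` the weight is pinned at zero.  ``error_sd``
    (e.g. from :func:`covariance_entry_sd`) floors the profiled error
    variance so the likelihood stays finite when the model saturates the
    entries.
    """
    cov = np.asarray(cov, float)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be a symmetric 3x3 matrix")
    rng = np.random.default_rng(seed)
    scale = max(float(np.abs(cov).max()), 1e-12)
    wmax = 0.999 if allow_migration else 0.0
    # v0 may be negative: compositional allele-indicator columns give every
    # entry a small negative structural offset on top of the root variance
    bounds = [(None, None)] + [(0.0, None)] * 4 + [(0.0, wmax)]
    # method-of-moments start: v0 from the SFL/WCU covariance, w from the
    # excess MIA/WCU covariance
    v0_mm = cov[0, 2]
    c4_mm = max(cov[2, 2] - v0_mm, 1e-3 * scale)
    w_mm = np.clip((cov[1, 2] - v0_mm) / c4_mm, 0.0, wmax)
    c1_mm = max((cov[0, 1] - v0_mm) / max(1 - w_mm, 1e-3), 1e-3 * scale)
    starts = [np.array([v0_mm, c1_mm, max(cov[0, 0] - v0_mm - c1_mm, 1e-3 * scale),
                        0.1 * scale, c4_mm, w_mm])]
    for _ in range(restarts):
        starts.append(np.array([
            *(rng.uniform(0.01, 1.0, 5) * scale),
            rng.uniform(0.0, 0.8) * (wmax > 0),
        ]))
    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(_sse, x0, args=(cov,), method="L-BFGS-B", bounds=bounds)
        if res.success:
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if n_ok == 0:
        raise RuntimeError(f"optimizer failed on all restarts: {best.message}")
    theta = best.x
    fitted = _model_cov(theta)
    sse = _sse(theta, cov)
    floor_var = (error_sd ** 2) if error_sd else (1e-10 * scale) ** 2
    return MigrationGraphFit(
        pops=["SFL", "MIA", "WCU"],
        root_var=float(theta[0]),
        drift={"root_to_inner": theta[1], "inner_to_SFL": theta[2],
               "inner_to_MIA": theta[3], "root_to_WCU": theta[4]},
        w=float(theta[5]),
        loglik=_loglik(sse, floor_var),
        fitted_cov=fitted,
        residuals=cov - fitted,
        sse=sse,
        allow_migration=allow_migration,
        error_sd=error_sd,
        n_restarts_converged=n_ok,
    )


def likelihood_ratio_test(fit0: MigrationGraphFit, fit1: MigrationGraphFit,
                          tol: float = 1e-2) -> tuple[float, float]:
    """LRT of the migration edge: returns (statistic, p-value).

    ``fit0`` is the bifurcating (w = 0) model nested in ``fit1``.  The
    statistic 2*(ll1 - ll0) is referred to chi-square with one degree of
    freedom; because w sits on the boundary of its support under the null
    this reference distribution is conservative, which is logged.
    """
    if fit0.allow_migration or not fit1.allow_migration:
        raise ValueError("fit0 must be the no-migration model, fit1 the full one")
    stat = 2.0 * (fit1.loglik - fit0.loglik)
    if stat < -tol:
        raise RuntimeError(
            f"nested model has higher likelihood (stat={stat:.3g}); "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    logger.info("boundary caveat: chi2(1) reference is conservative for w=0")
    return stat, float(chi2.sf(stat, df=1))


def variance_explained(fit: MigrationGraphFit, cov: np.ndarray) -> float:
    """Proportion of covariance-entry variance explained: 1 - SSE/SST.

    SST is taken around the mean of the six unique observed entries.
    """
    cov = np.asarray(cov, float)
    obs = cov[_TRIU]
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed covariance entries are constant; R^2 undefined")
    sse = float(np.sum((obs - fit.fitted_cov[_TRIU]) ** 2))
    return 1.0 - sse / sst
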