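"""Rejection-ABC engine for the demographic scenario.

Workflow: draw parameter vectors from the prior, simulate a study-shaped
dataset per draw, reduce each to the fixed 10-element summary-statistic
vector, then retain the ``n_keep`` draws whose statistics fall closest to
the observed vector in standardized Euclidean distance.  Posterior point
summaries (median, KDE mode, 95% equal-tailed interval) and a posterior
predictive check complete the stage.

Distances are standardized per statistic by the robust scale
1.4826 * MAD estimated from the reference table (falling back to the
sample sd when the MAD is zero), which makes rejection invariant to affine
rescaling of any statistic column.  An optional local-linear regression
adjustment of the accepted draws is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalsim import DemographicModel, simulate_dataset
from .io import PopulationMap
from .sumstats import SUMMARY_STAT_NAMES, SummaryStatVector, summary_stat_vector

__all__ = [
    "PriorSpec",
    "SimulationTable",
    "ABCPosterior",
    "default_priors",
    "sample_prior",
    "build_reference_table",
    "observed_stats",
    "reject",
    "posterior_summary",
    "posterior_predictive_check",
]

PARAM_NAMES = ("n_sfl", "n_mia", "n_wcu", "t_admix", "r_admix", "t_split")


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors: family ('uniform' | 'loguniform')
    with finite bounds."""

    params: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for name, (family, lo, hi) in self.params.items():
            if family not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown family {family!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: invalid bounds ({lo}, {hi})")
            if family == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform requires lo > 0")

    def bounds(self, name: str) -> tuple[float, float]:
        return self.params[name][1:]


def default_priors() -> PriorSpec:
    """Study priors: uniform effective sizes (100-10,000), admixture time
    1-4,000 generations, split time 6-13 million generations, admixture
    rate uniform on (0, 1)."""
    return PriorSpec({
        "n_sfl": ("uniform", 100, 10_000),
        "n_mia": ("uniform", 100, 10_000),
        "n_wcu": ("uniform", 100, 10_000),
        "t_admix": ("uniform", 1, 4_000),
        "r_admix": ("uniform", 0.0, 1.0),
        "t_split": ("uniform", 6e6, 1.3e7),
    })


@dataclass
class SimulationTable:
    """Parameter draws paired with summary-statistic vectors."""

    params: pd.DataFrame
    stats: pd.DataFrame
    seed: int
    prior: PriorSpec

    def __post_init__(self) -> None:
        if list(self.stats.columns) != list(SUMMARY_STAT_NAMES):
            raise ValueError("statistic columns out of order")
        if len(self.params) != len(self.stats):
            raise ValueError("params/stats row mismatch")
        if self.stats.isna().any().any():
            raise ValueError("summary statistics contain missing values")

    def __len__(self) -> int:
        return len(self.params)

    def to_csv(self, path) -> None:
        pd.concat([self.params, self.stats], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1,
                 prior: PriorSpec | None = None) -> "SimulationTable":
        frame = pd.read_csv(path)
        params = frame[[c for c in frame.columns if c in PARAM_NAMES]]
        stats = frame[list(SUMMARY_STAT_NAMES)]
        return cls(params, stats, seed, prior or default_priors())


@dataclass
class ABCPosterior:
    """Accepted draws with distances, sorted ascending by distance."""

    accepted: pd.DataFrame          # parameter columns
    distances: np.ndarray
    scale: pd.Series                # per-stat standardization scale
    observed: pd.Series
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.accepted)


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator,
                 ) -> pd.DataFrame:
    """Draw ``n`` i.i.d. parameter vectors from the prior."""
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (family, lo, hi) in spec.params.items():
        if family == "uniform":
            cols[name] = rng.uniform(lo, hi, n)
        else:
            cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return pd.DataFrame(cols)


def _model_from_row(row: pd.Series, mu: float, gsm_p: float) -> DemographicModel:
    return DemographicModel(
        n_sfl=float(row["n_sfl"]), n_mia=float(row["n_mia"]),
        n_wcu=float(row["n_wcu"]), t_admix=float(row["t_admix"]),
        r_admix=float(row["r_admix"]), t_split=float(row["t_split"]),
        mu=mu, gsm_p=gsm_p,
    )


def _row_rng(seed: int, row: int) -> np.random.Generator:
    # per-row seed stream: reproducible independently of evaluation order
    return np.random.default_rng(np.random.SeedSequence([seed, row]))


def observed_stats(dataset, parent1: str = "SFL", parent2: str = "WCU",
                   hybrid: str = "MIA") -> pd.Series:
    """Summary-statistic vector of an observed (or synthetic) dataset."""
    vec = summary_stat_vector(dataset.genotypes if hasattr(dataset, "genotypes")
                              else dataset, parent1, parent2, hybrid)
    return vec.as_series()


def build_reference_table(spec: PriorSpec, samples: PopulationMap,
                          n_loci: int = 18, n_sims: int = 20_000,
                          seed: int = 0, mu: float = 5e-4,
                          gsm_p: float = 1.0,
                          progress: bool = False) -> SimulationTable:
    """Simulate the ABC reference table: one dataset per prior draw.

    Each row is simulated from a sub-seed derived from ``(seed, row)`` so
    the table is reproducible row-by-row.  A failed simulation (degenerate
    statistics) is re-drawn from a fresh sub-stream and logged in the
    table's metadata.
    """
    if n_sims < 100:
        raise ValueError("reference table needs at least 100 simulations")
    params = sample_prior(spec, n_sims, seed)
    rows = np.empty((n_sims, len(SUMMARY_STAT_NAMES)))
    iterator = range(n_sims)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="simulating")
        except ImportError:
            pass
    for i in iterator:
        attempt = 0
        while True:
            rng = _row_rng(seed, i + attempt * n_sims)
            try:
                ds = simulate_dataset(_model_from_row(params.iloc[i], mu, gsm_p),
                                      samples, n_loci, rng)
                vec = summary_stat_vector(ds.genotypes, "SFL", "WCU", "MIA")
                break
            except (ValueError, FloatingPointError):
                attempt += 1
                if attempt > 5:
                    raise
        rows[i] = vec.values
    stats = pd.DataFrame(rows, columns=list(SUMMARY_STAT_NAMES))
    return SimulationTable(params, stats, seed, spec)


def _robust_scale(stats: pd.DataFrame, observed: pd.Series) -> pd.Series:
    med = stats.median()
    mad = (stats - med).abs().median()
    scale = 1.4826 * mad
    fallback = stats.std(ddof=1)
    scale = scale.where(scale > 0, fallback)
    # a constant column carries no information; it is only an error if the
    # observed value disagrees with the constant
    const = scale <= 0
    if const.any():
        mismatch = const & (stats.iloc[0] != observed)
        if mismatch.any():
            raise ValueError(
                f"degenerate statistic column(s) conflicting with observed: "
                f"{mismatch.index[mismatch].tolist()}")
        scale = scale.mask(const, 1.0)
    return scale


def reject(table: SimulationTable, observed: pd.Series | SummaryStatVector,
           n_keep: int = 200, regression_adjust: bool = False) -> ABCPosterior:
    """Retain the ``n_keep`` draws closest to the observed statistics.

    Statistics are standardized by 1.4826*MAD (sd fallback) estimated from
    the reference table; the distance is Euclidean on the standardized
    vectors; ties break by row index.  With ``regression_adjust`` the
    accepted draws are post-processed by a local-linear (Beaumont-style)
    regression of parameters on statistics, with Epanechnikov weights and
    log/logit transforms keeping adjusted draws inside the prior support.
    """
    if isinstance(observed, SummaryStatVector):
        observed = observed.as_series()
    observed = observed[list(SUMMARY_STAT_NAMES)].astype(float)
    if observed.isna().any():
        bad = observed.index[observed.isna()].tolist()
        raise ValueError(f"observed statistics undefined: {bad}")
    if n_keep > len(table):
        raise ValueError("n_keep exceeds table size")
    scale = _robust_scale(table.stats, observed)
    z = (table.stats - observed) / scale
    dist = np.sqrt((z ** 2).sum(axis=1).to_numpy())
    order = np.lexsort((np.arange(len(dist)), dist))[:n_keep]
    accepted = table.params.iloc[order].reset_index(drop=True).copy()
    distances = dist[order]
    diagnostics = {"n_table": len(table), "n_keep": n_keep,
                   "max_distance": float(distances[-1])}
    if regression_adjust:
        accepted = _loclinear_adjust(table, order, distances, observed,
                                     scale, accepted)
        diagnostics["regression_adjusted"] = True
    return ABCPosterior(accepted, distances, scale, observed, diagnostics)


def _loclinear_adjust(table: SimulationTable, order: np.ndarray,
                      distances: np.ndarray, observed: pd.Series,
                      scale: pd.Series, accepted: pd.DataFrame) -> pd.DataFrame:
    """Beaumont local-linear regression adjustment on transformed scales."""
    X = ((table.stats.iloc[order] - observed) / scale).to_numpy()
    dmax = distances[-1] if distances[-1] > 0 else 1.0
    w = 1.0 - (distances / dmax) ** 2  # Epanechnikov kernel
    w = np.clip(w, 1e-8, None)
    Xd = np.column_stack([np.ones(len(X)), X])
    W = np.sqrt(w)[:, None]
    out = {}
    for name in accepted.columns:
        lo, hi = table.prior.bounds(name)
        y = accepted[name].to_numpy().astype(float)
        # logit transform onto the prior support to keep adjustments inside
        span = hi - lo
        u = np.clip((y - lo) / span, 1e-9, 1 - 1e-9)
        ty = np.log(u / (1 - u))
        beta, *_ = np.linalg.lstsq(Xd * W, ty * W[:, 0], rcond=None)
        resid = ty - Xd @ beta
        ty_adj = beta[0] + resid
        u_adj = 1.0 / (1.0 + np.exp(-ty_adj))
        out[name] = lo + span * u_adj
    return pd.DataFrame(out)


def posterior_summary(posterior: ABCPosterior | pd.DataFrame) -> pd.DataFrame:
    """Median, KDE mode, and 95% equal-tailed interval per parameter.

    The mode is the argmax of a Gaussian kernel density (Silverman
    bandwidth) evaluated on a 512-point grid spanning the accepted range;
    degenerate (zero-variance) parameters report the common value.
    """
    accepted = posterior.accepted if isinstance(posterior, ABCPosterior) else posterior
    if len(accepted) < 20:
        raise ValueError("need at least 20 accepted draws to summarise")
    rows = {}
    for name in accepted.columns:
        x = accepted[name].to_numpy().astype(float)
        lo, hi = np.quantile(x, [0.025, 0.975])
        if np.ptp(x) == 0:
            mode = float(x[0])
        else:
            kde = gaussian_kde(x, bw_method="silverman")
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        rows[name] = {"median": float(np.median(x)), "mode": mode,
                      "ci_low": float(lo), "ci_high": float(hi)}
    return pd.DataFrame.from_dict(rows, orient="index")


def posterior_predictive_check(posterior: ABCPosterior, samples: PopulationMap,
                               n_loci: int = 18, n_draws: int = 100,
                               seed: int = 0, mu: float = 5e-4,
                               gsm_p: float = 1.0) -> pd.DataFrame:
    """Two-sided predictive p-value per summary statistic.

    Re-simulates datasets at parameter vectors resampled from the accepted
    set and compares each simulated statistic with the observed value:
    p = 2 * min(P(sim <= obs), P(sim >= obs)) with the plus-one correction.
    """
    if n_draws > len(posterior):
        raise ValueError("n_draws exceeds the accepted count")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(posterior), n_draws)
    sims = np.empty((n_draws, len(SUMMARY_STAT_NAMES)))
    for k, i in enumerate(idx):
        row = posterior.accepted.iloc[int(i)]
        ds = simulate_dataset(_model_from_row(row, mu, gsm_p), samples,
                              n_loci, _row_rng(seed, k + 1))
        sims[k] = summary_stat_vector(ds.genotypes, "SFL", "WCU", "MIA").values
    obs = posterior.observed.to_numpy()
    le = (sims <= obs).sum(axis=0)
    ge = (sims >= obs).sum(axis=0)
    p = 2.0 * np.minimum(le + 1, ge + 1) / (n_draws + 1)
    frame = pd.DataFrame({
        "observed": obs,
        "sim_mean": sims.mean(axis=0),
        "sim_sd": sims.std(axis=0, ddof=1),
        "p_value": np.minimum(p, 1.0),
    }, index=list(SUMMARY_STAT_NAMES))
    return frame
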