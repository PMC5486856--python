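"""The two statistical studies around the simulator.

1. A mixed-level full factorial (2 x 3 x 4 x 6 = 144 runs) over the
   wound radius ``c_I``, the initial wound fill ``I_w``, the collagen
   secretion rate ``k_rho`` and the myofibroblast apoptosis rate
   ``delta_M``, analyzed by OLS regression of the Rankit-normalized
   day-42 relative wound area on the z-scored factors, with squared
   semipartial correlations (sr^2) as unique variance shares.

2. A probabilistic (Monte-Carlo) analysis: 100 draws of
   (k_rho, delta_M) from Gaussians, one simulation per draw, with
   summary statistics, an Anderson-Darling normality test of the
   resulting relative-area distribution, and the pairwise Pearson
   correlation matrix among inputs and day-42 outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import observables as obs
from . import parameters as par
from . import radial_solver

logger = logging.getLogger(__name__)

__all__ = [
    "FactorialDesign",
    "RegressionResult",
    "MonteCarloConfig",
    "MonteCarloResult",
    "build_factorial_design",
    "rankit_normalize",
    "zscore",
    "ols_with_semipartials",
    "anderson_darling_normality",
    "pearson_with_p",
    "run_factorial_experiment",
    "run_probabilistic_experiment",
]

FACTOR_LEVELS: dict[str, np.ndarray] = {
    "c_I": np.array([3.57, 3.99]),
    "I_w": np.array([0.10, 0.15, 0.20]),
    "k_rho": np.array([1.25e-8, 1.75e-8, 2.25e-8, 2.75e-8]),
    "delta_M": np.array([1e-2, 2e-2, 3e-2, 4e-2, 5e-2, 6e-2]),
}


@dataclass
class FactorialDesign:
    """Full crossing of the four factors in lexicographic row order."""

    factors: dict[str, np.ndarray]
    table: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.table)


@dataclass
class RegressionResult:
    predictors: list[str]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sr2: np.ndarray
    r2: float
    r2_adj: float
    f_stat: float
    df_model: int
    df_resid: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictors, "beta": self.beta, "t": self.t,
            "p": self.p, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "sr2": self.sr2,
        })


@dataclass
class MonteCarloConfig:
    """Gaussian input distributions of the probabilistic analysis."""

    n_draws: int = 100
    k_rho_mean: float = 2e-8        # g/(cells day)
    k_rho_sd: float = 3.75e-9
    delta_M_mean: float = 3.5e-2    # /day
    delta_M_sd: float = 1.25e-2
    I_w: float = 1.5e-1
    c_I: float = 3.78               # cm
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")
        if self.k_rho_sd <= 0 or self.delta_M_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass
class MonteCarloResult:
    draws: pd.DataFrame            # per-draw inputs and day-42 outputs
    mean_area: float
    sd_area: float
    skew_area: float
    ad_statistic: float            # corrected A2* of the relative areas
    ad_p: float
    input_ad: dict[str, tuple[float, float]]
    correlations: pd.DataFrame     # Pearson r
    correlation_p: pd.DataFrame
    engine: str = "radial"
    config: MonteCarloConfig | None = None
    n_redraws: int = 0
    extras: dict = field(default_factory=dict)


def build_factorial_design() -> FactorialDesign:
    """The 144-row mixed-level full factorial (levels 2, 3, 4, 6).

    Levels divide each factor's reported range equally, endpoints
    included; rows are ordered lexicographically by
    (c_I, I_w, k_rho, delta_M).
    """
    names = list(FACTOR_LEVELS)
    grids = np.meshgrid(*[FACTOR_LEVELS[n] for n in names], indexing="ij")
    table = pd.DataFrame({n: g.ravel() for n, g in zip(names, grids)})
    return FactorialDesign(factors=dict(FACTOR_LEVELS), table=table)


def rankit_normalize(values) -> np.ndarray:
    """Rankit normal scores: rank r of n maps to Phi^{-1}((r - 0.5)/n).

    Ties receive average ranks.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.ptp(x) == 0.0:
        raise ValueError("all values identical: normal scores undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def zscore(values) -> np.ndarray:
    """Standard scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def ols_with_semipartials(y, X, names=None) -> RegressionResult:
    """OLS with intercept; sr^2 per predictor as the drop in R^2.

    ``y`` is the (normalized) response, ``X`` the (standardized)
    predictor matrix.  t/p/CI come from the t distribution with
    n - p - 1 df; F is the global fit statistic.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p_ = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p_)]
    if n <= p_ + 1:
        raise ValueError("not enough rows for the requested predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p_ + 1:
        corr = np.corrcoef(X, rowvar=False)
        bad = [names[i] for i in range(p_)
               if np.any(np.abs(corr[i, :i]) > 1 - 1e-10)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    r2 = fit.rsquared
    sr2 = np.empty(p_)
    for i in range(p_):
        sub = np.delete(X, i, axis=1)
        sr2[i] = r2 - sm.OLS(y, sm.add_constant(sub)).fit().rsquared
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        predictors=list(names),
        beta=fit.params[1:], t=fit.tvalues[1:], p=fit.pvalues[1:],
        ci_lower=ci[1:, 0], ci_upper=ci[1:, 1], sr2=sr2,
        r2=r2, r2_adj=fit.rsquared_adj, f_stat=fit.fvalue,
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
    )


def anderson_darling_normality(sample) -> tuple[float, float]:
    """Anderson-Darling test with mean and variance estimated.

    Returns the small-sample-corrected statistic
    ``A2* = A2 (1 + 0.75/n + 2.25/n^2)`` and its p value from the
    standard piecewise-exponential approximation for the
    estimated-parameters case.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance sample")
    z = stats.norm.cdf((x - mu) / sd)
    z = np.clip(z, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
    elif a2s > 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s ** 2)
    elif a2s > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s ** 2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s ** 2)
    return float(a2s), float(min(max(p, 0.0), 1.0))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# experiment drivers


def _engine_callable(engine):
    if callable(engine):
        return engine
    if engine in ("radial", None):
        return radial_solver.run_simulation
    if engine == "fem2d":
        from . import fem2d
        return run_2d_like_radial(fem2d.run_simulation_2d)
    raise ValueError(f"unknown engine {engine!r}")


def run_2d_like_radial(fn):
    def wrapped(p, t_end, output_times):
        return fn(p, t_end=t_end, output_times=output_times)
    return wrapped


def _simulate_day42(run, params: par.DimensionalParameters):
    res = run(params, 42.0, [0.0, 42.0])
    area = obs.relative_area(res, 42.0)
    m_avg, rho_avg = obs.probe_average(res, 42.0)
    return area, m_avg, rho_avg


def run_factorial_experiment(engine="radial",
                             design: FactorialDesign | None = None,
                             base_params: par.DimensionalParameters | None = None,
                             ) -> tuple[pd.DataFrame, RegressionResult]:
    """One deterministic run per design row; Rankit/z-score/OLS pipeline.

    Returns the per-run table (factors + day-42 relative area) and the
    fitted regression.
    """
    run = _engine_callable(engine)
    if design is None:
        design = build_factorial_design()
    if base_params is None:
        base_params = par.DimensionalParameters()
    rows = []
    failures = []
    for idx, row in design.table.iterrows():
        p = par.with_overrides(base_params, **{k: float(v)
                                               for k, v in row.items()})
        try:
            area, m_avg, rho_avg = _simulate_day42(run, p)
        except Exception as exc:      # pragma: no cover - defensive
            failures.append((int(idx), repr(exc)))
            continue
        rows.append({**{k: float(v) for k, v in row.items()},
                     "relative_area_day42": area,
                     "M_avg_day42": m_avg, "rho_avg_day42": rho_avg})
        logger.info("factorial run %d/%d: area=%.4f", idx + 1,
                    design.n_runs, area)
    if failures:
        raise RuntimeError(f"simulations failed for rows: {failures}")
    table = pd.DataFrame(rows)
    names = list(design.factors)
    y = rankit_normalize(table["relative_area_day42"].to_numpy())
    X = np.column_stack([zscore(table[n].to_numpy()) for n in names])
    reg = ols_with_semipartials(y, X, names)
    return table, reg


def run_probabilistic_experiment(engine="radial",
                                 cfg: MonteCarloConfig | None = None,
                                 base_params: par.DimensionalParameters | None = None,
                                 ) -> MonteCarloResult:
    """100-draw Monte-Carlo propagation of (k_rho, delta_M) uncertainty.

    Non-positive Gaussian draws are rejected and redrawn (logged); the
    input samples are checked for normality (warning only).  Per draw,
    one simulation to day 42 records the relative area and the 9-point
    probe averages of M and rho.
    """
    run = _engine_callable(engine)
    if cfg is None:
        cfg = MonteCarloConfig()
    if base_params is None:
        base_params = par.DimensionalParameters()
    rng = np.random.default_rng(cfg.seed)
    n_redraws = 0

    def draw(mean, sd):
        nonlocal n_redraws
        while True:
            v = rng.normal(mean, sd)
            if v > 0:
                return v
            n_redraws += 1
            logger.info("redrew non-positive sample (mean=%g)", mean)

    k_rho = np.array([draw(cfg.k_rho_mean, cfg.k_rho_sd)
                      for _ in range(cfg.n_draws)])
    delta_M = np.array([draw(cfg.delta_M_mean, cfg.delta_M_sd)
                        for _ in range(cfg.n_draws)])
    input_ad = {}
    for name, sample in (("k_rho", k_rho), ("delta_M", delta_M)):
        try:
            a2s, p_ad = anderson_darling_normality(sample)
        except ValueError:             # degenerate (e.g. zero-spread) sample
            a2s, p_ad = float("nan"), 0.0
        input_ad[name] = (a2s, p_ad)
        if p_ad <= 0.05:
            warnings.warn(f"input sample {name} deviates from normality "
                          f"(AD p = {p_ad:.3f})", RuntimeWarning)

    recs = []
    for i in range(cfg.n_draws):
        p = par.with_overrides(base_params, k_rho=float(k_rho[i]),
                               delta_M=float(delta_M[i]),
                               I_w=cfg.I_w, c_I=cfg.c_I)
        area, m_avg, rho_avg = _simulate_day42(run, p)
        recs.append({"draw": i, "k_rho": k_rho[i], "delta_M": delta_M[i],
                     "relative_area_day42": area, "M_avg_day42": m_avg,
                     "rho_avg_day42": rho_avg})
        logger.info("monte-carlo draw %d/%d: area=%.4f", i + 1,
                    cfg.n_draws, area)
    draws = pd.DataFrame(recs)

    areas = draws["relative_area_day42"].to_numpy()
    sd = areas.std(ddof=1)
    if sd > 0:
        a2s, ad_p = anderson_darling_normality(areas)
        skew = float(stats.skew(areas))
    else:
        a2s, ad_p, skew = float("nan"), float("nan"), 0.0
    cols = ["delta_M", "k_rho", "M_avg_day42", "rho_avg_day42",
            "relative_area_day42"]
    rmat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols,
                        columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                try:
                    r, pv = pearson_with_p(draws[a], draws[b])
                except ValueError:
                    r, pv = float("nan"), float("nan")
                rmat.loc[a, b] = rmat.loc[b, a] = r
                pmat.loc[a, b] = pmat.loc[b, a] = pv
    return MonteCarloResult(
        draws=draws, mean_area=float(areas.mean()), sd_area=float(sd),
        skew_area=skew, ad_statistic=a2s, ad_p=ad_p, input_ad=input_ad,
        correlations=rmat, correlation_p=pmat,
        engine=engine if isinstance(engine, str) else "custom",
        config=cfg, n_redraws=n_redraws,
    )
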