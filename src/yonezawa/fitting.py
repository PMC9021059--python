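"""Least-squares estimation of the adaptive-response parameters.

Both estimators minimise the sum of squared residuals (SSR) between the
delta observed in each two-dose experiment and the delta predicted by the
closed-form model at candidate alphas:

* ``fit_lbfgsb`` — bounded limited-memory quasi-Newton (L-BFGS-B) started
  from a log-spaced multistart grid; deterministic given its configuration.
* ``fit_sga`` — a simplified genetic algorithm: a population of parameter
  triplets evolved by fitness-proportional selection (fitness = 1/SSR) and
  small multiplicative log-normal perturbations whose scale anneals over
  generations; crossover is deliberately absent.  Runs are restarted many
  times and restarts whose final fitness falls more than 1% below the best
  are discarded; the surviving optimum is polished by a local grid search.

Parameter uncertainty is estimated by the Poisson worst-case (upper-lower
bound) method: event counts are shifted by +-1 standard deviation (sqrt(k))
in the directions that maximise/minimise every delta, each extreme dataset
is refitted, and the per-parameter spread is reported.

All searches run in log-parameter space: the alphas are positive and span
orders of magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import linregress

from .params import AdaptiveResponseParams

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "ssr_objective",
    "fit_lbfgsb",
    "fit_sga",
    "poisson_worstcase_uncertainty",
    "linear_trend",
]

# generous positive bounds spanning every plausible alpha by >= 2 orders
# of magnitude: (alpha0 [Gy^-2 h^-3], alpha1 [Gy^-1], alpha2 [h^-1])
DEFAULT_BOUNDS = ((1e-6, 1e6), (1e-3, 1e4), (1e-8, 10.0))


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by both estimators.

    The genetic-algorithm defaults (population 99, many generations, 50
    restarts) mirror the published recipe; tests and routine use pass
    smaller budgets.
    """

    bounds: tuple = DEFAULT_BOUNDS
    grid_points: int = 5          # multistart grid per axis (L-BFGS-B)
    population: int = 99
    generations: int = 200_000
    restarts: int = 50
    mutation_scale: float = 0.5   # initial log-normal sigma
    mutation_scale_min: float = 0.01
    keep_within: float = 0.01     # 1% fitness filter for restarts
    refine: bool = True           # brute-force polish of the SGA optimum
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if any(lo <= 0 or hi <= lo for lo, hi in self.bounds):
            raise ValueError("bounds must be positive with lo < hi")


@dataclass(frozen=True)
class FitResult:
    """Estimated alphas with the objective value and fit diagnostics."""

    params: AdaptiveResponseParams
    ssr: float
    method: str
    variant: str
    n_records: int
    restarts_kept: int = 1
    restarts_discarded: int = 0
    uncertainty: Optional[dict] = None
    config: Optional[FitConfig] = None
    seed: Optional[int] = None

    @property
    def fitness(self) -> float:
        """Reciprocal of the SSR, the genetic algorithm's fitness measure."""
        return 1.0 / self.ssr if self.ssr > 0 else np.inf

    def to_json(self, **kwargs) -> str:
        payload = {
            "params": {
                "alpha0": self.params.alpha0,
                "alpha1": self.params.alpha1,
                "alpha2": self.params.alpha2,
            },
            "ssr": self.ssr,
            "method": self.method,
            "variant": self.variant,
            "n_records": self.n_records,
            "restarts_kept": self.restarts_kept,
            "restarts_discarded": self.restarts_discarded,
            "uncertainty": self.uncertainty,
            "seed": self.seed,
            "config": asdict(self.config) if self.config else None,
        }
        return json.dumps(payload, **kwargs)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records.records  # DatasetBundle


def _delta_batch(
    alphas: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    dt: np.ndarray,
    T: Optional[np.ndarray],
    variant: str,
) -> np.ndarray:
    """Model delta for a (P, 3) batch of alphas over M records -> (P, M).

    Exponents of the form f(D,b) - f(D,a) with b >= a are mathematically
    <= 0 (f is nonincreasing in time); they are clipped at 0 to suppress
    floating-point cancellation at extreme parameter values.
    """
    a0 = alphas[:, 0:1]
    a1 = alphas[:, 1:2]
    a2 = alphas[:, 2:3]

    def f(dose, t):
        a2t = a2 * t
        return a0 / a2**3 * dose**2 * np.exp(-a1 * dose - a2t) * (a2t**2 + 2 * a2t + 2)

    with np.errstate(over="ignore", invalid="ignore"):
        f0 = f(d1, 0.0)
        f_dt = f(d1, dt)
        if variant == "mutations":
            return 1.0 - np.exp(-f_dt) - (d1 / d2) * np.exp(-f0)
        f_T = f(d1, T)
        return (
            1.0
            - np.exp(np.minimum(f_T - f_dt, 0.0))
            - (d1 / d2) * np.exp(np.minimum(f_T - f0, 0.0))
        )


def _extract_design(df: pd.DataFrame, variant: str):
    if variant not in {"lesions", "mutations"}:
        raise ValueError(f"variant must be 'lesions' or 'mutations', got {variant!r}")
    d1 = df["d1_gy"].to_numpy(float)
    d2 = df["d2_gy"].to_numpy(float)
    dt = df["dt_h"].to_numpy(float)
    obs = df["delta"].to_numpy(float)
    if variant == "lesions":
        if "t_h" not in df.columns or df["t_h"].isna().any():
            raise ValueError("the lesions variant requires an observation time t_h per record")
        T = df["t_h"].to_numpy(float)
    else:
        T = None
    return d1, d2, dt, T, obs


def ssr_objective(
    params: Union[AdaptiveResponseParams, Sequence[float]],
    records,
    variant: str = "lesions",
) -> float:
    """Sum of squared (delta_obs - delta_model) residuals over the records."""
    if isinstance(params, AdaptiveResponseParams):
        a = params.as_array()
    else:
        a = np.asarray(params, dtype=float)
    df = _as_frame(records)
    if len(df) == 0:
        return 0.0
    d1, d2, dt, T, obs = _extract_design(df, variant)
    pred = _delta_batch(a.reshape(1, 3), d1, d2, dt, T, variant)[0]
    return float(np.sum((obs - pred) ** 2))


def _log_bounds(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    lo = np.log([b[0] for b in config.bounds])
    hi = np.log([b[1] for b in config.bounds])
    return lo, hi


def fit_lbfgsb(
    records,
    variant: str = "lesions",
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Bounded quasi-Newton least squares with log-spaced multistart.

    Deterministic: the starting points are a fixed grid over the (log)
    bounds, the best converged start wins.
    """
    config = config or FitConfig()
    df = _as_frame(records)
    if len(df) < 3:
        import warnings

        warnings.warn(
            f"{len(df)} records for 3 parameters: the fit is underdetermined",
            UserWarning,
            stacklevel=2,
        )
    d1, d2, dt, T, obs = _extract_design(df, variant)
    lo, hi = _log_bounds(config)

    def objective(logp: np.ndarray) -> float:
        pred = _delta_batch(np.exp(logp).reshape(1, 3), d1, d2, dt, T, variant)[0]
        r = obs - pred
        val = float(np.dot(r, r))
        return val if np.isfinite(val) else 1e300

    axes = [np.linspace(l, h, config.grid_points) for l, h in zip(lo, hi)]
    starts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    best = None
    n_failed = 0
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} L-BFGS-B starts diverged (records={len(df)}, variant={variant})"
        )
    return FitResult(
        params=AdaptiveResponseParams.from_array(np.exp(best.x)),
        ssr=float(best.fun),
        method="lbfgsb",
        variant=variant,
        n_records=len(df),
        restarts_kept=len(starts) - n_failed,
        restarts_discarded=n_failed,
        config=config,
        seed=config.seed,
    )


def _sga_single_run(
    rng: np.random.Generator,
    d1, d2, dt, T, obs,
    variant: str,
    config: FitConfig,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[np.ndarray, float]:
    """One seeded run of the simplified genetic algorithm in log space."""
    pop = rng.uniform(lo, hi, size=(config.population, 3))
    sigma = config.mutation_scale
    decay = (config.mutation_scale_min / config.mutation_scale) ** (
        1.0 / max(config.generations - 1, 1)
    )
    best_x, best_ssr = None, np.inf
    for _ in range(config.generations):
        pred = _delta_batch(np.exp(pop), d1, d2, dt, T, variant)
        ssr = np.sum((obs[None, :] - pred) ** 2, axis=1)
        ssr = np.where(np.isfinite(ssr), ssr, 1e300)
        i_best = int(np.argmin(ssr))
        if ssr[i_best] < best_ssr:
            best_ssr = float(ssr[i_best])
            best_x = pop[i_best].copy()
        # fitness-proportional selection (fitness = 1/SSR)
        fitness = 1.0 / (ssr + 1e-300)
        probs = fitness / fitness.sum()
        idx = rng.choice(config.population, size=config.population, p=probs)
        pop = pop[idx]
        # small random changes: multiplicative log-normal perturbations,
        # annealed; the incumbent best re-enters unperturbed (elitism)
        pop = pop + rng.normal(0.0, sigma, size=pop.shape)
        pop[0] = best_x
        np.clip(pop, lo, hi, out=pop)
        sigma *= decay
    return best_x, best_ssr


def _brute_refine(
    center: np.ndarray, d1, d2, dt, T, obs, variant, lo, hi, span: float = 0.05, n: int = 7
) -> tuple[np.ndarray, float]:
    """Local brute-force grid polish around the best SGA point (log space)."""
    axes = [
        np.clip(np.linspace(c - span, c + span, n), l, h)
        for c, l, h in zip(center, lo, hi)
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pred = _delta_batch(np.exp(grid), d1, d2, dt, T, variant)
    ssr = np.sum((obs[None, :] - pred) ** 2, axis=1)
    i = int(np.argmin(ssr))
    return grid[i], float(ssr[i])


def fit_sga(
    records,
    variant: str = "lesions",
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Simplified genetic algorithm fit with restart filtering.

    Restarts whose final fitness is more than ``config.keep_within`` (1%)
    below the best restart are discarded as stuck runs.  Reproducible given
    ``config.seed``.
    """
    config = config or FitConfig()
    df = _as_frame(records)
    d1, d2, dt, T, obs = _extract_design(df, variant)
    lo, hi = _log_bounds(config)
    rng = np.random.default_rng(config.seed)
    runs: list[tuple[np.ndarray, float]] = []
    for _ in range(config.restarts):
        runs.append(_sga_single_run(rng, d1, d2, dt, T, obs, variant, config, lo, hi))
    finite = [(x, s) for x, s in runs if np.isfinite(s)]
    if not finite:
        raise RuntimeError(f"no SGA restart converged ({config.restarts} runs)")
    best_ssr = min(s for _, s in finite)
    best_fitness = 1.0 / best_ssr if best_ssr > 0 else np.inf
    kept = [
        (x, s)
        for x, s in finite
        if best_fitness == np.inf
        or (1.0 / s) >= (1.0 - config.keep_within) * best_fitness
    ]
    x_best, s_best = min(kept, key=lambda t: t[1])
    if config.refine:
        x_ref, s_ref = _brute_refine(x_best, d1, d2, dt, T, obs, variant, lo, hi)
        if s_ref < s_best:
            x_best, s_best = x_ref, s_ref
    return FitResult(
        params=AdaptiveResponseParams.from_array(np.exp(x_best)),
        ssr=float(s_best),
        method="sga",
        variant=variant,
        n_records=len(df),
        restarts_kept=len(kept),
        restarts_discarded=len(runs) - len(kept),
        config=config,
        seed=config.seed,
    )


def poisson_worstcase_uncertainty(
    records,
    best: FitResult,
    variant: str = "lesions",
    config: Optional[FitConfig] = None,
) -> dict:
    """Upper-lower bound (Poisson worst-case) parameter uncertainty.

    Event counts k are treated as Poisson, so one standard deviation is
    sqrt(k).  Two extreme datasets are built — all deltas pushed up
    (N2 + sqrt, N1+2 - sqrt) and all pushed down (reversed) — and refitted
    with the deterministic estimator.  Returns, per parameter, the
    (negative, positive) offsets from the central estimate; the interval
    always brackets it.
    """
    config = config or best.config or FitConfig()
    df = _as_frame(records).copy()
    for col in ("n2_events", "n2_denom", "n12_events", "n12_denom"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(
                "Poisson worst-case bounds need raw event counts and denominators"
            )

    def shifted(direction: int) -> pd.DataFrame:
        out = df.copy()
        n2 = out["n2_events"].to_numpy(float)
        n12 = out["n12_events"].to_numpy(float)
        n2s = np.maximum(n2 + direction * np.sqrt(n2), 1e-9)
        n12s = np.maximum(n12 - direction * np.sqrt(n12), 0.0)
        out["n2_events"] = n2s
        out["n12_events"] = n12s
        out["delta"] = 1.0 - (n12s / out["n12_denom"]) / (n2s / out["n2_denom"])
        return out

    central = best.params.as_array()
    extremes = [fit_lbfgsb(shifted(d), variant, config).params.as_array() for d in (+1, -1)]
    names = ("alpha0", "alpha1", "alpha2")
    bounds = {}
    for i, name in enumerate(names):
        values = [central[i]] + [e[i] for e in extremes]
        bounds[name] = (float(min(values) - central[i]), float(max(values) - central[i]))
    return bounds


def linear_trend(records, x: str = "dt_h", y: str = "delta"):
    """Ordinary least squares of one record field against another.

    Returns (slope, intercept, r_squared).  Used for the empirical
    delta-versus-interval trend in the lymphocyte data.
    """
    df = _as_frame(records)
    if len(df) < 2:
        raise ValueError("need at least 2 points")
    xv = df[x].to_numpy(float)
    yv = df[y].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError(f"degenerate predictor: {x} has zero variance")
    res = linregress(xv, yv)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
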