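"""The delta quantification of the priming-dose (Raper-Yonezawa) effect.

delta = 1 - N_{1+2}/N_2 compares the damage observed after a priming dose D1
followed, dt hours later, by a challenging dose D2 against the damage after
the challenge alone.  delta > 0 means the priming dose protected (the
Yonezawa effect); delta can be negative — down to
delta_min = -(D1/D2) e^{-xi_D1} — when the priming signal has decayed and the
extra D1 lesions merely add to the total.  delta = 1 would be perfect repair
and is unreachable.

Two closed-form variants exist: a finite-observation-time form for direct
DNA lesions and its T -> infinity limit for stable mutations.  Both are
independent of the lesion-induction parameters (mu) once the small metabolic
background is neglected; the mu-dependent form is available when mu is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .kinetics import f_antiderivative, repair_integral, xi
from .params import AdaptiveResponseParams, LesionInductionParams

__all__ = [
    "DeltaResult",
    "ThresholdResult",
    "delta_from_counts",
    "delta_lesions",
    "delta_mutations",
    "delta_min",
    "dt_threshold_ok",
    "delta_two_priming",
    "delta_multi_priming",
]

# heuristic validity guard: the model assumes the challenge is "not too
# large"; alpha1*D2 beyond this triggers a non-fatal warning
HIGH_CHALLENGE_ALPHA1_D2 = 10.0


@dataclass(frozen=True)
class DeltaResult:
    """A computed delta with its dosing scheme and echoed inputs."""

    delta: float
    scheme: str
    inputs: dict = field(default_factory=dict)

    @property
    def yonezawa_effect(self) -> bool:
        """True when the priming dose actually protected (delta > 0)."""
        return self.delta > 0

    def __float__(self) -> float:
        return self.delta


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the inter-dose-interval threshold test (delta >= 0)."""

    satisfied: bool
    boundary_dt: Optional[float]
    satisfiable: bool = True


def _warn_high_challenge(params: AdaptiveResponseParams, challenge: float) -> None:
    if params.alpha1 * challenge > HIGH_CHALLENGE_ALPHA1_D2:
        warnings.warn(
            "challenging dose is large relative to 2/alpha1 (alpha1*D > 10): "
            "the model is unreliable for very high challenges",
            UserWarning,
            stacklevel=3,
        )


def delta_from_counts(
    n2_events: float, n2_denom: float, n12_events: float, n12_denom: float
) -> float:
    """delta = 1 - (N_{1+2} frequency)/(N_2 frequency) from raw experiment counts.

    Negative values are returned as-is: they do not represent a protective
    effect but are informative for calibration.
    """
    if n2_denom <= 0 or n12_denom <= 0:
        raise ValueError("denominators must be > 0")
    if n2_events <= 0:
        raise ValueError("delta is undefined when no events occur under D2 alone")
    return 1.0 - (n12_events / n12_denom) / (n2_events / n2_denom)


def delta_lesions(
    params: AdaptiveResponseParams,
    d1: float,
    d2: float,
    dt: float,
    T: float,
    mu: Optional[LesionInductionParams] = None,
) -> DeltaResult:
    """delta for direct DNA lesions observed at finite time T (0 < dt < T).

    Without mu (the default, used in all fits) the mu-free form is used:

        delta = 1 - e^{f(D1,T)-f(D1,dt)} - (D1/D2) e^{f(D1,T)-f(D1,0)}.

    With mu the background-aware form is used; the two agree exactly at mu0=0.
    """
    if d2 <= 0:
        raise ValueError("delta is undefined for D2 <= 0")
    if d1 < 0:
        raise ValueError("doses must be >= 0")
    if not (0 <= dt < T):
        raise ValueError("require 0 <= dt < T")
    _warn_high_challenge(params, d2)
    prime_late = np.exp(repair_integral(params, d1, dt, T))   # e^{f(D1,T)-f(D1,dt)}
    prime_full = np.exp(repair_integral(params, d1, 0.0, T))  # e^{f(D1,T)-f(D1,0)}
    if mu is None:
        value = 1.0 - prime_late - (d1 / d2) * prime_full
    else:
        n01 = mu.mu0 + mu.mu1 * d1
        n02 = mu.mu1 * d2
        value = (n02 * (1.0 - prime_late) - n01 * prime_full) / n02
    return DeltaResult(
        float(value), "lesions", {"params": params, "d1": d1, "d2": d2, "dt": dt, "T": T, "mu": mu}
    )


def delta_mutations(
    params: AdaptiveResponseParams, d1: float, d2: float, dt: float
) -> DeltaResult:
    """delta for stable mutations (T -> infinity limit of the lesion form):

        delta = 1 - e^{-f(D1,dt)} - (D1/D2) e^{-xi_D1}.
    """
    if d2 <= 0:
        raise ValueError("delta is undefined for D2 <= 0")
    if d1 < 0 or dt < 0:
        raise ValueError("doses and dt must be >= 0")
    _warn_high_challenge(params, d2)
    value = (
        1.0
        - np.exp(-f_antiderivative(params, d1, dt))
        - (d1 / d2) * np.exp(-xi(params, d1))
    )
    return DeltaResult(
        float(value), "mutations", {"params": params, "d1": d1, "d2": d2, "dt": dt}
    )


def delta_min(params: AdaptiveResponseParams, d1: float, d2: float) -> float:
    """Large-dt asymptote of delta: -(D1/D2) e^{-xi_D1} (<= 0, 0 only at D1=0)."""
    if d2 <= 0:
        raise ValueError("delta is undefined for D2 <= 0")
    if d1 < 0:
        raise ValueError("D1 must be >= 0")
    return float(-(d1 / d2) * np.exp(-xi(params, d1)))


def dt_threshold_ok(
    params: AdaptiveResponseParams,
    d1: float,
    d2: float,
    dt: float,
    T: float = np.inf,
) -> ThresholdResult:
    """Test whether the inter-dose interval still yields a protective delta.

    delta >= 0 holds iff f(D1, dt) >= -ln(e^{-f(D1,T)} - (D1/D2) e^{-xi_D1})
    (with f(D1,T)=0 for the mutation endpoint T=inf).  Returns the boolean
    together with the boundary interval at which delta crosses zero, found by
    bracketed root search on f(D1, .).  If the log argument is nonpositive no
    interval can make delta nonnegative (condition unsatisfiable).
    """
    if d2 <= 0:
        raise ValueError("delta is undefined for D2 <= 0")
    if d1 < 0 or dt < 0:
        raise ValueError("doses and dt must be >= 0")
    ln_arg = np.exp(-f_antiderivative(params, d1, T)) - (d1 / d2) * np.exp(-xi(params, d1))
    if ln_arg <= 0:
        return ThresholdResult(satisfied=False, boundary_dt=None, satisfiable=False)
    rhs = -np.log(ln_arg)
    satisfied = bool(f_antiderivative(params, d1, dt) >= rhs)
    if d1 == 0 or rhs <= 0:
        # f(0,.) = 0 or the condition holds for every interval: no boundary
        return ThresholdResult(satisfied=satisfied, boundary_dt=None)
    xi1 = xi(params, d1)
    if rhs > xi1:
        # even dt = 0 fails
        return ThresholdResult(satisfied=False, boundary_dt=None, satisfiable=False)
    hi = 1.0
    while f_antiderivative(params, d1, hi) > rhs:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological parameters
            return ThresholdResult(satisfied=satisfied, boundary_dt=None)
    boundary = brentq(lambda x: f_antiderivative(params, d1, x) - rhs, 0.0, hi, xtol=1e-12)
    return ThresholdResult(satisfied=satisfied, boundary_dt=float(boundary))


def _survivor_recursion(
    params: AdaptiveResponseParams,
    doses: list[float],
    times: list[float],
    challenge: float,
    challenge_time: float,
) -> float:
    """Priming-lesion survival bookkeeping up to the challenge, then T -> inf.

    Walks the dose sequence keeping the running unrepaired-lesion total S
    (mu-free convention: each pulse D injects lesions proportional to D).
    Between consecutive pulses every pool decays under the summed repair
    signal of all pulses already delivered; after the challenge all signals
    integrate to infinity.  Returns N_{1+..+n+*}/(mu1 e^{-xi_D*}) for the
    mutation endpoint, i.e. with the challenge's own lifetime repair factor
    (common to the reference arm) already divided out.
    """
    seq_doses = doses + [challenge]
    seq_times = times + [challenge_time]
    s = 0.0
    for j, (d_j, t_j) in enumerate(zip(seq_doses, seq_times)):
        if j > 0:
            decay = sum(
                repair_integral(params, seq_doses[i], seq_times[j - 1] - seq_times[i], t_j - seq_times[i])
                for i in range(j)
            )
            s *= np.exp(decay)
        s += d_j
    # tail over the priming pulses only: the challenge's own lifetime factor
    # e^{-xi} is common to N_{1+..+n+*} and the reference N_* and cancels in
    # the delta ratio (cancelling it analytically avoids 0/0 underflow)
    tail = sum(
        repair_integral(params, d_i, seq_times[-1] - t_i, np.inf)
        for d_i, t_i in zip(seq_doses[:-1], seq_times[:-1])
    )
    return float(s * np.exp(tail))


def delta_two_priming(
    params: AdaptiveResponseParams,
    d1: float,
    d2: float,
    d3: float,
    dt1: float,
    dt2: float,
) -> DeltaResult:
    """delta for two priming doses D1, D2 before the challenge D3 (mutations):

        delta = 1 - e^{-f(D1,dt1+dt2) - f(D2,dt2)}
                  - (D2/D3) e^{-f(D1,dt1) - xi_D2}
                  - (D1/D3) e^{-xi_D1 - xi_D2}.
    """
    if d3 <= 0:
        raise ValueError("delta is undefined for D3 <= 0")
    if min(d1, d2) < 0 or min(dt1, dt2) < 0:
        raise ValueError("doses and intervals must be >= 0")
    _warn_high_challenge(params, d3)
    value = (
        1.0
        - np.exp(-f_antiderivative(params, d1, dt1 + dt2) - f_antiderivative(params, d2, dt2))
        - (d2 / d3) * np.exp(-f_antiderivative(params, d1, dt1) - xi(params, d2))
        - (d1 / d3) * np.exp(-xi(params, d1) - xi(params, d2))
    )
    return DeltaResult(
        float(value),
        "two_priming",
        {"params": params, "d1": d1, "d2": d2, "d3": d3, "dt1": dt1, "dt2": dt2},
    )


def delta_multi_priming(
    params: AdaptiveResponseParams,
    priming_dose: float,
    challenge_dose: float,
    dt: float,
    n: int,
) -> DeltaResult:
    """delta after n identical priming doses ("radiation training"), mutations.

    n equal pulses D separated by dt, with the challenge D* arriving dt after
    the last one.  Evaluated by the per-dose survival recursion; reduces
    exactly to the single- and two-priming closed forms at n = 1, 2.  The
    dt -> 0, n -> inf limit (chronic exposure) is outside this formula's
    validity and is handled by the chronic-saturation rate instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (no priming dose means delta = 0 by definition)")
    if challenge_dose <= 0:
        raise ValueError("delta is undefined for challenge_dose <= 0")
    if priming_dose < 0 or dt < 0:
        raise ValueError("dose and dt must be >= 0")
    _warn_high_challenge(params, challenge_dose)
    times = [i * dt for i in range(n)]
    n_combined = _survivor_recursion(
        params, [priming_dose] * n, times, challenge_dose, n * dt
    )
    value = 1.0 - n_combined / challenge_dose
    return DeltaResult(
        float(value),
        "multi_priming",
        {
            "params": params,
            "priming_dose": priming_dose,
            "challenge_dose": challenge_dose,
            "dt": dt,
            "n": n,
        },
    )
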