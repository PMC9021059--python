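"""Closed-form adaptive-response kinetics for pulse and chronic exposures.

The probability rate of a successful adaptive-response repair triggered by a
short dose pulse D received t hours ago is the hunchbacked function

    p_AR(D, t) = alpha0 * D^2 * t^2 * exp(-alpha1*D - alpha2*t)   [h^-1]

Its (negative) antiderivative in time has the closed form

    f(D, t) = (alpha0/alpha2^3) * D^2 * exp(-alpha1*D - alpha2*t)
              * ((alpha2*t)^2 + 2*alpha2*t + 2),

so that -integral_a^b p_AR dt = f(D, b) - f(D, a), with f(D, inf) = 0 and
f(D, 0) = xi_D = 2*(alpha0/alpha2^3)*D^2*exp(-alpha1*D), the total lifetime
repair credit of the pulse.  Lesion decay follows dN = -N p_AR dt, giving
N(T) = N0 * exp(f(D,T) - f(D,0)) for a single pulse: nonincreasing in T and
bounded below by N0*exp(-xi_D) — repair never removes every lesion.

t = numpy.inf is accepted everywhere as a first-class sentinel for the
late-time (mutation) limit.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np
from scipy.integrate import quad

from .params import AdaptiveResponseParams, DoseSchedule, LesionInductionParams

__all__ = [
    "p_ar_pulse",
    "f_antiderivative",
    "xi",
    "repair_integral",
    "induced_lesions",
    "lesions_remaining_single",
    "lesions_remaining_two_dose",
    "p_ar_schedule_discrete",
    "p_ar_continuous",
    "chronic_saturation",
]

ArrayLike = Union[float, np.ndarray]


def p_ar_pulse(params: AdaptiveResponseParams, dose: ArrayLike, t: ArrayLike) -> ArrayLike:
    """Adaptive-response probability rate after a single pulse [h^-1].

    Maximal over time at t = 2/alpha2 and over dose at D = 2/alpha1.
    """
    dose = np.asarray(dose, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(invalid="ignore"):
        out = params.alpha0 * dose**2 * t**2 * np.exp(
            -params.alpha1 * dose - params.alpha2 * t
        )
    # D^2 t^2 e^{-...} -> 0 as t -> inf; 0*inf guard
    out = np.where(np.isinf(t), 0.0, out)
    return out if out.ndim else float(out)


def f_antiderivative(params: AdaptiveResponseParams, dose: ArrayLike, t: ArrayLike) -> ArrayLike:
    """Negative time-antiderivative f(D, t) of p_AR (dimensionless, >= 0).

    f is nonincreasing in t, f(D, 0) = xi_D and f(D, inf) = 0.
    """
    dose = np.asarray(dose, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a2t = params.alpha2 * t
    with np.errstate(invalid="ignore", over="ignore"):
        out = (
            params.alpha0 / params.alpha2**3
            * dose**2
            * np.exp(-params.alpha1 * dose - a2t)
            * (a2t**2 + 2.0 * a2t + 2.0)
        )
    out = np.where(np.isinf(t), 0.0, out)
    return out if out.ndim else float(out)


def xi(params: AdaptiveResponseParams, dose: ArrayLike) -> ArrayLike:
    """Lifetime repair credit of one pulse: xi_D = 2*(alpha0/alpha2^3)*D^2*e^{-alpha1 D}.

    Equals f(D, 0); maximal over dose at D = 2/alpha1.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = 2.0 * params.alpha0 / params.alpha2**3 * dose**2 * np.exp(-params.alpha1 * dose)
    return out if out.ndim else float(out)


def repair_integral(
    params: AdaptiveResponseParams, dose: ArrayLike, a: ArrayLike, b: ArrayLike
) -> ArrayLike:
    """-integral_a^b p_AR dt = f(D, b) - f(D, a); always <= 0 for b >= a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a > b):
        raise ValueError("require a <= b")
    out = f_antiderivative(params, dose, b) - f_antiderivative(params, dose, a)
    # exact sign constraint (f nonincreasing); clip float cancellation noise
    out = np.minimum(out, 0.0)
    return out if np.ndim(out) else float(out)


def induced_lesions(mu: LesionInductionParams, dose: ArrayLike) -> ArrayLike:
    """Immediate lesion count N = mu0 + mu1 * D."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = mu.mu0 + mu.mu1 * dose
    return out if out.ndim else float(out)


def lesions_remaining_single(
    params: AdaptiveResponseParams, n0: float, dose: float, T: ArrayLike
) -> ArrayLike:
    """Unrepaired lesions at time T after a single pulse: N0*exp(f(D,T) - f(D,0))."""
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    out = n0 * np.exp(repair_integral(params, dose, 0.0, T))
    return out if np.ndim(out) else float(out)


def lesions_remaining_two_dose(
    params: AdaptiveResponseParams,
    mu: LesionInductionParams,
    d1: float,
    d2: float,
    dt: float,
    T: ArrayLike,
) -> ArrayLike:
    """Unrepaired lesions at time T in the priming+challenging scheme.

    The priming dose D1 arrives at time 0 and induces N01 = mu0 + mu1*D1
    lesions; the challenge D2 at time dt adds N02 = mu1*D2 (the metabolic
    background is counted once).  Repair signals from the two pulses are
    additive, so

        N(T) = (N02 + N01*e^{f(D1,dt)-f(D1,0)})
               * e^{f(D1,T)-f(D1,dt) + f(D2,T-dt)-f(D2,0)}.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be >= 0")
    T = np.asarray(T, dtype=float)
    if np.any(T < dt):
        raise ValueError("require dt <= T")
    n01 = mu.mu0 + mu.mu1 * d1
    n02 = mu.mu1 * d2
    survivors_at_dt = n02 + n01 * np.exp(repair_integral(params, d1, 0.0, dt))
    joint = repair_integral(params, d1, dt, T) + repair_integral(params, d2, 0.0, T - dt)
    out = survivors_at_dt * np.exp(joint)
    return out if np.ndim(out) else float(out)


def p_ar_schedule_discrete(
    params: AdaptiveResponseParams,
    schedule: DoseSchedule,
    age_step: int,
    step_hours: float = 1.0,
) -> float:
    """Summed adaptive-response rate of a discrete pulse schedule at step K.

    Each pulse D_k delivered at step k contributes an independent signal
    p_AR(D_k, (K-k)*step_hours); signals are additive.  Event times are step
    indices here; ``step_hours`` converts a step to hours (default 1 h/step).
    """
    total = 0.0
    for ev in schedule:
        if ev.time > age_step:
            raise ValueError(f"event at step {ev.time} is after age_step {age_step}")
        total += p_ar_pulse(params, ev.dose, (age_step - ev.time) * step_hours)
    return float(total)


def p_ar_continuous(
    params: AdaptiveResponseParams,
    dose_rate_fn: Callable[[float], float],
    tau: float,
    abs_tol: float = 1e-10,
) -> float:
    """Adaptive-response rate under a continuous exposure history.

    Integrates alpha0 * Ddot(t)^2 (tau-t)^2 exp(-alpha1*Ddot(t) - alpha2*(tau-t))
    over t in [0, tau] by adaptive quadrature.  For a constant dose rate and
    tau >> 2/alpha2 this converges to ``chronic_saturation``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")

    def integrand(t: float) -> float:
        rate = dose_rate_fn(t)
        if rate < 0:
            raise ValueError(f"negative dose rate {rate!r} at t={t!r}")
        u = tau - t
        return params.alpha0 * rate**2 * u**2 * np.exp(-params.alpha1 * rate - params.alpha2 * u)

    val, _ = quad(integrand, 0.0, tau, epsabs=abs_tol, limit=200)
    return float(val)


def chronic_saturation(params: AdaptiveResponseParams, dose_rate: ArrayLike) -> ArrayLike:
    """Saturation rate under chronic constant-rate exposure: equals xi(dose_rate)."""
    return xi(params, dose_rate)
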