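"""Parameter containers for the adaptive-response model.

The model of radioadaptation used throughout this package is controlled by
three positive rate parameters:

``alpha0``
    amplitude of the adaptive-response probability rate [Gy^-2 h^-3],
``alpha1``
    dose-decay constant [Gy^-1]; the response is maximal at D = 2/alpha1,
``alpha2``
    time-decay constant [h^-1]; the response is maximal at t = 2/alpha2.

Lesion induction is linear in dose with a small background, N = mu0 + mu1*D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AdaptiveResponseParams",
    "LesionInductionParams",
    "DoseEvent",
    "DoseSchedule",
]


@dataclass(frozen=True)
class AdaptiveResponseParams:
    """The three positive parameters of the adaptive-response rate p_AR.

    Parameters
    ----------
    alpha0 : float
        Rate amplitude, in Gy^-2 h^-3 (or the matching abstract units).
    alpha1 : float
        Dose-decay constant, Gy^-1.
    alpha2 : float
        Time-decay constant, h^-1.
    """

    alpha0: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "alpha2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def dose_at_max(self) -> float:
        """Dose maximising the response rate, 2/alpha1 [Gy]."""
        return 2.0 / self.alpha1

    @property
    def time_at_max(self) -> float:
        """Post-exposure time maximising the response rate, 2/alpha2 [h]."""
        return 2.0 / self.alpha2

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha0, self.alpha1, self.alpha2], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "AdaptiveResponseParams":
        a0, a1, a2 = (float(x) for x in a)
        return cls(a0, a1, a2)


@dataclass(frozen=True)
class LesionInductionParams:
    """Linear lesion-induction law N = mu0 + mu1 * D.

    mu0 is the spontaneous (zero-dose) lesion frequency; mu1 the lesions
    induced per gray.  Typically mu0 << mu1, but that is not enforced.
    """

    mu0: float
    mu1: float

    def __post_init__(self) -> None:
        if self.mu0 < 0:
            raise ValueError(f"mu0 must be >= 0, got {self.mu0!r}")
        if self.mu1 <= 0:
            raise ValueError(f"mu1 must be > 0, got {self.mu1!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single short dose pulse: absorbed dose [Gy] at an exposure instant [h]."""

    dose: float
    time: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered sequence of dose pulses with nondecreasing times."""

    events: tuple[DoseEvent, ...]

    def __init__(self, events: Sequence[DoseEvent]) -> None:
        events = tuple(events)
        times = [e.time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)
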