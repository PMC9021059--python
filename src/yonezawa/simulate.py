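"""Synthetic two-dose experiments with known alphas and Poisson count noise.

The generator emulates the calibration data's structure: a design of
(D1, D2, dt, T) conditions with a per-condition baseline event frequency and
scoring denominator (cells examined).  The expected challenge-only frequency
is the baseline; the expected priming+challenge frequency is
baseline * (1 - delta_model) at the true alphas; observed event counts are
Poisson draws over the denominators, the only noise source (doses and times
are treated as exact, matching how the real experiments are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import DatasetBundle, load_bundled
from .delta import delta_lesions, delta_mutations
from .fitting import FitConfig, fit_lbfgsb
from .params import AdaptiveResponseParams

__all__ = [
    "DesignRow",
    "SyntheticDatasetSpec",
    "table2_like_spec",
    "generate",
    "recovery_experiment",
]


@dataclass(frozen=True)
class DesignRow:
    """One experimental condition of a synthetic design."""

    d1: float
    d2: float
    dt: float
    T: float
    denom: float
    baseline_rate: float

    def __post_init__(self) -> None:
        if self.denom <= 0:
            raise ValueError("denom must be > 0")
        if not (0 < self.baseline_rate <= 1):
            raise ValueError("baseline_rate must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """True alphas + design + noise model for one synthetic dataset."""

    true_params: AdaptiveResponseParams
    design: tuple[DesignRow, ...]
    variant: str = "lesions"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in {"lesions", "mutations"}:
            raise ValueError(f"variant must be 'lesions' or 'mutations', got {self.variant!r}")
        object.__setattr__(self, "design", tuple(self.design))


def table2_like_spec(
    true_params: AdaptiveResponseParams,
    variant: str = "lesions",
    seed: Optional[int] = None,
    denom_scale: float = 1.0,
) -> SyntheticDatasetSpec:
    """A spec mirroring the 23 lymphocyte lesion conditions.

    Doses, intervals, observation times, denominators (200-300 cells) and
    baseline frequencies are taken from the bundled lesion records;
    ``denom_scale`` multiplies all denominators (for consistency checks).
    """
    df = load_bundled("shadley_lesions").records
    design = tuple(
        DesignRow(
            d1=r.d1_gy,
            d2=r.d2_gy,
            dt=r.dt_h,
            T=r.t_h,
            denom=r.n2_denom * denom_scale,
            baseline_rate=r.n2_events / r.n2_denom,
        )
        for r in df.itertuples()
    )
    return SyntheticDatasetSpec(true_params, design, variant=variant, seed=seed)


def _model_delta(spec: SyntheticDatasetSpec, row: DesignRow) -> float:
    if spec.variant == "lesions":
        return delta_lesions(spec.true_params, row.d1, row.d2, row.dt, row.T).delta
    return delta_mutations(spec.true_params, row.d1, row.d2, row.dt).delta


def generate(spec: SyntheticDatasetSpec, noiseless: bool = False) -> DatasetBundle:
    """Draw one synthetic dataset; bitwise reproducible given spec.seed.

    With ``noiseless=True`` the expected (non-integer) counts are used
    directly, making the true alphas an exact zero-residual optimum.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i, row in enumerate(spec.design):
        d_model = _model_delta(spec, row)
        if d_model >= 1:
            raise ValueError(f"design row {i}: model delta {d_model} >= 1 is degenerate")
        mean_n2 = row.baseline_rate * row.denom
        mean_n12 = row.baseline_rate * (1.0 - d_model) * row.denom
        if noiseless:
            n2, n12 = mean_n2, mean_n12
        else:
            n2 = rng.poisson(mean_n2)
            n12 = rng.poisson(mean_n12)
            while n2 == 0:  # delta undefined without challenge-only events
                n2 = rng.poisson(mean_n2)
        rows.append(
            {
                "study": "synthetic",
                "source_table": "-",
                "tissue": "synthetic",
                "endpoint": "synthetic_counts",
                "d1_gy": row.d1,
                "d2_gy": row.d2,
                "dt_h": row.dt,
                "t_h": row.T,
                "n2_events": n2,
                "n2_denom": row.denom,
                "n12_events": n12,
                "n12_denom": row.denom,
                "delta": 1.0 - (n12 / row.denom) / (n2 / row.denom),
                "delta_model": d_model,
            }
        )
    return DatasetBundle(
        name="synthetic",
        records=pd.DataFrame(rows),
        endpoint_class=spec.variant,
        provenance=f"synthetic, seed={spec.seed}",
    )


def recovery_experiment(
    spec: SyntheticDatasetSpec,
    n_replicates: int,
    fit_config: Optional[FitConfig] = None,
    noiseless: bool = False,
) -> dict:
    """Generate-and-refit study: per-parameter bias, RMSE and relative error.

    Each replicate r regenerates the dataset with seed spec.seed + r and
    refits with the deterministic estimator.  Fit failures are counted, not
    fatal.  Returns a summary dict with per-parameter arrays and statistics.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    base_seed = spec.seed or 0
    truth = spec.true_params.as_array()
    fits, failures = [], 0
    for r in range(n_replicates):
        rep_spec = SyntheticDatasetSpec(
            spec.true_params, spec.design, spec.variant, seed=(base_seed + r) % (2**31)
        )
        bundle = generate(rep_spec, noiseless=noiseless)
        try:
            res = fit_lbfgsb(bundle.records, spec.variant, fit_config)
        except RuntimeError:
            failures += 1
            continue
        fits.append(res.params.as_array())
    fits = np.array(fits)
    names = ("alpha0", "alpha1", "alpha2")
    summary: dict = {"n_replicates": n_replicates, "n_failures": failures}
    for i, name in enumerate(names):
        est = fits[:, i]
        rel = np.abs(est - truth[i]) / truth[i]
        summary[name] = {
            "truth": float(truth[i]),
            "bias": float(np.mean(est) - truth[i]),
            "rmse": float(np.sqrt(np.mean((est - truth[i]) ** 2))),
            "median_relative_error": float(np.median(rel)),
            "estimates": est.tolist(),
        }
    return summary
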