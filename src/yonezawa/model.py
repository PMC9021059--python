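"""Model/Results interface over the adaptive-response estimators.

``AdaptiveResponseModel`` wraps a table of two-dose experiment records;
``fit`` runs one of the two least-squares estimators and returns an
``AdaptiveResponseResults`` carrying the alphas, the objective value,
optional Poisson worst-case uncertainty bounds, and a text summary, in the
style familiar from statistical modelling packages.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from . import fitting
from .datasets import DatasetBundle, load_bundled, read_records_csv
from .delta import delta_lesions, delta_mutations
from .fitting import FitConfig, FitResult
from .params import AdaptiveResponseParams

__all__ = ["AdaptiveResponseModel", "AdaptiveResponseResults"]


class AdaptiveResponseModel:
    """Three-parameter adaptive-response model bound to experiment records.

    Parameters
    ----------
    data : DataFrame or DatasetBundle
        Records with columns d1_gy, d2_gy, dt_h, t_h (lesions), delta and,
        for uncertainty estimation, the raw count columns.
    endpoint : {"lesions", "mutations"}
        Which closed-form delta links doses and times to the observation:
        finite-time lesion counts or the late-time mutation limit.
    """

    def __init__(self, data: Union[pd.DataFrame, DatasetBundle], endpoint: str = "lesions"):
        if endpoint not in {"lesions", "mutations"}:
            raise ValueError(f"endpoint must be 'lesions' or 'mutations', got {endpoint!r}")
        self.data = data.records if isinstance(data, DatasetBundle) else data
        self.endpoint = endpoint
        self.source = data.name if isinstance(data, DatasetBundle) else "dataframe"

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, endpoint: str = "lesions") -> "AdaptiveResponseModel":
        return cls(df, endpoint=endpoint)

    @classmethod
    def from_bundled(cls, name: str, endpoint: Optional[str] = None) -> "AdaptiveResponseModel":
        bundle = load_bundled(name)
        return cls(bundle, endpoint=endpoint or bundle.endpoint_class)

    @classmethod
    def from_csv(
        cls, path, endpoint: str = "lesions", dose_unit: str = "gy"
    ) -> "AdaptiveResponseModel":
        bundle = read_records_csv(path, dose_unit=dose_unit, endpoint_class=endpoint)
        return cls(bundle, endpoint=endpoint)

    # ---- estimation ---------------------------------------------------
    def ssr(self, params) -> float:
        """Objective value at given alphas (sum of squared delta residuals)."""
        return fitting.ssr_objective(params, self.data, self.endpoint)

    def fit(self, method: str = "lbfgsb", config: Optional[FitConfig] = None) -> "AdaptiveResponseResults":
        if method == "lbfgsb":
            res = fitting.fit_lbfgsb(self.data, self.endpoint, config)
        elif method == "sga":
            res = fitting.fit_sga(self.data, self.endpoint, config)
        else:
            raise ValueError(f"method must be 'lbfgsb' or 'sga', got {method!r}")
        return AdaptiveResponseResults(self, res)


class AdaptiveResponseResults:
    """Fit results: estimated alphas, diagnostics and prediction helpers."""

    def __init__(self, model: AdaptiveResponseModel, fit_result: FitResult):
        self.model = model
        self._fit = fit_result

    # delegated essentials
    @property
    def params(self) -> AdaptiveResponseParams:
        return self._fit.params

    @property
    def ssr(self) -> float:
        return self._fit.ssr

    @property
    def fitness(self) -> float:
        return self._fit.fitness

    @property
    def method(self) -> str:
        return self._fit.method

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    def uncertainty(self, config: Optional[FitConfig] = None) -> dict:
        """Poisson worst-case (lower, upper) offsets per parameter (cached)."""
        if getattr(self, "_uncertainty", None) is None:
            self._uncertainty = fitting.poisson_worstcase_uncertainty(
                self.model.data, self._fit, self.model.endpoint, config
            )
        return self._uncertainty

    def predict(
        self,
        d1,
        d2,
        dt,
        T: Optional[float] = None,
    ) -> np.ndarray:
        """Model delta at the fitted alphas for new dose schemes (vectorised)."""
        d1, d2, dt = np.broadcast_arrays(
            np.atleast_1d(np.asarray(d1, float)),
            np.asarray(d2, float),
            np.asarray(dt, float),
        )
        if self.model.endpoint == "lesions":
            if T is None:
                raise ValueError("the lesions endpoint needs an observation time T")
            out = [
                delta_lesions(self.params, a, b, c, T).delta for a, b, c in zip(d1, d2, dt)
            ]
        else:
            out = [delta_mutations(self.params, a, b, c).delta for a, b, c in zip(d1, d2, dt)]
        return np.array(out)

    def fittedvalues(self) -> np.ndarray:
        """Model delta at the fitted alphas for the training records."""
        df = self.model.data
        T = df["t_h"].to_numpy(float) if self.model.endpoint == "lesions" else None
        if self.model.endpoint == "lesions":
            return np.array(
                [
                    delta_lesions(self.params, r.d1_gy, r.d2_gy, r.dt_h, r.t_h).delta
                    for r in df.itertuples()
                ]
            )
        return np.array(
            [
                delta_mutations(self.params, r.d1_gy, r.d2_gy, r.dt_h).delta
                for r in df.itertuples()
            ]
        )

    def resid(self) -> np.ndarray:
        return self.model.data["delta"].to_numpy(float) - self.fittedvalues()

    def summary(self) -> str:
        p = self.params
        unc = getattr(self, "_uncertainty", None)
        lines = [
            "Adaptive-response model fit",
            "=" * 46,
            f"endpoint:   {self.model.endpoint}",
            f"records:    {self._fit.n_records}  (source: {self.model.source})",
            f"method:     {self._fit.method}",
            f"SSR:        {self.ssr:.6g}",
            f"restarts:   {self._fit.restarts_kept} kept / "
            f"{self._fit.restarts_discarded} discarded",
            "-" * 46,
        ]
        units = {"alpha0": "Gy^-2 h^-3", "alpha1": "Gy^-1", "alpha2": "h^-1"}
        for name, value in zip(units, p.as_array()):
            row = f"{name:8s} {value:12.5g}  [{units[name]}]"
            if unc:
                lo, hi = unc[name]
                row += f"  ({lo:+.3g} / {hi:+.3g})"
            lines.append(row)
        lines.append("-" * 46)
        lines.append(
            f"response maximal at D = {p.dose_at_max:.4g} Gy, t = {p.time_at_max:.4g} h"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.params
        return (
            f"<AdaptiveResponseResults {self.method} alphas=({p.alpha0:.4g}, "
            f"{p.alpha1:.4g}, {p.alpha2:.4g}) ssr={self.ssr:.4g}>"
        )
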