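"""Bell-model fits of rupture force against loading rate.

The Bell model predicts a logarithmic dependence of the rupture force on
the loading rate r = k·v:

    F_r = (k_B·T / x_b) · ln( k·v·x_b / (k_B·T·k_off) ) = A · ln(k·v / B)

with x_b the distance to the transition state and k_off the zero-force
rupture rate.  A and B are fitted by unweighted least squares of the
individual rupture records against ln(k·v); then x_b = k_B·T/A and
k_off = B/A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt_pn_nm
from .forces import RuptureRecord

__all__ = ["BellFit", "ExtrapolationWarning", "fit_bell", "slope_per_decade",
           "extrapolate_k0"]


class ExtrapolationWarning(UserWarning):
    """The requested quantity extrapolates the fit far outside the data."""


@dataclass
class BellFit:
    """Fitted Bell-model parameters over a pulling-velocity ladder."""

    A: float  # pN
    B: float  # pN/ns
    x_b: float  # nm
    k_off: float  # 1/ns
    kT: float  # pN·nm
    k_spring: float  # pN/nm
    velocities: np.ndarray  # nm/ns, distinct values fitted over
    residuals: np.ndarray  # pN, per record
    flagged: bool = False  # non-positive A: anti-Bell trend

    def predict(self, v: float | np.ndarray) -> np.ndarray:
        """Predicted rupture force at pulling velocity v (nm/ns)."""
        return self.A * np.log(self.k_spring * np.asarray(v, dtype=float) / self.B)


def fit_bell(
    records: Sequence[RuptureRecord],
    k_spring: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BellFit:
    """Unweighted least-squares Bell fit over individual rupture records.

    Requires at least two distinct pulling velocities.  A non-positive
    fitted slope A (forces decreasing with loading rate) yields a flagged
    fit with B, x_b, k_off undefined (NaN).
    """
    if k_spring <= 0:
        raise ValueError("k_spring must be positive")
    f_r = np.array([r.f_r for r in records], dtype=float)
    v = np.array([r.v_pull for r in records], dtype=float)
    if len(records) < 2 or len(np.unique(v)) < 2:
        raise ValueError("Bell fit needs records at >= 2 distinct velocities")
    x = np.log(k_spring * v)
    slope, intercept = np.polyfit(x, f_r, 1)
    kT = kt_pn_nm(temperature)
    residuals = f_r - (slope * x + intercept)
    if slope <= 0:
        warnings.warn("non-positive Bell slope (anti-Bell trend); fit flagged",
                      stacklevel=2)
        return BellFit(A=float(slope), B=float("nan"), x_b=float("nan"),
                       k_off=float("nan"), kT=kT, k_spring=k_spring,
                       velocities=np.unique(v), residuals=residuals, flagged=True)
    A = float(slope)
    B = float(np.exp(-intercept / A))
    return BellFit(A=A, B=B, x_b=kT / A, k_off=B / A, kT=kT, k_spring=k_spring,
                   velocities=np.unique(v), residuals=residuals)


def slope_per_decade(fit: BellFit) -> float:
    """Rupture-force increase per order of magnitude in velocity: A·ln 10 pN."""
    return fit.A * float(np.log(10.0))


def extrapolate_k0(fit: BellFit) -> float:
    """Zero-force rupture rate k_off (1/ns) under the fitted Bell model.

    This extrapolates the log-linear trend across many orders of magnitude
    below the sampled loading rates; a warning is always emitted.
    """
    if fit.flagged:
        raise ValueError("cannot extrapolate a flagged (anti-Bell) fit")
    warnings.warn(
        "zero-force rate extrapolates the Bell fit far below the sampled "
        "loading rates; treat as an order-of-magnitude estimate",
        ExtrapolationWarning, stacklevel=2)
    return fit.k_off
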