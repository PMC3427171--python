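"""Pseudo-first-order kinetics of protein trans-splicing (PTS).

With the short intein fragment in excess over its complement, ligated-product
formation follows A(t) = A₀(1 − e^(−kt)): k is the apparent PTS rate constant
and A₀ the plateau yield (band densitometry, so a unitless fraction that may
slightly exceed 1).  Replicate time courses are fit globally — one shared
(k, A₀) across all replicates, every point weighted equally — and the
half-life t½ = ln2/k is reported in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PTSTimecourse",
    "FirstOrderFit",
    "first_order_model",
    "fit_first_order",
    "half_life",
    "yield_at",
]

A0_MAX = 1.05  # densitometry tolerance above a nominal fraction of 1


@dataclass
class PTSTimecourse:
    """One replicate: times (s) and ligated-product fractions."""

    replicate: str
    time_s: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.time_s.shape != self.fraction.shape:
            raise ValueError("time and fraction arrays differ in length")
        if np.any(self.time_s < 0) or np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if np.any(self.fraction < 0) or np.any(self.fraction > A0_MAX):
            raise ValueError(f"fractions must lie in [0, {A0_MAX}]")


@dataclass
class FirstOrderFit:
    k_per_s: float
    k_se: float
    a0: float
    a0_se: float
    t_half_min: float
    rss: float
    n_points: int
    n_replicates: int


def first_order_model(t: np.ndarray, k: float, a0: float) -> np.ndarray:
    return a0 * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def fit_first_order(
    timecourses: Sequence[PTSTimecourse],
    loss: str = "linear",
) -> FirstOrderFit:
    """Global nonlinear least-squares fit of shared (k, A₀) to all replicates.

    Initial guesses: A₀ from the maximum observed fraction; k from the
    earliest nonzero point via k ≈ −ln(1 − A/A₀)/t.  ``loss='soft_l1'``
    selects a robust loss for outlier-prone densitometry.
    """
    if not timecourses:
        raise ValueError("no time courses supplied")
    t = np.concatenate([tc.time_s for tc in timecourses])
    a = np.concatenate([tc.fraction for tc in timecourses])
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points pooled")
    if np.all(a <= 0):
        raise ValueError("all-zero signal: nothing to fit")

    a0_init = min(max(float(a.max()), 1e-3), A0_MAX)
    pos = (t > 0) & (a > 0) & (a < a0_init)
    if pos.any():
        i = int(np.argmin(t[pos]))
        k_init = -np.log(1.0 - a[pos][i] / a0_init) / t[pos][i]
    else:
        k_init = 1.0 / max(float(t.max()), 1.0)
    k_init = float(np.clip(k_init, 1e-8, 1e2))

    try:
        popt, pcov = curve_fit(
            first_order_model,
            t,
            a,
            p0=[k_init, a0_init],
            bounds=([1e-10, 1e-6], [np.inf, A0_MAX]),
            loss=loss,
            method="trf",
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"first-order fit did not converge (k_init={k_init:.3g}, "
            f"a0_init={a0_init:.3g}): {exc}"
        ) from exc
    k, a0 = popt
    se = np.sqrt(np.diag(pcov))
    resid = a - first_order_model(t, k, a0)
    return FirstOrderFit(
        k_per_s=float(k),
        k_se=float(se[0]),
        a0=float(a0),
        a0_se=float(se[1]),
        t_half_min=half_life(float(k)),
        rss=float(resid @ resid),
        n_points=len(t),
        n_replicates=len(timecourses),
    )


def half_life(k_per_s: float) -> float:
    """First-order half-life ln2/k, in minutes."""
    if k_per_s <= 0:
        raise ValueError(f"rate constant must be positive, got {k_per_s}")
    return float(np.log(2.0) / k_per_s / 60.0)


def yield_at(fit: FirstOrderFit, t_s: float) -> float:
    """Predicted ligated fraction at time t (s)."""
    if t_s < 0:
        raise ValueError("time must be non-negative")
    return float(first_order_model(np.asarray(t_s), fit.k_per_s, fit.a0))
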