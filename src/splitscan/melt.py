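"""Two-state van't Hoff analysis of CD thermal-denaturation curves.

A melt monitored by ellipticity at a single wavelength (224 nm here) is
reduced to the folded fraction f(T) by linear pre- and post-transition
baselines, converted to the two-state unfolding equilibrium constant
K = [D]/[F] = (1-f)/f, and fit by ordinary least squares to

    ln K = -ΔH/(R T) + ΔS/R

so the slope gives -ΔH/R and the intercept ΔS/R, with ΔH and ΔS the
(positive) unfolding enthalpy and entropy.  Writing K for the folding
direction instead merely flips both signs (ln K is antisymmetric under
f -> 1-f).  ΔH is reported in
kcal mol⁻¹ and ΔS in cal mol⁻¹ K⁻¹ (R = 1.987 cal mol⁻¹ K⁻¹), with the
derived quantities TΔS and ΔG = ΔH − TΔS at a reference temperature
(298 K default) and the midpoint temperature T_M both as the f = 0.5
crossing of the curve and as ΔH/ΔS.

The model assumes a temperature-independent ΔH over the transition (no ΔCp
term) and exactly two populated states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_CAL",
    "MeltCurve",
    "FractionFolded",
    "TwoStateFit",
    "fraction_folded",
    "vant_hoff_fit",
    "tm_from_curve",
    "derive_thermo",
    "compare_variants",
]

R_CAL = 1.987  # gas constant, cal mol-1 K-1
C_TO_K = 273.15
DEFAULT_T_REF = 298.0
DEFAULT_F_BOUNDS = (0.05, 0.95)
AUTO_BASELINE_FRACTION = 0.15


@dataclass
class MeltCurve:
    """An ellipticity-vs-temperature trace (single wavelength)."""

    temp_c: np.ndarray
    theta: np.ndarray  # millidegrees
    wavelength_nm: float = 224.0
    construct: Optional[str] = None

    def __post_init__(self) -> None:
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.temp_c.shape != self.theta.shape:
            raise ValueError("temperature and ellipticity arrays differ in length")
        if len(self.temp_c) < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temp_c) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class FractionFolded:
    """Folded-fraction trace derived from a melt curve."""

    temp_k: np.ndarray
    f: np.ndarray
    n_clipped: int
    folded_baseline: tuple[float, float]  # (intercept mdeg, slope mdeg/degC)
    denatured_baseline: tuple[float, float]


@dataclass
class TwoStateFit:
    """van't Hoff two-state parameters and derived thermodynamics."""

    dh_kcal: float
    dh_se_kcal: float
    ds_cal: float
    ds_se_cal: float
    t_ref_k: float
    tds_kcal: float  # T_ref * dS
    dg_kcal: float  # dH - T_ref * dS
    tm_vant_hoff_c: Optional[float]  # dH/dS - 273.15
    tm_curve_c: Optional[float] = None  # f = 0.5 crossing
    n_points: int = 0
    f_bounds: tuple[float, float] = DEFAULT_F_BOUNDS
    r_squared: float = np.nan
    construct: Optional[str] = None
    #: folded-fraction trace under the final (refined) baselines
    fraction: Optional[FractionFolded] = None

    @property
    def tm_c(self) -> Optional[float]:
        """Preferred midpoint: the curve crossing when available."""
        return self.tm_curve_c if self.tm_curve_c is not None else self.tm_vant_hoff_c


def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(t) < 2:
        raise ValueError("baseline window contains fewer than 2 points")
    slope, intercept = np.polyfit(t, y, 1)
    return float(intercept), float(slope)


def _auto_windows(temp_c: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    lo, hi = temp_c[0], temp_c[-1]
    span = hi - lo
    w = AUTO_BASELINE_FRACTION * span
    return (lo, lo + w), (hi - w, hi)


def fraction_folded(
    curve: MeltCurve,
    baselines: Union[
        str, tuple[tuple[float, float], tuple[float, float]]
    ] = "auto",
) -> FractionFolded:
    """Convert ellipticity to folded fraction via linear baselines.

    ``baselines`` is either 'auto' (outer 15% of the temperature range on
    each side) or ((t1, t2), (t3, t4)) windows in °C for the folded and
    denatured states.  f = (θ − θ_D) / (θ_F − θ_D) evaluated per point and
    clipped to [0, 1]; the number of clipped points is reported.
    """
    t, y = curve.temp_c, curve.theta
    if baselines == "auto":
        (f1, f2), (d1, d2) = _auto_windows(t)
    else:
        (f1, f2), (d1, d2) = baselines
    fold_mask = (t >= f1) & (t <= f2)
    den_mask = (t >= d1) & (t <= d2)
    bf = _fit_line(t[fold_mask], y[fold_mask])
    bd = _fit_line(t[den_mask], y[den_mask])

    theta_f = bf[0] + bf[1] * t
    theta_d = bd[0] + bd[1] * t
    sep = np.abs(theta_f - theta_d)
    if np.median(sep) < 0.05 * (np.max(np.abs(y)) + 1e-12) or np.all(sep < 1e-9):
        raise ValueError(
            "degenerate baselines: folded and denatured states are not "
            "spectroscopically separated (no transition in range?)"
        )
    # a baseline window that overlaps the transition shows up as the fitted
    # baselines crossing inside the scanned range
    if np.any(np.sign(theta_f - theta_d) != np.sign(theta_f[0] - theta_d[0])):
        warnings.warn(
            "baselines cross inside the temperature range; baseline windows "
            "may overlap the transition",
            stacklevel=2,
        )
    f = (y - theta_d) / (theta_f - theta_d)
    n_clipped = int(np.sum((f < 0) | (f > 1)))
    return FractionFolded(
        temp_k=t + C_TO_K,
        f=np.clip(f, 0.0, 1.0),
        n_clipped=n_clipped,
        folded_baseline=bf,
        denatured_baseline=bd,
    )


def derive_thermo(dh_kcal: float, ds_cal: float, t_ref_k: float = DEFAULT_T_REF):
    """Derived quantities from (ΔH, ΔS): TΔS and ΔG at t_ref (kcal mol⁻¹) and
    the van't Hoff midpoint ΔH/ΔS in °C (None when ΔS = 0)."""
    tds = t_ref_k * ds_cal / 1000.0
    dg = dh_kcal - tds
    tm = dh_kcal * 1000.0 / ds_cal - C_TO_K if ds_cal != 0 else None
    return tds, dg, tm


def vant_hoff_fit(
    ff: FractionFolded,
    f_bounds: tuple[float, float] = DEFAULT_F_BOUNDS,
    t_ref_k: float = DEFAULT_T_REF,
    construct: Optional[str] = None,
) -> TwoStateFit:
    """OLS regression of ln K on 1/T over the transition window.

    Points with f outside ``f_bounds`` are excluded to keep ln K finite and
    the regression well conditioned; at least 5 points must remain.
    """
    lo, hi = f_bounds
    mask = (ff.f > lo) & (ff.f < hi)
    if int(mask.sum()) < 5:
        raise ValueError(
            f"only {int(mask.sum())} points with f in ({lo}, {hi}); need >= 5"
        )
    f = ff.f[mask]
    t = ff.temp_k[mask]
    ln_k = np.log((1.0 - f) / f)  # unfolding constant [D]/[F]
    x = 1.0 / t
    res = stats.linregress(x, ln_k)
    dh_kcal = -res.slope * R_CAL / 1000.0
    ds_cal = res.intercept * R_CAL
    dh_se = res.stderr * R_CAL / 1000.0
    ds_se = res.intercept_stderr * R_CAL
    tds, dg, tm_vh = derive_thermo(dh_kcal, ds_cal, t_ref_k)
    return TwoStateFit(
        dh_kcal=dh_kcal,
        dh_se_kcal=dh_se,
        ds_cal=ds_cal,
        ds_se_cal=ds_se,
        t_ref_k=t_ref_k,
        tds_kcal=tds,
        dg_kcal=dg,
        tm_vant_hoff_c=tm_vh,
        tm_curve_c=tm_from_curve(ff),
        n_points=int(mask.sum()),
        f_bounds=f_bounds,
        r_squared=float(res.rvalue**2),
        construct=construct,
        fraction=ff,
    )


def tm_from_curve(ff: FractionFolded) -> Optional[float]:
    """Midpoint temperature (°C) from the f = 0.5 crossing, by linear
    interpolation; None (with a warning) when f never crosses 0.5 — the
    melt-beyond-range case reported as a lower bound."""
    f, t = ff.f, ff.temp_k
    crossings = []
    for i in range(len(f) - 1):
        a, b = f[i] - 0.5, f[i + 1] - 0.5
        if a == 0:
            crossings.append(t[i])
        elif a * b < 0:
            crossings.append(t[i] + (t[i + 1] - t[i]) * a / (a - b))
    if f[-1] == 0.5:
        crossings.append(t[-1])
    if not crossings:
        warnings.warn("folded fraction never crosses 0.5 in the scanned range",
                      stacklevel=2)
        return None
    if len(crossings) == 1:
        return float(crossings[0] - C_TO_K)
    # multiple crossings (noise): take the one nearest the steepest descent
    mid = t[int(np.argmax(-np.gradient(f)))]
    return float(min(crossings, key=lambda c: abs(c - mid)) - C_TO_K)


def fit_melt(
    curve: MeltCurve,
    baselines="auto",
    f_bounds: tuple[float, float] = DEFAULT_F_BOUNDS,
    t_ref_k: float = DEFAULT_T_REF,
    refine_baselines: bool = True,
    polish: bool = True,
    max_iter: int = 10,
) -> TwoStateFit:
    """Full pipeline: baselines → fraction folded → van't Hoff fit.

    With ``refine_baselines`` (default), the baseline fit is iterated
    self-consistently: the current (ΔH, ΔS) estimate predicts the residual
    minority-state population at each baseline-window point, its ellipticity
    contribution is subtracted before the pure-state lines are refit, and the
    regression is repeated until ΔH converges.  This removes the bias from
    transition tails leaking into fixed baseline windows (on noiseless
    two-state data the refined fit converges to the generating parameters).

    With ``polish`` (default), the van't Hoff estimate then seeds a direct
    nonlinear least-squares fit of θ(T) over all points with (ΔH, ΔS) and
    both baselines free.  For Gaussian noise on the ellipticity this is the
    maximum-likelihood estimator; the ln K regression weights noise near the
    fraction bounds very unevenly and is kept as the initializer (the two
    coincide on noiseless data).
    """
    t = curve.temp_c
    windows = _auto_windows(t) if baselines == "auto" else baselines
    ff = fraction_folded(curve, baselines=windows)
    fit = vant_hoff_fit(ff, f_bounds=f_bounds, t_ref_k=t_ref_k,
                        construct=curve.construct)
    if not refine_baselines:
        return fit
    y = curve.theta
    (f1, f2), (d1, d2) = windows
    fold_mask = (t >= f1) & (t <= f2)
    den_mask = (t >= d1) & (t <= d2)
    bf, bd = ff.folded_baseline, ff.denatured_baseline
    t_k = t + C_TO_K
    for _ in range(max_iter):
        ln_k = -fit.dh_kcal * 1000.0 / (R_CAL * t_k) + fit.ds_cal / R_CAL
        f_model = 1.0 / (1.0 + np.exp(ln_k))
        theta_f_line = bf[0] + bf[1] * t
        theta_d_line = bd[0] + bd[1] * t
        # subtract the predicted minority-state contribution, then refit
        fm = f_model[fold_mask]
        pure_f = (y[fold_mask] - (1.0 - fm) * theta_d_line[fold_mask]) / np.maximum(fm, 1e-6)
        bf = _fit_line(t[fold_mask], pure_f)
        dm = f_model[den_mask]
        pure_d = (y[den_mask] - dm * theta_f_line[den_mask]) / np.maximum(1.0 - dm, 1e-6)
        bd = _fit_line(t[den_mask], pure_d)
        theta_f = bf[0] + bf[1] * t
        theta_d = bd[0] + bd[1] * t
        f_new = np.clip((y - theta_d) / (theta_f - theta_d), 0.0, 1.0)
        ff = FractionFolded(
            temp_k=t_k, f=f_new,
            n_clipped=int(np.sum((f_new <= 0) | (f_new >= 1))),
            folded_baseline=bf, denatured_baseline=bd,
        )
        new_fit = vant_hoff_fit(ff, f_bounds=f_bounds, t_ref_k=t_ref_k,
                                construct=curve.construct)
        if abs(new_fit.dh_kcal - fit.dh_kcal) < 1e-9 * max(abs(fit.dh_kcal), 1.0):
            fit = new_fit
            break
        fit = new_fit
    if polish:
        fit = _polish_fit(curve, fit, bf, bd, f_bounds, t_ref_k)
    return fit


def _polish_fit(
    curve: MeltCurve,
    fit: TwoStateFit,
    bf: tuple[float, float],
    bd: tuple[float, float],
    f_bounds: tuple[float, float],
    t_ref_k: float,
) -> TwoStateFit:
    """Direct NLLS of the full ellipticity model, seeded by the van't Hoff
    estimate; falls back to the seed if the optimizer fails."""
    from scipy.optimize import least_squares

    t = curve.temp_c
    t_k = t + C_TO_K
    y = curve.theta

    def resid(p):
        dh, ds, a0, a1, b0, b1 = p
        ln_k = -dh * 1000.0 / (R_CAL * t_k) + ds / R_CAL
        f = 1.0 / (1.0 + np.exp(ln_k))
        return (a0 + a1 * t) * f + (b0 + b1 * t) * (1.0 - f) - y

    p0 = [fit.dh_kcal, fit.ds_cal, bf[0], bf[1], bd[0], bd[1]]
    try:
        res = least_squares(resid, p0, method="lm", max_nfev=20000)
    except Exception:  # pragma: no cover
        return fit
    if not res.success or res.x[0] <= 0 or res.x[1] <= 0:
        return fit
    dh, ds = float(res.x[0]), float(res.x[1])
    dof = max(len(y) - 6, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        dh_se, ds_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:  # pragma: no cover
        dh_se, ds_se = fit.dh_se_kcal, fit.ds_se_cal
    tds, dg, tm_vh = derive_thermo(dh, ds, t_ref_k)
    theta_f = res.x[2] + res.x[3] * t
    theta_d = res.x[4] + res.x[5] * t
    f_final = np.clip((y - theta_d) / (theta_f - theta_d), 0.0, 1.0)
    ff = FractionFolded(
        temp_k=t_k, f=f_final,
        n_clipped=int(np.sum((f_final <= 0) | (f_final >= 1))),
        folded_baseline=(float(res.x[2]), float(res.x[3])),
        denatured_baseline=(float(res.x[4]), float(res.x[5])),
    )
    ss_res = float(2.0 * res.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return TwoStateFit(
        dh_kcal=dh, dh_se_kcal=dh_se, ds_cal=ds, ds_se_cal=ds_se,
        t_ref_k=t_ref_k, tds_kcal=tds, dg_kcal=dg, tm_vant_hoff_c=tm_vh,
        tm_curve_c=tm_from_curve(ff), n_points=len(y), f_bounds=f_bounds,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        construct=fit.construct,
        fraction=ff,
    )


def compare_variants(fits: Sequence[TwoStateFit]) -> pd.DataFrame:
    """Stability comparison table, most stable first (by T_M, then ΔG).

    Flags single-chain/two-piece pairs sharing a split site (constructs named
    like CP36/SP36) so the stability cost of the extra backbone opening is
    read off directly.  Fits without a measurable T_M (melt beyond range)
    sort above everything, mirroring '>T_max' reporting.
    """
    if len(fits) < 2:
        if not fits:
            raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        name = f.construct or "?"
        rows.append(
            {
                "construct": name,
                "tm_c": f.tm_c,
                "dh_kcal": f.dh_kcal,
                "ds_cal": f.ds_cal,
                "tds_kcal": f.tds_kcal,
                "dg_kcal": f.dg_kcal,
            }
        )
    df = pd.DataFrame(rows)
    order = df["tm_c"].fillna(np.inf)
    df = (
        df.assign(_o=order)
        .sort_values(["_o", "dg_kcal"], ascending=False)
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    sites = df["construct"].str.extract(r"^(?:CP|SP)(\d+)$", expand=False)
    df["paired_site"] = [
        s if s is not None and (sites == s).sum() > 1 else None for s in sites
    ]
    return df
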