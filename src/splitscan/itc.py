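"""Single-site binding analysis of isothermal titration calorimetry data.

The association of two split-protein fragments is measured by titrating one
fragment (syringe) into the other (cell) and integrating the heat of each
injection.  The standard single-site total-heat model is fit for the
stoichiometry n, association constant K_a, binding enthalpy ΔH, and a
constant per-injection dilution-heat offset:

    [MX] = ½[(n·M + X + K_d) − sqrt((n·M + X + K_d)² − 4·n·M·X)]
    Q_i  = V₀ · ΔH · [MX]_i
    q_i  = Q_i − Q_{i−1} + (dV_i/V₀)·(Q_i + Q_{i−1})/2 + offset

where M and X are the cell-macromolecule and titrant concentrations after
injection i, corrected for volume displacement (each injection pushes an
equal volume out of the overfilled cell, so M_i = M₀·e^(−V_i/V₀) and
X_i = X₀·(1 − e^(−V_i/V₀)) with V_i the cumulative injected volume).  Derived
quantities: K_d = 1/K_a, ΔG = RT·ln K_d and TΔS = ΔH − ΔG, so the closure
ΔG = ΔH − TΔS holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ITCIsotherm",
    "BindingFit",
    "injection_heats",
    "fit_single_site",
    "affinity_fold_ratio",
    "cross_pairing_report",
]

R_KCAL = 1.987e-3  # kcal mol-1 K-1
C_VALUE_RANGE = (1.0, 1e4)


@dataclass
class ITCIsotherm:
    """An injection-heat series with the cell/syringe bookkeeping needed to
    model it.  Concentrations in µM, volumes in mL (cell) / µL (injections),
    heats in µcal."""

    cell_volume_ml: float
    cell_conc_um: float
    syringe_conc_um: float
    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_ul.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats differ in length")
        if np.any(self.injection_volumes_ul <= 0):
            raise ValueError("injection volumes must be positive")
        if self.cell_volume_ml <= 0 or self.cell_conc_um <= 0 or self.syringe_conc_um <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.heats_ucal) < 10:
            raise ValueError("need at least 10 injections for fitting")


@dataclass
class BindingFit:
    n: float
    kd_molar: float
    kd_se_molar: float
    dh_kcal: float
    dh_se_kcal: float
    offset_ucal: float
    temperature_k: float
    dg_kcal: float  # RT ln Kd (negative for binding)
    tds_kcal: float  # dH - dG
    rss: float = np.nan
    c_value: float = np.nan


def _concentrations(iso: ITCIsotherm) -> tuple[np.ndarray, np.ndarray]:
    """Cell-species and titrant molar concentrations after each injection,
    under continuous-displacement dilution."""
    v0 = iso.cell_volume_ml * 1e-3  # L
    v_cum = np.cumsum(iso.injection_volumes_ul) * 1e-6  # L
    dil = np.exp(-v_cum / v0)
    m = iso.cell_conc_um * 1e-6 * dil
    x = iso.syringe_conc_um * 1e-6 * (1.0 - dil)
    return m, x


def injection_heats(
    iso: ITCIsotherm,
    n: float,
    kd_molar: float,
    dh_kcal: float,
    offset_ucal: float = 0.0,
) -> np.ndarray:
    """Model per-injection heats (µcal) for given single-site parameters."""
    v0 = iso.cell_volume_ml * 1e-3
    m, x = _concentrations(iso)
    b = n * m + x + kd_molar
    complex_conc = 0.5 * (b - np.sqrt(b * b - 4.0 * n * m * x))
    q = v0 * dh_kcal * 1e3 * complex_conc * 1e6  # ucal (dh kcal->cal, then *1e6)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = iso.injection_volumes_ul * 1e-6
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + offset_ucal


def fit_single_site(
    iso: ITCIsotherm,
    skip_first: bool = True,
    t_ref_k: Optional[float] = None,
) -> BindingFit:
    """Nonlinear least-squares fit of (n, K_d, ΔH, offset) to injection heats.

    The first injection is excluded by default (diffusion across the syringe
    tip during equilibration corrupts it in practice).  K_d is fit in log
    space to stay positive.  A c-value (n·K_a·[cell]) outside [1, 10⁴] raises
    a warning: the affinity is then poorly constrained by the isotherm shape.
    """
    heats = iso.heats_ucal
    mask = np.ones(len(heats), dtype=bool)
    if skip_first:
        mask[0] = False
    if np.allclose(heats[mask], heats[mask][-1], atol=1e-12) and np.allclose(
        heats[mask], 0.0, atol=1e-9
    ):
        raise RuntimeError("all-zero heats: no binding signal to fit")

    v0 = iso.cell_volume_ml * 1e-3
    m0 = iso.cell_conc_um * 1e-6
    # initial guesses: offset from the saturated tail, dH from the initial
    # plateau of the Wiseman curve, Kd from a mid-range c-value
    offset0 = float(np.mean(heats[mask][-3:]))
    x_step = iso.syringe_conc_um * 1e-6 * iso.injection_volumes_ul * 1e-6 / v0
    with np.errstate(divide="ignore", invalid="ignore"):
        dh_per_mol = (heats - offset0) / (x_step * v0 * 1e6)  # cal/mol
    dh0 = float(np.nanmedian(dh_per_mol[mask][:3]) / 1e3)  # kcal/mol
    if not np.isfinite(dh0) or dh0 == 0:
        dh0 = -10.0
    kd0 = m0 / 50.0

    def residuals(p):
        n, log_kd, dh, off = p
        return injection_heats(iso, n, np.exp(log_kd), dh, off)[mask] - heats[mask]

    res = least_squares(
        residuals,
        x0=[1.0, np.log(kd0), dh0, offset0],
        bounds=([1e-3, np.log(1e-15), -1e4, -np.inf], [1e2, np.log(1.0), 1e4, np.inf]),
        method="trf",
        max_nfev=20000,
    )
    if not res.success:
        raise RuntimeError(f"single-site fit did not converge: {res.message}")
    n_fit, log_kd, dh_fit, off_fit = res.x
    kd = float(np.exp(log_kd))

    # standard errors from the Jacobian (delta method for Kd)
    dof = max(int(mask.sum()) - 4, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        kd_se = float(np.sqrt(cov[1, 1]) * kd)
        dh_se = float(np.sqrt(cov[2, 2]))
    except np.linalg.LinAlgError:  # pragma: no cover
        kd_se = dh_se = np.nan

    temp = t_ref_k if t_ref_k is not None else iso.temperature_k
    c_value = n_fit * (1.0 / kd) * m0
    if not (C_VALUE_RANGE[0] <= c_value <= C_VALUE_RANGE[1]):
        warnings.warn(
            f"c-value {c_value:.3g} outside {C_VALUE_RANGE}: affinity is "
            "poorly determined by the isotherm shape",
            stacklevel=2,
        )
    dg = R_KCAL * temp * np.log(kd)
    return BindingFit(
        n=float(n_fit),
        kd_molar=kd,
        kd_se_molar=kd_se,
        dh_kcal=float(dh_fit),
        dh_se_kcal=dh_se,
        offset_ucal=float(off_fit),
        temperature_k=float(temp),
        dg_kcal=float(dg),
        tds_kcal=float(dh_fit - dg),
        rss=float(2.0 * res.cost),
        c_value=float(c_value),
    )


def affinity_fold_ratio(a: BindingFit, b: BindingFit) -> tuple[float, str]:
    """Fold difference in affinity, >= 1, with a flag naming the weaker
    binder ('a', 'b', or 'equal')."""
    if a.kd_molar <= 0 or b.kd_molar <= 0:
        raise ValueError("dissociation constants must be positive")
    if a.kd_molar == b.kd_molar:
        return 1.0, "equal"
    weaker = "a" if a.kd_molar > b.kd_molar else "b"
    ratio = max(a.kd_molar, b.kd_molar) / min(a.kd_molar, b.kd_molar)
    return float(ratio), weaker


def cross_pairing_report(
    fits: Mapping[str, Optional[BindingFit]],
) -> pd.DataFrame:
    """Comparison table over fragment pairings, strongest binder first;
    pairings with no detectable binding (None) rank weakest."""
    if len(fits) < 2:
        raise ValueError("need at least 2 pairings to compare")
    rows = []
    for name, fit in fits.items():
        if fit is None:
            rows.append(
                {"pairing": name, "kd_molar": np.nan, "dh_kcal": np.nan,
                 "dg_kcal": np.nan, "tds_kcal": np.nan, "binding": False}
            )
        else:
            rows.append(
                {"pairing": name, "kd_molar": fit.kd_molar, "dh_kcal": fit.dh_kcal,
                 "dg_kcal": fit.dg_kcal, "tds_kcal": fit.tds_kcal, "binding": True}
            )
    df = pd.DataFrame(rows)
    df = df.sort_values("kd_molar", na_position="last").reset_index(drop=True)
    return df
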