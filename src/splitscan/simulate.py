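"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one experimental input — CP-viability score profiles,
CD melt curves, backbone shift-table pairs, PTS time courses, ITC isotherms —
from the forward model its paired analysis module inverts, so parameter
recovery on noiseless output is an exact round trip and seeded noisy output
supports calibration studies.  All randomness flows through
``numpy.random.default_rng(seed)``: a fixed seed reproduces the data
byte-identically.

Noise models are independent Gaussian per observation; default magnitudes
are instrument-plausible (CD: ~1–2% of the ellipticity range; densitometry:
2–3% absolute on a fraction; ITC: ~1% of the largest injection heat; shifts:
assignment-precision scatter well below a real perturbation).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import CpResidueMap, cp_residue_map
from .itc import ITCIsotherm, injection_heats
from .melt import C_TO_K, MeltCurve, R_CAL
from .pts import PTSTimecourse, first_order_model
from .shifts import load_random_coil
from .sites import Residue, ScoreProfile

__all__ = [
    "AMINO_ACIDS",
    "random_sequence",
    "gen_score_profile",
    "gen_melt_curve",
    "gen_shift_pair",
    "gen_pts_timecourse",
    "gen_itc_isotherm",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(n: int, seed: int = 0) -> str:
    """Deterministic synthetic amino-acid sequence (uniform over 20 residues).

    Used as a stand-in parent chain where a real sequence is not available;
    all sequence-design operations are sequence-agnostic.
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def gen_score_profile(
    n: int,
    peaks: Sequence[tuple[int, float, float]],
    baseline: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    protein_id: str = "synthetic",
    gaps: Sequence[int] = (),
) -> ScoreProfile:
    """Smooth Gaussian-bump CP-score profile with planted peaks.

    ``peaks`` is a list of (site, height-above-baseline, width-in-residues);
    peak sites are the ground truth that site selection should recover.
    ``gaps`` lists residue indices to emit with no score (missing
    coordinates).  Scores are clipped to [0, 1] after noise.
    """
    for site, height, _ in peaks:
        if not (1 <= site <= n):
            raise ValueError(f"peak site {site} outside 1..{n}")
        if baseline + height > 1.0 + 1e-9:
            raise ValueError(f"peak at {site}: baseline+height exceeds 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(1, n + 1)
    score = np.full(n, float(baseline))
    for site, height, width in peaks:
        score += height * np.exp(-0.5 * ((idx - site) / width) ** 2)
    if noise_sd > 0:
        score += rng.normal(0.0, noise_sd, size=n)
    score = np.clip(score, 0.0, 1.0)
    seq = random_sequence(n, seed=seed)
    gapset = set(gaps)
    residues = [
        Residue(index=int(i), aa=seq[i - 1], score=None if i in gapset else float(score[i - 1]))
        for i in idx
    ]
    return ScoreProfile(protein_id=protein_id, residues=residues)


def gen_melt_curve(
    dh_kcal: float,
    ds_cal: float,
    folded_baseline: tuple[float, float] = (-20.0, 0.0),
    denatured_baseline: tuple[float, float] = (-4.0, 0.0),
    t_range_c: tuple[float, float] = (25.0, 95.0),
    step_c: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    construct: Optional[str] = None,
) -> MeltCurve:
    """Two-state CD melt: folded fraction f(T) = 1/(1+K) with the unfolding
    constant K = exp(−ΔH·1000/(R·T) + ΔS/R), and
    θ = f·θ_F(T) + (1−f)·θ_D(T) + noise.

    Baselines are (intercept mdeg, slope mdeg/°C).  ΔH in kcal mol⁻¹ (>0 for
    unfolding), ΔS in cal mol⁻¹ K⁻¹; the generated midpoint is ΔH/ΔS in K.
    """
    if dh_kcal <= 0 or ds_cal <= 0:
        raise ValueError("two-state unfolding needs dH, dS > 0")
    rng = np.random.default_rng(seed)
    t_c = np.arange(t_range_c[0], t_range_c[1] + step_c / 2, step_c)
    t_k = t_c + C_TO_K
    ln_k = -dh_kcal * 1000.0 / (R_CAL * t_k) + ds_cal / R_CAL
    k_unfold = np.exp(ln_k)
    f = 1.0 / (1.0 + k_unfold)
    theta_f = folded_baseline[0] + folded_baseline[1] * t_c
    theta_d = denatured_baseline[0] + denatured_baseline[1] * t_c
    theta = f * theta_f + (1.0 - f) * theta_d
    if noise_sd > 0:
        theta = theta + rng.normal(0.0, noise_sd, size=len(theta))
    return MeltCurve(temp_c=t_c, theta=theta, construct=construct)


def gen_shift_pair(
    n: int = 137,
    perturb_sites: Sequence[int] = (2, 35, 71, 119, 136),
    magnitudes: tuple[float, float] = (0.8, 0.15),
    cp_site: Optional[int] = None,
    linker_len: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, Optional[CpResidueMap]]:
    """Reference/variant backbone shift-table pair with planted amide
    perturbations.

    The reference table takes each residue's shifts from the pinned
    random-coil values plus seeded structure-like offsets.  The variant is
    identical except that residues in ``perturb_sites`` (native numbering)
    receive amide offsets of ``magnitudes`` (ppm ¹⁵N, ppm NH); the default
    site list models termini-proximal perturbations in a 137-residue chain.
    With ``cp_site`` set, the variant is renumbered through
    :func:`~splitscan.design.cp_residue_map` and linker rows (glycine/serine,
    coil shifts) are inserted.  Returns (reference, variant, map-or-None).
    """
    rng = np.random.default_rng(seed)
    rc = load_random_coil()
    # perturbation sites must carry an amide, so never place proline there
    seq = list(random_sequence(n, seed=seed))
    for s in perturb_sites:
        if 1 <= s <= n and seq[s - 1] == "P":
            seq[s - 1] = "A"
    seq = "".join(seq)

    def structured_row(aa: str):
        r = rc.loc[aa]
        return {
            "N": r["N"] + rng.normal(0, 3.0),
            "HN": (r["HN"] + rng.normal(0, 0.4)) if pd.notna(r["HN"]) else np.nan,
            "CA": r["CA"] + rng.normal(0, 1.5),
            "CB": (r["CB"] + rng.normal(0, 1.5)) if pd.notna(r["CB"]) else np.nan,
        }

    ref_rows = []
    for i in range(1, n + 1):
        row = {"residue": i, "aa": seq[i - 1]}
        row.update(structured_row(seq[i - 1]))
        ref_rows.append(row)
    reference = pd.DataFrame(ref_rows)

    perturb = set(perturb_sites)
    for s in perturb:
        if not (1 <= s <= n):
            raise ValueError(f"perturbation site {s} outside 1..{n}")
    var_native = reference.copy()
    if noise_sd > 0:
        for col in ("N", "HN"):
            var_native[col] = var_native[col] + rng.normal(0, noise_sd, size=n)
    for s in perturb:
        j = var_native.index[var_native["residue"] == s][0]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        var_native.loc[j, "N"] += sign * magnitudes[0]
        var_native.loc[j, "HN"] += sign * magnitudes[1]

    if cp_site is None:
        return reference, var_native, None

    cmap = cp_residue_map(cp_site, n, linker_len)
    linker_aa = ("G" + "S" * max(linker_len - 1, 0))[:linker_len]
    var_rows = []
    native_by_idx = var_native.set_index("residue")
    li = 0
    for cp_pos in range(1, len(cmap) + 1):
        nat = cmap.to_native(cp_pos)
        if isinstance(nat, int):
            row = native_by_idx.loc[nat].to_dict()
            row["residue"] = cp_pos
            row["aa"] = row.pop("aa")
        else:
            aa = linker_aa[li]
            li += 1
            r = rc.loc[aa]
            row = {"residue": cp_pos, "aa": aa, "N": r["N"], "HN": r["HN"],
                   "CA": r["CA"], "CB": r["CB"]}
        var_rows.append(row)
    variant = pd.DataFrame(var_rows)[["residue", "aa", "N", "HN", "CA", "CB"]]
    return reference, variant, cmap


def gen_pts_timecourse(
    k_per_s: float,
    a0: float,
    timepoints_s: Optional[Sequence[float]] = None,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[PTSTimecourse]:
    """Seeded replicate PTS time courses from A(t) = A₀(1 − e^(−kt)).

    Default sampling covers ~5 half-lives with 12 points per replicate
    (denser early), mimicking gel time-point sampling.  Noise is Gaussian on
    the fraction, clipped to the valid densitometry range.
    """
    if k_per_s <= 0 or not (0 < a0 <= 1):
        raise ValueError("need k > 0 and 0 < A0 <= 1")
    if timepoints_s is None:
        t_end = 5.0 * np.log(2.0) / k_per_s
        timepoints_s = np.unique(np.round(np.geomspace(t_end / 60.0, t_end, 12), 3))
    t = np.asarray(timepoints_s, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        a = first_order_model(t, k_per_s, a0)
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=len(t))
        a = np.clip(a, 0.0, 1.05)
        out.append(PTSTimecourse(replicate=f"rep{rep + 1}", time_s=t, fraction=a))
    return out


def gen_itc_isotherm(
    kd_molar: float,
    dh_kcal: float,
    n_stoich: float = 1.0,
    cell_conc_um: float = 20.0,
    syringe_conc_um: float = 300.0,
    n_injections: int = 30,
    injection_volume_ul: float = 5.0,
    cell_volume_ml: float = 1.4,
    temperature_c: float = 25.0,
    offset_ucal: float = 0.0,
    noise_sd_ucal: float = 0.0,
    seed: int = 0,
) -> ITCIsotherm:
    """Single-site titration: heats from the same total-heat model the fitter
    inverts, with the 30 × 5 µL / 1.4 mL / 25 °C scheme as the default
    geometry, plus a constant dilution offset and seeded Gaussian noise."""
    if kd_molar <= 0:
        raise ValueError("Kd must be positive")
    rng = np.random.default_rng(seed)
    vols = np.full(n_injections, float(injection_volume_ul))
    iso = ITCIsotherm(
        cell_volume_ml=cell_volume_ml,
        cell_conc_um=cell_conc_um,
        syringe_conc_um=syringe_conc_um,
        injection_volumes_ul=vols,
        heats_ucal=np.zeros(n_injections),
        temperature_k=temperature_c + C_TO_K,
    )
    heats = injection_heats(iso, n_stoich, kd_molar, dh_kcal, offset_ucal)
    if noise_sd_ucal > 0:
        heats = heats + rng.normal(0.0, noise_sd_ucal, size=n_injections)
    iso.heats_ucal = heats
    return iso
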