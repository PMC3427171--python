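"""Chemical-shift similarity analytics for CP/SP variants versus the parent.

Two complementary statistics localize structural change from backbone shifts:

* Secondary shifts.  Δδ_Cα and Δδ_Cβ are deviations of the observed Cα/Cβ
  shifts from random-coil values; their difference Δδ_Cα − Δδ_Cβ is positive
  in α-helix and negative in β-strand.  The per-residue value is smoothed as
  a 3-residue running mean, and the between-variant difference ΔΔδ measures
  secondary-structure conservation (values generally below ~2 ppm indicate a
  preserved fold).

* Amide chemical-shift perturbation (CSP).  The composite
  Δδ_N+NH = sqrt((Δδ_NH² + Δδ_N²/25)/2) weights the ¹⁵N difference down by
  its larger shift dispersion; residues above a significance cutoff flag
  local environment changes, which for a well-chosen split site cluster at
  the old and new chain termini rather than in the core.

Shift tables are pandas DataFrames with columns ``residue, aa, N, HN, CA,
CB`` (ppm; NaN for unassigned/absent).  Cross-numbering comparisons (CP vs
native) go through a :class:`~splitscan.design.CpResidueMap`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .design import CpResidueMap

__all__ = [
    "load_random_coil",
    "secondary_shift",
    "delta_delta",
    "csp",
    "composite_csp",
]

SHIFT_COLUMNS = ["residue", "aa", "N", "HN", "CA", "CB"]

#: smoothed-value threshold (ppm) separating helix/strand calls from coil
DEFAULT_KAPPA = 0.7
MIN_SMOOTH_POINTS = 2
MIN_MAPPABLE = 5


def load_random_coil(name: str = "wishart1995") -> pd.DataFrame:
    """Pinned random-coil reference shifts, indexed by one-letter amino acid."""
    ref = importlib.resources.files("splitscan.data") / f"random_coil_{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index("aa")


def _validate_table(table: pd.DataFrame, need: list[str]) -> pd.DataFrame:
    missing = [c for c in ("residue", "aa", *need) if c not in table.columns]
    if missing:
        raise ValueError(f"shift table missing columns {missing}")
    if table["residue"].duplicated().any():
        raise ValueError("duplicate residue indices in shift table")
    return table


def secondary_shift(
    table: pd.DataFrame,
    random_coil: Optional[pd.DataFrame] = None,
    kappa: Optional[float] = DEFAULT_KAPPA,
) -> pd.DataFrame:
    """Per-residue Δδ_Cα − Δδ_Cβ with 3-residue smoothing and a structure call.

    raw = (δ_Cα − rc_Cα) − (δ_Cβ − rc_Cβ); for glycine (no Cβ) the Cβ term is
    zero.  smoothed(i) = mean of raw over residues i−1, i, i+1, using available
    values only and requiring at least two contributors (chain ends and gap
    edges average over what exists).  Call: helix if smoothed > +kappa, strand
    if < −kappa, else coil; ``kappa=None`` selects sign-only calls.

    Returns a DataFrame with columns residue, aa, raw, smoothed, ss_call.
    """
    table = _validate_table(table, ["CA", "CB"])
    if random_coil is None:
        random_coil = load_random_coil()

    rows = []
    for _, r in table.sort_values("residue").iterrows():
        aa = str(r["aa"]).upper()
        if aa not in random_coil.index:
            if pd.notna(r["CA"]) or pd.notna(r["CB"]):
                warnings.warn(
                    f"residue {int(r['residue'])}: unknown amino acid {aa!r} "
                    "with shifts present — excluded",
                    stacklevel=2,
                )
            continue
        rc = random_coil.loc[aa]
        raw = np.nan
        if pd.notna(r["CA"]):
            d_ca = r["CA"] - rc["CA"]
            if aa == "G":
                raw = d_ca
            elif pd.notna(r["CB"]) and pd.notna(rc["CB"]):
                raw = d_ca - (r["CB"] - rc["CB"])
        rows.append({"residue": int(r["residue"]), "aa": aa, "raw": raw})
    prof = pd.DataFrame(rows, columns=["residue", "aa", "raw"])

    raw_by_idx = dict(zip(prof["residue"], prof["raw"]))
    smoothed = []
    for i in prof["residue"]:
        vals = [raw_by_idx[j] for j in (i - 1, i, i + 1) if pd.notna(raw_by_idx.get(j, np.nan))]
        smoothed.append(float(np.mean(vals)) if len(vals) >= MIN_SMOOTH_POINTS else np.nan)
    prof["smoothed"] = smoothed

    thr = 0.0 if kappa is None else kappa
    prof["ss_call"] = [
        "helix" if s > thr else "strand" if s < -thr else "coil" if pd.notna(s) else None
        for s in prof["smoothed"]
    ]
    return prof


def delta_delta(
    variant: pd.DataFrame,
    reference: pd.DataFrame,
    residue_map: Optional[CpResidueMap] = None,
) -> pd.DataFrame:
    """Per-residue ΔΔδ between two smoothed secondary-shift profiles.

    ``variant``/``reference`` are outputs of :func:`secondary_shift`.  When a
    CP map is given, variant positions are translated to native numbering and
    linker positions excluded; otherwise the numbering is shared (SP case).
    Returns columns residue (native numbering), delta_delta; positions absent
    from either profile are dropped, their count reported as an attribute.
    """
    ref_by_idx = dict(zip(reference["residue"], reference["smoothed"]))
    rows, skipped = [], 0
    for _, r in variant.iterrows():
        pos = int(r["residue"])
        if residue_map is not None:
            native = residue_map.to_native(pos)
            if not isinstance(native, int):
                continue  # linker position: no native counterpart
        else:
            native = pos
        ref_val = ref_by_idx.get(native, np.nan)
        if pd.isna(ref_val) or pd.isna(r["smoothed"]):
            skipped += 1
            continue
        rows.append({"residue": native, "delta_delta": r["smoothed"] - ref_val})
    out = pd.DataFrame(rows, columns=["residue", "delta_delta"]).sort_values("residue")
    out = out.reset_index(drop=True)
    out.attrs["n_unmapped"] = skipped
    return out


def composite_csp(d_nh: float, d_n: float) -> float:
    """Composite amide perturbation sqrt((Δδ_NH² + Δδ_N²/25) / 2)."""
    return float(np.sqrt((d_nh**2 + d_n**2 / 25.0) / 2.0))


def csp(
    variant: pd.DataFrame,
    reference: pd.DataFrame,
    residue_map: Optional[CpResidueMap] = None,
    threshold_rule: Union[str, float, Callable[[np.ndarray], float]] = "mean+sd",
) -> pd.DataFrame:
    """Composite amide chemical-shift perturbation between two shift tables.

    Both inputs are raw shift tables (columns residue, aa, N, HN, ...).  The
    perturbation is computed per mapped residue with an assigned amide in
    both tables; prolines and unassigned residues drop out naturally.
    Significance: 'mean+sd' (default) flags residues at or above
    mean + 1 SD of all computed values; a float is an absolute ppm cutoff; a
    callable receives the value array and returns the cutoff.

    Returns columns residue (native numbering), d_nh, d_n, csp, significant.
    """
    variant = _validate_table(variant, ["N", "HN"])
    reference = _validate_table(reference, ["N", "HN"])
    ref_rows = reference.set_index("residue")

    rows = []
    for _, r in variant.iterrows():
        pos = int(r["residue"])
        if residue_map is not None:
            native = residue_map.to_native(pos)
            if not isinstance(native, int):
                continue
        else:
            native = pos
        if native not in ref_rows.index:
            continue
        ref = ref_rows.loc[native]
        if pd.isna(r["N"]) or pd.isna(r["HN"]) or pd.isna(ref["N"]) or pd.isna(ref["HN"]):
            continue
        d_nh = float(r["HN"] - ref["HN"])
        d_n = float(r["N"] - ref["N"])
        rows.append(
            {"residue": native, "d_nh": d_nh, "d_n": d_n, "csp": composite_csp(d_nh, d_n)}
        )
    if len(rows) < MIN_MAPPABLE:
        raise ValueError(
            f"only {len(rows)} mappable assigned residues (need >= {MIN_MAPPABLE})"
        )
    out = pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)

    values = out["csp"].to_numpy()
    if callable(threshold_rule):
        cutoff = float(threshold_rule(values))
    elif isinstance(threshold_rule, str):
        if threshold_rule != "mean+sd":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        cutoff = float(values.mean() + values.std(ddof=0))
    else:
        cutoff = float(threshold_rule)
    # a flat all-zero profile has cutoff 0; nothing is "significant" then
    out["significant"] = (out["csp"] >= cutoff) & (out["csp"] > 0)
    out.attrs["cutoff"] = cutoff
    return out
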