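"""Readers and writers for the pipeline's tabular and sequence formats.

All tabular inputs are headered TSV with ``NA`` for missing values:

* score profile — ``residue``, optional ``aa``, ``score``
* shift table   — ``residue``, ``aa``, ``N``, ``HN``, ``CA``, ``CB`` (ppm)
* melt curve    — ``temp_C``, ``theta_mdeg``
* PTS data      — ``replicate``, ``time_s``, ``fraction``
* ITC series    — ``volume_ul``, ``heat_ucal`` plus ``# key: value`` header
                  lines for cell volume/concentrations/temperature

Sequences go through FASTA (Biopython); designed products are written as
separate records suffixed ``|CP<site>``, ``|SP<site>N``/``|SP<site>C`` or
``|PRE<site>``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import SequenceDesign
from .itc import ITCIsotherm
from .melt import MeltCurve
from .pts import PTSTimecourse
from .sites import Residue, ScoreProfile

__all__ = [
    "load_score_profile",
    "load_shift_table",
    "load_melt_curve",
    "load_pts_timecourses",
    "load_itc_isotherm",
    "read_fasta",
    "write_designs_fasta",
]

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: list[str], **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#", **kw)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_score_profile(path: PathLike, protein_id: str | None = None) -> ScoreProfile:
    """Read a CP-score profile TSV; rows with score NA become gaps."""
    df = _read_tsv(path, ["residue", "score"])
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    if not df["residue"].is_monotonic_increasing or df["residue"].duplicated().any():
        raise ValueError(f"{path}: residue indices must be strictly increasing")
    has_aa = "aa" in df.columns
    residues = [
        Residue(
            index=int(r["residue"]),
            aa=str(r["aa"]) if has_aa and pd.notna(r["aa"]) else "X",
            score=None if pd.isna(r["score"]) else float(r["score"]),
        )
        for _, r in df.iterrows()
    ]
    return ScoreProfile(protein_id=protein_id or Path(path).stem, residues=residues)


def load_shift_table(path: PathLike) -> pd.DataFrame:
    """Read a backbone shift table TSV (ppm; NA for unassigned)."""
    df = _read_tsv(path, ["residue", "aa"])
    for col in ("N", "HN", "CA", "CB"):
        if col not in df.columns:
            df[col] = np.nan
    return df[["residue", "aa", "N", "HN", "CA", "CB"]]


def load_melt_curve(path: PathLike, construct: str | None = None) -> MeltCurve:
    df = _read_tsv(path, ["temp_C", "theta_mdeg"])
    return MeltCurve(
        temp_c=df["temp_C"].to_numpy(),
        theta=df["theta_mdeg"].to_numpy(),
        construct=construct or Path(path).stem,
    )


def load_pts_timecourses(path: PathLike) -> list[PTSTimecourse]:
    df = _read_tsv(path, ["replicate", "time_s", "fraction"])
    out = []
    for rep, g in df.groupby("replicate", sort=False):
        g = g.sort_values("time_s")
        out.append(
            PTSTimecourse(
                replicate=str(rep),
                time_s=g["time_s"].to_numpy(),
                fraction=g["fraction"].to_numpy(),
            )
        )
    return out


def load_itc_isotherm(path: PathLike) -> ITCIsotherm:
    """Read an injection-heat series; experiment metadata comes from
    ``# key: value`` comment lines (cell_volume_ml, cell_conc_uM,
    syringe_conc_uM, temperature_K)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val.strip())
    df = pd.read_csv(
        _io.StringIO("".join(l for l in lines if not l.startswith("#"))), sep="\t"
    )
    for col in ("volume_ul", "heat_ucal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    required = ["cell_volume_ml", "cell_conc_uM", "syringe_conc_uM"]
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing header metadata {missing}")
    return ITCIsotherm(
        cell_volume_ml=meta["cell_volume_ml"],
        cell_conc_um=meta["cell_conc_uM"],
        syringe_conc_um=meta["syringe_conc_uM"],
        injection_volumes_ul=df["volume_ul"].to_numpy(),
        heats_ucal=df["heat_ucal"].to_numpy(),
        temperature_k=meta.get("temperature_K", 298.15),
    )


def read_fasta(path: PathLike) -> dict[str, str]:
    """id -> sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _design_records(name: str, design: SequenceDesign):
    site = design.site
    if design.kind == "CP":
        yield SeqRecord(Seq(design.products[0]), id=f"{name}|CP{site}", description="")
    elif design.kind == "SP":
        yield SeqRecord(Seq(design.products[0]), id=f"{name}|SP{site}N", description="")
        yield SeqRecord(Seq(design.products[1]), id=f"{name}|SP{site}C", description="")
    else:
        yield SeqRecord(Seq(design.products[0]), id=f"{name}|PRE{site}", description="")


def write_designs_fasta(path: PathLike, designs: dict[str, SequenceDesign]) -> None:
    records = [rec for name, d in designs.items() for rec in _design_records(name, d)]
    SeqIO.write(records, str(path), "fasta")
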