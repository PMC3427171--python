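"""Cα coordinate extraction for spatial annotation of candidate split sites.

Only the minimal structural operation the pipeline needs lives here: reading
Cα coordinates for one chain of a PDB/mmCIF file (first model) and measuring
Cα–Cα distances from a candidate site to active-site residues.  Anything
heavier belongs in a structural-biology library, not this package.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = ["load_ca_coordinates", "ca_min_distance"]


def load_ca_coordinates(
    path: Union[str, Path], chain: Optional[str] = None
) -> dict[int, np.ndarray]:
    """Residue number -> Cα coordinate (Å) for one chain of the first model.

    ``chain`` selects a chain id; default is the first chain.  Residues
    without a Cα atom (or with missing coordinates) are simply absent from
    the mapping, which downstream code treats as a gap.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    if chain is not None:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"chain {chain!r} not found in {path}")
    else:
        ch = model[0]
    coords: dict[int, np.ndarray] = {}
    for res in ch:
        ca = res.find_atom("CA", "*")
        if ca is not None and res.seqid.num is not None:
            coords[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    return coords


def ca_min_distance(
    coords: Mapping[int, np.ndarray],
    site: int,
    targets: Sequence[int],
) -> Optional[float]:
    """Minimum Cα–Cα distance (Å) from the residues flanking bond ``site``
    to any target residue; None when coordinates are missing."""
    pts = [np.asarray(coords[i]) for i in (site, site + 1) if i in coords]
    tg = [np.asarray(coords[t]) for t in targets if t in coords]
    if not pts or not tg:
        return None
    return float(min(np.linalg.norm(p - t) for p in pts for t in tg))
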