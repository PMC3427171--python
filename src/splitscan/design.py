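"""Construction of circularly permuted (CP) and split (SP) protein sequences.

Given a parent sequence and a split site i (the bond between residues i and
i+1), three constructs are built:

* CP       — single chain starting at residue i+1; the native termini are
             joined through a short flexible linker (GSS by default).
* SP       — the two fragments 1..i and i+1..n expressed separately.
* SP precursor — a single-chain permuted sequence carrying a self-excising
             CFNGSS junction: with the catalytic first Cys and last Asn left
             intact, the intein splices the linker out in vivo, releasing the
             two SP fragments.

Mutations are specified in native numbering (e.g. C1G, N137A — the catalytic
knockouts used to trap inactive complexes) and applied before permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Mutation",
    "SequenceDesign",
    "CpResidueMap",
    "parse_mutation",
    "apply_mutations",
    "build_cp_sequence",
    "build_sp_fragments",
    "build_sp_precursor",
    "cp_residue_map",
]

CP_LINKER = "GSS"
PRECURSOR_LINKER = "CFNGSS"
LINKER_TAG = "linker"


@dataclass(frozen=True)
class Mutation:
    """Point substitution at a native-numbered position."""

    index: int
    from_aa: str
    to_aa: str

    def __str__(self) -> str:
        return f"{self.from_aa}{self.index}{self.to_aa}"


@dataclass
class SequenceDesign:
    """A designed construct and its product sequence(s).

    ``products`` holds one sequence for CP and SP_PRECURSOR kinds and the
    (N-fragment, C-fragment) pair for SP.
    """

    kind: str  # "CP" | "SP" | "SP_PRECURSOR"
    parent: str
    site: int
    linker: str
    mutations: tuple[Mutation, ...]
    products: tuple[str, ...]


def parse_mutation(text: str) -> Mutation:
    """Parse 'C1G'-style notation into a Mutation."""
    text = text.strip()
    if len(text) < 3 or not text[1:-1].isdigit():
        raise ValueError(f"cannot parse mutation {text!r}")
    return Mutation(index=int(text[1:-1]), from_aa=text[0].upper(), to_aa=text[-1].upper())


def _coerce_mutations(mutations: Iterable[Union[Mutation, str]]) -> tuple[Mutation, ...]:
    return tuple(m if isinstance(m, Mutation) else parse_mutation(m) for m in mutations)


def apply_mutations(parent: str, mutations: Iterable[Union[Mutation, str]]) -> str:
    """Apply native-numbered substitutions, validating the from-letters."""
    seq = list(parent)
    muts = _coerce_mutations(mutations)
    for m in muts:
        if not (1 <= m.index <= len(seq)):
            raise ValueError(f"mutation {m} outside sequence of length {len(seq)}")
        if seq[m.index - 1] != m.from_aa:
            raise ValueError(
                f"mutation {m}: parent has {seq[m.index - 1]} at position {m.index}"
            )
        seq[m.index - 1] = m.to_aa
    return "".join(seq)


def _check_site(parent: str, site: int) -> None:
    if not (1 <= site < len(parent)):
        raise ValueError(f"site {site} not a valid bond index for length {len(parent)}")


def build_cp_sequence(
    parent: str,
    site: int,
    linker: str = CP_LINKER,
    mutations: Iterable[Union[Mutation, str]] = (),
) -> SequenceDesign:
    """Circular permutant opened at ``site``: product = parent[site+1..n] +
    linker + parent[1..site], mutations applied in native numbering first."""
    _check_site(parent, site)
    muts = _coerce_mutations(mutations)
    seq = apply_mutations(parent, muts)
    product = seq[site:] + linker + seq[:site]
    return SequenceDesign("CP", parent, site, linker, muts, (product,))


def build_sp_fragments(
    parent: str,
    site: int,
    mutations: Iterable[Union[Mutation, str]] = (),
) -> SequenceDesign:
    """Two-piece split: N-fragment parent[1..site], C-fragment parent[site+1..n]."""
    _check_site(parent, site)
    muts = _coerce_mutations(mutations)
    seq = apply_mutations(parent, muts)
    return SequenceDesign("SP", parent, site, "", muts, (seq[:site], seq[site:]))


def build_sp_precursor(
    parent: str,
    site: int,
    linker: str = PRECURSOR_LINKER,
) -> SequenceDesign:
    """Single-chain permuted precursor with a self-excising junction.

    The catalytic termini are left unmutated so the expressed chain splices
    the linker out; ``excision_products`` gives the expected in-vivo result.
    """
    _check_site(parent, site)
    product = parent[site:] + linker + parent[:site]
    return SequenceDesign("SP_PRECURSOR", parent, site, linker, (), (product,))


def excision_products(design: SequenceDesign) -> tuple[str, str]:
    """Expected fragments after in-vivo excision of a precursor's linker:
    identical to the two-piece split of the parent at the same site."""
    if design.kind != "SP_PRECURSOR":
        raise ValueError("excision products defined only for SP_PRECURSOR designs")
    sp = build_sp_fragments(design.parent, design.site)
    return sp.products  # type: ignore[return-value]


class CpResidueMap:
    """Bijection between CP-construct positions and native residue numbers.

    CP position 1 corresponds to native residue site+1; linker positions map
    to the tag 'linker'; native residue 1 sits at CP position
    n - site + linker_len + 1.
    """

    def __init__(self, site: int, n: int, linker_len: int = len(CP_LINKER)):
        if not (1 <= site < n):
            raise ValueError(f"site {site} not a valid bond index for length {n}")
        self.site = site
        self.n = n
        self.linker_len = linker_len

    def __len__(self) -> int:
        return self.n + self.linker_len

    def to_native(self, cp_pos: int) -> Union[int, str]:
        """Native residue number at a CP position, or 'linker'."""
        if not (1 <= cp_pos <= len(self)):
            raise KeyError(cp_pos)
        head = self.n - self.site  # residues site+1..n
        if cp_pos <= head:
            return self.site + cp_pos
        if cp_pos <= head + self.linker_len:
            return LINKER_TAG
        return cp_pos - head - self.linker_len

    def to_cp(self, native: int) -> int:
        """CP position of a native residue number."""
        if not (1 <= native <= self.n):
            raise KeyError(native)
        if native > self.site:
            return native - self.site
        return self.n - self.site + self.linker_len + native

    def items(self):
        """(cp_pos, native-or-'linker') pairs over the whole construct."""
        return [(p, self.to_native(p)) for p in range(1, len(self) + 1)]


def cp_residue_map(site: int, n: int, linker_len: int = len(CP_LINKER)) -> CpResidueMap:
    return CpResidueMap(site, n, linker_len)
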