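"""Split-site selection from circular-permutation (CP) viability score profiles.

A CP predictor assigns each residue of a protein a score in [0, 1] giving the
likelihood that opening the backbone there yields a viable, natively folded
circular permutant.  Because a backbone opening tolerated in a circular
permutant is a strong candidate for a split site, the same profile drives
split-protein design: we look for favorable local score maxima, keep those
sufficiently separated from catalytically essential residues, and prefer
sites in the N-terminal half (short N-fragments are chemically synthesizable,
which is what makes an N-proximal split site valuable).

Site indexing convention: split site ``i`` denotes the peptide bond between
residues ``i`` and ``i+1`` (1-based), so "site 36" opens N36-G37.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Residue",
    "ScoreProfile",
    "SplitCandidate",
    "find_local_maxima",
    "classify_sites",
    "rank_candidates",
    "nearest_predicted_site",
]

#: classification thresholds — favorable strictly above, unfavorable strictly below
DEFAULT_HI = 0.7
DEFAULT_LO = 0.5
DEFAULT_WINDOW = 7
DEFAULT_MIN_SEP = 10

FAVORABLE = "favorable"
INDETERMINATE = "indeterminate"
UNFAVORABLE = "unfavorable"


@dataclass(frozen=True)
class Residue:
    """One scored position: 1-based index, one-letter code ('X' if unknown),
    and a CP-viability score in [0, 1] or None for a gap (e.g. residues whose
    coordinates are missing from the structure and therefore unscorable)."""

    index: int
    aa: str = "X"
    score: Optional[float] = None


@dataclass
class ScoreProfile:
    """Per-residue CP-viability scores for one protein.

    Indices must be strictly increasing; index gaps and None scores are both
    treated as "no call" regions that break local-maximum windows.
    """

    protein_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        prev = 0
        for r in self.residues:
            if r.index <= prev:
                raise ValueError(
                    f"{self.protein_id}: residue indices must be strictly "
                    f"increasing (got {r.index} after {prev})"
                )
            if r.score is not None and not (0.0 <= r.score <= 1.0):
                raise ValueError(
                    f"{self.protein_id}: score {r.score} at residue {r.index} "
                    "outside [0, 1]"
                )
            prev = r.index

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        """Length of the chain, taken as the highest residue index."""
        return self.residues[-1].index if self.residues else 0

    def scores(self) -> dict[int, float]:
        """Mapping of residue index -> score for scored residues only."""
        return {r.index: r.score for r in self.residues if r.score is not None}

    def aa_map(self) -> dict[int, str]:
        return {r.index: r.aa for r in self.residues}


@dataclass
class SplitCandidate:
    """A scored candidate backbone-opening site (bond i / i+1)."""

    site: int
    score: float
    is_local_max: bool = False
    klass: str = INDETERMINATE
    seq_sep_active: Optional[int] = None
    spatial_dist_active: Optional[float] = None
    in_n_half: bool = False
    rank: Optional[int] = None


def _check_window(window: int) -> int:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    return (window - 1) // 2


def _window_scores(scores: Mapping[int, float], i: int, half: int) -> list[float]:
    """Scores of contiguous scored neighbors of i within +/-half.

    The window truncates at the first missing index or unscored residue on
    either side, so gaps never silently compare across a break in the chain.
    """
    out = []
    j = i - 1
    while j >= i - half and j in scores:
        out.append(scores[j])
        j -= 1
    j = i + 1
    while j <= i + half and j in scores:
        out.append(scores[j])
        j += 1
    return out


def find_local_maxima(profile: ScoreProfile, window: int = DEFAULT_WINDOW) -> list[int]:
    """Residue indices whose score dominates every scored neighbor in a
    +/-((window-1)/2)-residue window.

    A position qualifies when its score is >= every window score and strictly
    greater than at least one of them; for plateaus of equal scores the
    leftmost position is reported.  Gaps (missing indices or None scores)
    truncate the window.
    """
    half = _check_window(window)
    scores = profile.scores()
    maxima = []
    for i, s in scores.items():
        neigh = _window_scores(scores, i, half)
        if not neigh:
            continue
        if all(s >= v for v in neigh) and any(s > v for v in neigh):
            # plateau: defer to the leftmost equal-scoring contiguous position
            if (i - 1) in scores and scores[i - 1] == s:
                continue
            maxima.append(i)
    return maxima


def classify_sites(
    profile: ScoreProfile,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    window: int = DEFAULT_WINDOW,
) -> list[SplitCandidate]:
    """Classify every scored residue as favorable (score > hi), unfavorable
    (score < lo) or indeterminate; comparisons are strict on both sides."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    maxima = set(find_local_maxima(profile, window=window))
    n = profile.n_residues
    out = []
    for r in profile.residues:
        if r.score is None:
            continue
        if r.score > hi:
            klass = FAVORABLE
        elif r.score < lo:
            klass = UNFAVORABLE
        else:
            klass = INDETERMINATE
        out.append(
            SplitCandidate(
                site=r.index,
                score=r.score,
                is_local_max=r.index in maxima,
                klass=klass,
                in_n_half=r.index <= n / 2,
            )
        )
    return out


def rank_candidates(
    profile: ScoreProfile,
    structure: Optional[Mapping[int, "object"]] = None,
    active_sites: Sequence[int] = (),
    min_sep: int = DEFAULT_MIN_SEP,
    prefer_n_half: bool = True,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    window: int = DEFAULT_WINDOW,
) -> list[SplitCandidate]:
    """Rank favorable local-maximum sites for splitting.

    Selection: favorable (score > hi) local maxima whose sequence separation
    from every active-site residue is >= min_sep.  Ordering: score descending
    with ties (to the nearest 0.01) broken toward the N-terminal half when
    ``prefer_n_half``, then toward the lower site index.

    ``structure`` may be a mapping residue index -> Cartesian Cα coordinate
    (any 3-sequence); when given, the minimum Cα–Cα distance from the site to
    any active-site residue is annotated (annotation only — the filter is
    sequence separation, which needs no structure).
    """
    for a in active_sites:
        if not (1 <= a <= max(profile.n_residues, 1)):
            raise ValueError(f"active site {a} outside sequence range")
    cands = [
        c
        for c in classify_sites(profile, hi=hi, lo=lo, window=window)
        if c.klass == FAVORABLE and c.is_local_max
    ]
    if active_sites:
        for c in cands:
            c.seq_sep_active = min(abs(c.site - a) for a in active_sites)
        cands = [c for c in cands if c.seq_sep_active >= min_sep]
    if structure is not None and active_sites:
        from .structure import ca_min_distance

        for c in cands:
            c.spatial_dist_active = ca_min_distance(structure, c.site, active_sites)
    if not cands:
        warnings.warn("no favorable local-maximum split sites found", stacklevel=2)
        return []

    def key(c: SplitCandidate):
        tie_half = (0 if c.in_n_half else 1) if prefer_n_half else 0
        return (-round(c.score, 2), tie_half, c.site)

    cands.sort(key=key)
    for i, c in enumerate(cands, start=1):
        c.rank = i
    return cands


def nearest_predicted_site(
    profile: ScoreProfile,
    reported_site: int,
    hi: float = DEFAULT_HI,
    window: int = DEFAULT_WINDOW,
    max_distance: Optional[int] = None,
) -> Optional[tuple[int, float]]:
    """The favorable local maximum nearest (in sequence) to a reported split
    site, or None when no favorable maximum exists within ``max_distance``
    (ties resolved toward the lower index)."""
    if not (1 <= reported_site <= profile.n_residues):
        raise ValueError(f"reported site {reported_site} outside sequence range")
    scores = profile.scores()
    best: Optional[tuple[int, float]] = None
    best_d = None
    for i in find_local_maxima(profile, window=window):
        if scores[i] <= hi:
            continue
        d = abs(i - reported_site)
        if max_distance is not None and d > max_distance:
            continue
        if best_d is None or d < best_d or (d == best_d and i < best[0]):
            best, best_d = (i, scores[i]), d
    return best
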