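"""Split-site selection: local maxima, classification, ranking, proximity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitscan.io import load_score_profile
from splitscan.sites import (
    FAVORABLE,
    INDETERMINATE,
    UNFAVORABLE,
    Residue,
    ScoreProfile,
    classify_sites,
    find_local_maxima,
    nearest_predicted_site,
    rank_candidates,
)


def make_profile(scores, start=1, pid="p"):
    return ScoreProfile(
        pid, [Residue(index=start + i, score=s) for i, s in enumerate(scores)]
    )


def brute_force_maxima(scores, window):
    """Exhaustive neighbor comparison on a dense (gap-free) profile:
    position i is a maximum when its score is >= every score within
    +/-(window-1)/2, beats at least one, and is the leftmost of a plateau."""
    half = (window - 1) // 2
    out = []
    for i in range(len(scores)):
        neigh = [
            scores[j]
            for j in range(max(0, i - half), min(len(scores), i + half + 1))
            if j != i
        ]
        if not neigh:
            continue
        ok = all(scores[i] >= v for v in neigh) and any(scores[i] > v for v in neigh)
        if ok and i > 0 and scores[i - 1] == scores[i]:
            ok = False
        if ok:
            out.append(i + 1)
    return out


class TestLoadScoreProfile:
    def test_full_length_profile(self, tmp_path):
        path = tmp_path / "p.tsv"
        rows = "\n".join(f"{i}\tA\t0.5" for i in range(1, 138))
        path.write_text("residue\taa\tscore\n" + rows + "\n")
        prof = load_score_profile(path)
        assert len(prof) == 137
        assert prof.n_residues == 137

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            load_score_profile(path)

    def test_missing_coordinate_gap_preserved(self, tmp_path):
        # simulates a chain whose structure lacks coordinates for 98-116
        path = tmp_path / "gap.tsv"
        rows = [f"{i}\t0.6" for i in range(1, 98)]
        rows += [f"{i}\t0.6" for i in range(117, 155)]
        path.write_text("residue\tscore\n" + "\n".join(rows) + "\n")
        prof = load_score_profile(path)
        scored = prof.scores()
        assert len(prof) == 97 + 38
        assert all(i not in scored for i in range(98, 117))

    def test_na_rows_become_gaps_not_zero(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("residue\tscore\n1\t0.5\n2\tNA\n3\t0.7\n")
        prof = load_score_profile(path)
        assert prof.scores() == {1: 0.5, 3: 0.7}

    def test_non_monotone_indices_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("residue\tscore\n2\t0.5\n1\t0.6\n")
        with pytest.raises(ValueError, match="increasing"):
            load_score_profile(path)

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        path.write_text("residue\tscore\n1\t1.5\n")
        with pytest.raises(ValueError):
            load_score_profile(path)


class TestFindLocalMaxima:
    def test_single_peak(self):
        assert find_local_maxima(make_profile([0.1, 0.2, 0.9, 0.2, 0.1]), 3) == [3]

    def test_flat_profile_has_no_strict_maximum(self):
        assert find_local_maxima(make_profile([0.5] * 20), 3) == []

    def test_plateau_reports_leftmost(self):
        assert find_local_maxima(make_profile([0.1, 0.8, 0.8, 0.1]), 3) == [2]

    def test_gap_breaks_window(self):
        # 0.9 at index 3 and 0.8 at index 5 separated by an unscored residue:
        # both dominate their truncated windows
        prof = ScoreProfile(
            "g",
            [
                Residue(1, score=0.1),
                Residue(2, score=0.2),
                Residue(3, score=0.9),
                Residue(4, score=None),
                Residue(5, score=0.8),
                Residue(6, score=0.2),
            ],
        )
        assert find_local_maxima(prof, 3) == [3, 5]

    @pytest.mark.parametrize("window", [2, 4, 1, 0])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            find_local_maxima(make_profile([0.1, 0.5, 0.1]), window)

    @settings(max_examples=150, derandomize=True)
    @given(
        scores=st.lists(
            st.floats(0, 1, allow_nan=False, width=16), min_size=3, max_size=200
        ),
        window=st.sampled_from([3, 5, 7]),
    )
    def test_agrees_with_exhaustive_oracle(self, scores, window):
        prof = make_profile(scores)
        assert find_local_maxima(prof, window) == brute_force_maxima(scores, window)


class TestClassifySites:
    def test_reported_favorable_scores(self):
        # scores of three known-functional split sites, all above 0.7
        prof = make_profile([0.812, 0.852, 0.791])
        assert all(c.klass == FAVORABLE for c in classify_sites(prof))

    def test_low_score_unfavorable(self):
        assert classify_sites(make_profile([0.378]))[0].klass == UNFAVORABLE

    def test_threshold_boundary_is_strict(self):
        cands = classify_sites(make_profile([0.7, 0.5]))
        assert [c.klass for c in cands] == [INDETERMINATE, INDETERMINATE]

    def test_partition_is_exhaustive_and_disjoint(self, npu_like_profile):
        cands = classify_sites(npu_like_profile)
        assert len(cands) == len(npu_like_profile.scores())
        assert all(c.klass in (FAVORABLE, INDETERMINATE, UNFAVORABLE) for c in cands)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_sites(make_profile([0.5]), hi=0.4, lo=0.6)


class TestRankCandidates:
    def test_planted_n_terminal_sites_retained(self, npu_like_profile):
        cands = rank_candidates(
            npu_like_profile, active_sites=[1, 137], min_sep=10
        )
        assert sorted(c.site for c in cands) == [12, 36, 102]
        assert all(c.seq_sep_active >= 10 for c in cands)

    def test_separation_filter_drops_terminal_site(self):
        prof = make_profile([0.5, 0.9, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="no favorable"):
            cands = rank_candidates(prof, active_sites=[1], min_sep=10, window=3)
        assert cands == []

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        peaks = [(10, 0.82), (30, 0.91), (55, 0.75), (80, 0.91)]
        scores = np.clip(rng.normal(0.3, 0.05, 100), 0, 0.6)
        for site, h in peaks:
            scores[site - 1] = h
        prof = make_profile(list(scores))
        cands = rank_candidates(prof, window=3)
        # independent sort: score (2 dp) desc, N-half first, lower index
        n = prof.n_residues
        expected = sorted(
            [(s, h) for s, h in peaks],
            key=lambda p: (-round(p[1], 2), 0 if p[0] <= n / 2 else 1, p[0]),
        )
        assert [c.site for c in cands] == [s for s, _ in expected]
        assert [c.rank for c in cands] == [1, 2, 3, 4]

    def test_row_order_cannot_vary(self, npu_like_profile):
        # profiles are index-sorted by construction; ranking depends only on
        # (index, score) pairs, so rebuilding from a shuffled copy is identical
        shuffled = ScoreProfile(
            "s", sorted(npu_like_profile.residues, key=lambda r: r.index)
        )
        a = [c.site for c in rank_candidates(npu_like_profile)]
        b = [c.site for c in rank_candidates(shuffled)]
        assert a == b


class TestNearestPredictedSite:
    def test_nearby_favorable_maximum_found(self):
        # reported site 34 with the nearest favorable maximum two residues away
        scores = [0.3] * 50
        scores[35] = 0.709  # residue 36
        prof = make_profile(scores)
        assert nearest_predicted_site(prof, 34, window=3) == (36, 0.709)

    def test_no_favorable_maximum_returns_absent(self):
        scores = [0.3] * 50
        scores[25] = 0.378  # local max but unfavorable
        assert nearest_predicted_site(make_profile(scores), 26, window=3) is None

    def test_exact_favorable_maximum_returns_itself(self, npu_like_profile):
        site, score = nearest_predicted_site(npu_like_profile, 36)
        assert site == 36 and score > 0.7

    def test_returned_distance_is_minimal(self, npu_like_profile):
        maxima = find_local_maxima(npu_like_profile)
        scored = npu_like_profile.scores()
        favorable = [i for i in maxima if scored[i] > 0.7]
        for reported in (5, 20, 60, 110, 130):
            site, _ = nearest_predicted_site(npu_like_profile, reported)
            assert all(abs(i - reported) >= abs(site - reported) for i in favorable)
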