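"""Contig building, CB layout, DQer, and relaxed merging — exercised on
fingerprints with fully controlled band sharing so every expected grouping
is known in advance."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from bacmap.assembly import (
    ScoreCache,
    build_contigs,
    contig_summary,
    dqer,
    layout_contig,
    relaxed_merge,
)
from bacmap.fingerprint import Fingerprint, ScoreParams, sulston_log10

N_BANDS = 130
PARAMS = ScoreParams(3, 5650, 1e-80)


def fp(cid, bands):
    return Fingerprint(cid, "synth", tuple(sorted(bands)))


def lattice(start, n):
    """n distinct band values spaced 10 units apart (> 2t+1, so values
    shared between clones match and values not shared never do)."""
    return [start + 10 * i for i in range(n)]


def shares_for_score(lo, hi):
    """Number of shared bands whose Sulston log10 score (n=130 vs 130)
    falls in (lo, hi)."""
    for j in range(N_BANDS, 0, -1):
        s = sulston_log10(N_BANDS, N_BANDS, j, PARAMS)
        if lo < s < hi:
            return j
    raise AssertionError("no share count gives a score in the window")


A_BANDS = lattice(40, N_BANDS)


def make_pair(name1, name2, shared, fresh_start):
    bands = sorted(A_BANDS[:shared] + lattice(fresh_start, N_BANDS - shared))
    return [fp(name1, bands), fp(name2, bands)]


class TestBuild:
    def test_separated_groups_form_two_contigs(self):
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + make_pair(
            "B1", "B2", 0, 3000
        )
        pmap = build_contigs(fps, PARAMS)
        groups = sorted(sorted(c.clone_ids) for c in pmap.contigs.values())
        assert groups == [["A1", "A2"], ["B1", "B2"]]
        assert pmap.singletons == []

    def test_unrelated_all_singletons(self):
        rng = np.random.default_rng(17)
        fps = [
            fp(f"c{i}", rng.choice(np.arange(40, 5600), 107, replace=False))
            for i in range(6)
        ]
        pmap = build_contigs(fps, PARAMS)
        assert pmap.contigs == {}
        assert len(pmap.singletons) == 6

    def test_empty_input(self):
        pmap = build_contigs([], PARAMS)
        assert pmap.n_clones == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            ScoreCache([fp("x", A_BANDS), fp("x", A_BANDS)], PARAMS)

    def test_deterministic(self):
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + make_pair(
            "B1", "B2", 0, 3000
        )
        p1 = build_contigs(fps, PARAMS)
        p2 = build_contigs(fps, PARAMS)
        assert {k: v.members for k, v in p1.contigs.items()} == {
            k: v.members for k, v in p2.contigs.items()
        }


class TestScoreCache:
    def test_upper_bound_dominates_matched(self):
        rng = np.random.default_rng(5)
        fps = [
            fp(f"c{i}", rng.choice(np.arange(40, 5600), 100, replace=False))
            for i in range(8)
        ]
        cache = ScoreCache(fps, PARAMS)
        ids = [f.clone_id for f in fps]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert cache.upper_bound_matched(a, b) >= cache.matched(a, b)
                assert cache.log10_upper_evidence(a, b) <= cache.log10_score(
                    a, b
                )

    def test_edges_sorted_best_first(self):
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + make_pair(
            "B1", "B2", shares_for_score(-78, -55), 3000
        )
        cache = ScoreCache(fps, PARAMS)
        edges = cache.edges([f.clone_id for f in fps], 0.0)
        scores = [s for s, _, _ in edges]
        assert scores == sorted(scores)


class TestLayout:
    def test_staggered_clones_ordered(self, pipe):
        """On the study run: within every contig of >= 10 clones the CB
        left ends must rank-correlate with the true genome starts."""
        truth = {c.clone_id: c.true_start for c in pipe.clones}
        checked = 0
        for contig in pipe.pmap.contigs.values():
            if len(contig.members) < 10:
                continue
            lefts = [m.left_cb for m in contig.members]
            starts = [truth[m.clone_id] for m in contig.members]
            rho = spearmanr(lefts, starts).statistic
            assert abs(rho) >= 0.95
            checked += 1
        assert checked >= 1

    def test_span_equals_band_count(self):
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)]
        cache = ScoreCache(fps, PARAMS)
        members = layout_contig(["A1", "A2"], cache, -80.0)
        for m in members:
            assert m.span_cb == N_BANDS

    def test_single_clone(self):
        cache = ScoreCache([fp("A1", A_BANDS)], PARAMS)
        [m] = layout_contig(["A1"], cache, -80.0)
        assert (m.left_cb, m.right_cb) == (0, N_BANDS)

    def test_disconnected_rejected(self):
        fps = [fp("A1", A_BANDS)] + make_pair("B1", "B2", 0, 3000)[:1]
        cache = ScoreCache(fps, PARAMS)
        with pytest.raises(ValueError):
            layout_contig(["A1", "B1"], cache, -80.0)


class TestDqer:
    def permissive_map(self):
        rng = np.random.default_rng(4)
        junk = [
            fp(f"J{i}", rng.choice(np.arange(40, 5600), N_BANDS, replace=False))
            for i in (1, 2)
        ]
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + junk
        perm = ScoreParams(3, 5650, 0.9)
        cache = ScoreCache(fps, perm)
        return build_contigs(fps, perm, cache), cache

    def test_breaks_glued_contig(self):
        pmap, cache = self.permissive_map()
        assert len(pmap.contigs) == 1  # permissive build glued everything
        broken = dqer(pmap, cache, q_threshold=0.10)
        groups = sorted(sorted(c.clone_ids) for c in broken.contigs.values())
        assert groups == [["A1", "A2"]]
        assert sorted(broken.singletons) == ["J1", "J2"]

    def test_threshold_one_is_noop(self):
        pmap, cache = self.permissive_map()
        kept = dqer(pmap, cache, q_threshold=1.0)
        assert len(kept.contigs) == 1
        assert kept.n_clones == pmap.n_clones

    def test_conserves_clones(self, pipe):
        assert pipe.pmap.n_clones == len(pipe.kept_fingerprints)


class TestRelaxedMerge:
    def two_contig_map(self, bridge_window):
        j = shares_for_score(*bridge_window)
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + make_pair(
            "B1", "B2", j, 3000
        )
        cache = ScoreCache(fps, PARAMS)
        pmap = build_contigs(fps, PARAMS, cache)
        assert len(pmap.contigs) == 2
        return pmap, cache

    def test_merge_respects_threshold_ordering(self):
        # bridge score between 1e-80 and 1e-50: merged at 1e-50, not 1e-80
        pmap, cache = self.two_contig_map((-78, -55))
        at80 = relaxed_merge(pmap, cache, 1e-80, "ends_to_ends")
        assert len(at80.contigs) == 2
        at50 = relaxed_merge(pmap, cache, 1e-50, "ends_to_ends")
        assert len(at50.contigs) == 1
        assert sorted(next(iter(at50.contigs.values())).clone_ids) == [
            "A1",
            "A2",
            "B1",
            "B2",
        ]

    def test_singles_to_ends_attaches(self):
        j = shares_for_score(-75, -55)
        s = fp("S", sorted(A_BANDS[:j] + lattice(8000, N_BANDS - j)))
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS), s]
        cache = ScoreCache(fps, PARAMS)
        pmap = build_contigs(fps, PARAMS, cache)
        assert pmap.singletons == ["S"]
        merged = relaxed_merge(pmap, cache, 1e-50, "singles_to_ends")
        assert merged.singletons == []
        assert sorted(next(iter(merged.contigs.values())).clone_ids) == [
            "A1",
            "A2",
            "S",
        ]

    def test_evidence_requires_shared_linkage(self):
        # bridge score between 1e-50 and the 1e-25 floor: only the
        # evidence mode may use it, and only with a shared linkage group
        pmap, cache = self.two_contig_map((-48, -27))
        plain = relaxed_merge(pmap, cache, 1e-50, "ends_to_ends")
        assert len(plain.contigs) == 2
        shared = {"ctg1": [("LG1", 10.0)], "ctg2": [("LG1", 12.0)]}
        other = {"ctg1": [("LG1", 10.0)], "ctg2": [("LG2", 12.0)]}
        far = {"ctg1": [("LG1", 10.0)], "ctg2": [("LG1", 40.0)]}
        assert (
            len(
                relaxed_merge(
                    pmap, cache, 1e-50, "evidence", evidence=shared
                ).contigs
            )
            == 1
        )
        assert (
            len(
                relaxed_merge(
                    pmap, cache, 1e-50, "evidence", evidence=other
                ).contigs
            )
            == 2
        )
        assert (
            len(
                relaxed_merge(
                    pmap, cache, 1e-50, "evidence", evidence=far
                ).contigs
            )
            == 2
        )

    def test_mode_validation(self):
        pmap, cache = self.two_contig_map((-78, -55))
        with pytest.raises(ValueError):
            relaxed_merge(pmap, cache, 1e-50, "sideways")
        with pytest.raises(ValueError):
            relaxed_merge(pmap, cache, 1e-50, "evidence")

    def test_merge_conserves_clones(self, pipe):
        assert set(pipe.pmap.all_clone_ids()) == {
            f.clone_id for f in pipe.kept_fingerprints
        }


class TestSummary:
    def test_histogram_arithmetic(self):
        fps = [fp("A1", A_BANDS), fp("A2", A_BANDS)] + make_pair(
            "B1", "B2", 0, 3000
        )
        pmap = build_contigs(fps, PARAMS)
        s = contig_summary(pmap)
        assert s["n_contigs"] == 2
        assert s["histogram"]["<=5"] == 2
        assert s["total_clones"] == 4
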