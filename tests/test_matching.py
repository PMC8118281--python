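"""Similarity-measure algebra, gallery construction, ranking, and CMC
behavior, including the random-performance null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibface.matching import (
    CMCCurve,
    build_gallery,
    cmc,
    enumerate_pairs,
    fuse_segments,
    gallery_size_resampling,
    identify,
    random_cmc_envelope,
    run_identification,
    similarity,
)


class TestSimilarity:
    def test_identical_vectors_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        s = np.array([1.0, 1.0, 2.0])
        for m in ("ED", "MD", "EA", "MA"):
            assert similarity(a, a.copy(), m, s) == pytest.approx(0.0)

    def test_hand_computed_whitening(self):
        sigma = np.array([2.0, 1.0])
        a, b = np.array([2.0, 0.0]), np.array([0.0, 1.0])
        assert similarity(a, b, "MD", sigma) == pytest.approx(np.sqrt(2))
        assert similarity(a, b, "MA", sigma) == pytest.approx(np.pi / 2)

    def test_antipodal_angle(self):
        assert similarity(np.array([1.0, 0.0]), np.array([-1.0, 0.0]), "EA") == (
            pytest.approx(np.pi)
        )

    def test_md_equals_ed_in_whitened_space(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        sigma = rng.uniform(0.5, 2.0, size=5)
        assert similarity(a, b, "MD", sigma) == pytest.approx(
            similarity(a / sigma, b / sigma, "ED"), abs=1e-12
        )

    def test_angles_scale_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=4), rng.normal(size=4)
        sigma = rng.uniform(0.5, 2.0, size=4)
        for m in ("EA", "MA"):
            assert similarity(3.7 * a, b, m, sigma) == pytest.approx(
                similarity(a, 0.2 * b, m, sigma), abs=1e-12
            )

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetry_property(self, a, b):
        a, b = np.array(a), np.array(b)
        sigma = np.array([1.0, 2.0, 0.5])
        for m in ("ED", "MD"):
            assert similarity(a, b, m, sigma) == similarity(b, a, m, sigma)
        if np.linalg.norm(a) > 1e-6 and np.linalg.norm(b) > 1e-6:
            for m in ("EA", "MA"):
                assert similarity(a, b, m, sigma) == similarity(b, a, m, sigma)

    def test_zero_vector_angle_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(3), np.ones(3), "EA")


class TestFusion:
    def test_single_segment_fusion_is_identity(self):
        f = {1: np.array([1.0, 2.0])}
        np.testing.assert_array_equal(fuse_segments(f), f[1])

    def test_fused_squared_distance_is_sum(self):
        rng = np.random.default_rng(2)
        fa = {s: rng.normal(size=3) for s in (1, 2, 3)}
        fb = {s: rng.normal(size=3) for s in (1, 2, 3)}
        fused = similarity(fuse_segments(fa), fuse_segments(fb), "ED") ** 2
        per_seg = sum(similarity(fa[s], fb[s], "ED") ** 2 for s in (1, 2, 3))
        assert fused == pytest.approx(per_seg, abs=1e-10)

    def test_fused_ma_matches_direct_concatenation(self):
        rng = np.random.default_rng(3)
        sigmas = {s: rng.uniform(0.5, 2, size=4) for s in (1, 2)}
        fa = {s: rng.normal(size=4) for s in (1, 2)}
        fb = {s: rng.normal(size=4) for s in (1, 2)}
        va = fuse_segments(fa, sigmas)
        vb = fuse_segments(fb, sigmas)
        direct = similarity(
            np.concatenate([fa[1] / sigmas[1], fa[2] / sigmas[2]]),
            np.concatenate([fb[1] / sigmas[1], fb[2] / sigmas[2]]),
            "EA",
        )
        assert similarity(va, vb, "EA") == pytest.approx(direct, abs=1e-12)
        # and in general differs from every per-segment MA
        per = [similarity(fa[s], fb[s], "MA", sigmas[s]) for s in (1, 2)]
        assert all(abs(direct - p) > 1e-6 for p in per)

    def test_missing_segment_named(self):
        with pytest.raises(ValueError, match="2"):
            fuse_segments({1: np.ones(2)}, segment_ids=[1, 2])


class TestGallery:
    def test_pairs_only_families_gallery_size(self):
        ids = [f"i{k}" for k in range(10)]
        fams = [f"f{k // 2}" for k in range(10)]
        for q, s in ((ids[0], ids[1]), (ids[4], ids[5])):
            g = build_gallery(q, s, ids, fams)
            assert len(g) == 9 and q not in g and g[0] == s

    def test_larger_family_members_excluded(self):
        ids = ["a1", "a2", "a3"] + [f"b{k}" for k in range(6)]
        fams = ["A"] * 3 + [f"B{k}" for k in range(6)]
        g = build_gallery("a1", "a2", ids, fams)
        assert "a3" not in g and len(g) == 7  # N - 2

    def test_experiment_count_is_twice_unique_pairs(self, sib_identification, strong_study):
        fam = strong_study["sib"].family_id
        sizes = fam.value_counts().to_numpy()
        n_pairs = int(np.sum(sizes * (sizes - 1) // 2))
        assert sib_identification.n_experiments == 2 * n_pairs


class TestIdentify:
    def _gallery(self):
        return {
            "sib": np.array([0.5, 0.0]),
            "o1": np.array([0.3, 0.0]),
            "o2": np.array([0.7, 0.0]),
        }

    def test_identical_sibling_rank_one(self):
        g = {"sib": np.array([1.0, 1.0]), "o": np.array([3.0, 0.0])}
        rank, _, _ = identify(np.array([1.0, 1.0]), g, "sib", "ED")
        assert rank == 1

    def test_enumerated_rank(self):
        rank, value, tied = identify(np.zeros(2), self._gallery(), "sib", "ED")
        assert rank == 2 and value == pytest.approx(0.5) and not tied

    def test_all_tied_pessimistic_rank(self):
        g = {k: np.array([1.0, 0.0]) for k in ("sib", "o1", "o2")}
        rank, _, tied = identify(np.array([2.0, 0.0]), g, "sib", "ED")
        assert rank == 3 and tied


class TestCMC:
    def test_all_rank_one(self):
        df = pd.DataFrame({"rank": [1] * 20, "gallery_size": [150] * 20})
        curve = cmc(df)
        assert curve.rate_at(1.0) == 1.0

    def test_monotone_and_saturates(self, sib_identification):
        curve = cmc(sib_identification)
        assert (np.diff(curve.rate) >= 0).all()
        assert curve.rate[-1] == 1.0

    def test_random_similarity_within_diagonal_envelope(self):
        # 500 experiments with uniformly random similarity: the CMC must
        # hug the diagonal within the 99% binomial envelope
        rng = np.random.default_rng(11)
        n_exp, gallery = 500, 200
        ranks = rng.integers(1, gallery + 1, size=n_exp)
        df = pd.DataFrame({"rank": ranks, "gallery_size": gallery})
        ks = np.array([1.0, 5.0, 10.0, 20.0, 50.0])
        curve = cmc(df, k_grid=ks)
        lo, hi = random_cmc_envelope(n_exp, ks)
        assert ((curve.rate >= lo) & (curve.rate <= hi)).all()

    def test_ranking_invariant_under_monotone_transform(self, strong_study, sib_scores, fullface_space):
        # cosine distance and angle give identical rankings
        sib = strong_study["sib"]
        res_angle = run_identification(
            sib_scores, sib.individual_ids, sib.family_id, "MA", fullface_space.sigma
        )
        normalized = sib_scores / fullface_space.sigma
        unit = normalized / np.linalg.norm(normalized, axis=1, keepdims=True)
        res_cos = run_identification(
            # ED on unit vectors = chord length, a monotone map of the angle
            unit, sib.individual_ids, sib.family_id, "ED",
        )
        assert np.array_equal(
            res_angle.experiments["rank"].to_numpy(),
            res_cos.experiments["rank"].to_numpy(),
        )


class TestGalleryResampling:
    def _toy(self, seed=0, n_fam=30, n_unrel=120, d=4):
        rng = np.random.default_rng(seed)
        ids = [f"s{k}" for k in range(2 * n_fam)] + [f"u{k}" for k in range(n_unrel)]
        fams = [f"f{k // 2}" for k in range(2 * n_fam)] + [f"uf{k}" for k in range(n_unrel)]
        feats = rng.normal(size=(len(ids), d))
        return feats, ids, fams

    def test_full_size_reproduces_unsubsampled(self):
        feats, ids, fams = self._toy()
        full = len(ids) - 1
        res = run_identification(feats, ids, fams, metric="ED")
        curve = cmc(res, k_grid=np.array([50.0]))
        df = gallery_size_resampling(
            feats, ids, fams, sizes=[full], n_repeats=2, metric="ED", k_pct=50.0
        )
        assert df["mean_rate"].iloc[0] == pytest.approx(curve.rate[0])
        assert df["min_rate"].iloc[0] == df["max_rate"].iloc[0]

    def test_random_rank1_rate_tracks_inverse_size(self):
        feats, ids, fams = self._toy(seed=5)
        # rank-1 (absolute) rate under random features ~ 1/size: k_pct =
        # 100/size admits exactly rank 1
        r10 = gallery_size_resampling(
            feats, ids, fams, sizes=[10], n_repeats=40,
            metric="ED", k_pct=100.0 / 10, seed=3,
        )["mean_rate"].iloc[0]
        r40 = gallery_size_resampling(
            feats, ids, fams, sizes=[40], n_repeats=40,
            metric="ED", k_pct=100.0 / 40, seed=3,
        )["mean_rate"].iloc[0]
        assert abs(r10 - 0.1) < 0.05
        assert abs(r40 - 0.025) < 0.02
        assert r10 > r40

    def test_deterministic_under_seed(self):
        feats, ids, fams = self._toy(seed=6, n_fam=8, n_unrel=30)
        kw = dict(sizes=[12], n_repeats=5, metric="ED", k_pct=10.0, seed=9)
        df1 = gallery_size_resampling(feats, ids, fams, **kw)
        df2 = gallery_size_resampling(feats, ids, fams, **kw)
        pd.testing.assert_frame_equal(df1, df2)

    def test_too_small_size_rejected(self):
        feats, ids, fams = self._toy(n_fam=3, n_unrel=5)
        with pytest.raises(ValueError):
            gallery_size_resampling(feats, ids, fams, sizes=[1], metric="ED")
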