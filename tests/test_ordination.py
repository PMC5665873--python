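import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from exfoliomics import ordination
from exfoliomics.ordination import anosim, bray_curtis, mds_leading_logfc, nmds


def square_dist(points):
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(points))
    return pd.DataFrame(d)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        abund = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        d = bray_curtis(abund)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        abund = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        assert bray_curtis(abund).loc["a", "b"] == 1.0

    def test_arithmetic_example(self):
        abund = pd.DataFrame({"x": [2, 2], "y": [1, 1]})
        assert bray_curtis(abund).loc["x", "y"] == pytest.approx(2 / 6)

    def test_all_zero_sample_rejected(self):
        abund = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(abund)

    def test_negative_rejected(self):
        abund = pd.DataFrame({"a": [1, -2], "b": [1, 1]})
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(abund)

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=100), min_size=4, max_size=4),
            min_size=3,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, rows):
        abund = pd.DataFrame(np.array(rows).T)
        d = bray_curtis(abund).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 1))


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = np.vstack([np.zeros((3, 2)), np.full((3, 2), 100.0)])
        pts += np.random.default_rng(0).normal(scale=0.1, size=pts.shape)
        res = anosim(square_dist(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=1)
        assert res.r_statistic == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="< 2 members"):
            anosim(square_dist(pts), ["a", "a", "a", "b"])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            pts = rng.normal(size=(6, 3))
            pts[3:] += 1.5
            dist = square_dist(pts)
            labels = ["a"] * 3 + ["b"] * 3
            res = anosim(dist, labels, n_perm="exact")

            # independent brute force over all label orderings
            d = dist.to_numpy()
            iu = np.triu_indices(6, k=1)
            ranks = scipy.stats.rankdata(d[iu])
            m = len(ranks)

            def r_stat(lab):
                lab = np.array(lab)
                within = lab[iu[0]] == lab[iu[1]]
                return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

            all_r = [r_stat(p) for p in set(itertools.permutations(labels))]
            expected_p = np.mean([r >= res.r_statistic - 1e-12 for r in all_r])
            assert res.p_value == pytest.approx(expected_p)
            assert res.r_statistic == pytest.approx(r_stat(labels))

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(8, 3))
        dist = square_dist(pts)
        labels = ["a"] * 4 + ["b"] * 4
        r1 = anosim(dist, labels, n_perm=9, seed=0).r_statistic
        r2 = anosim(dist**2, labels, n_perm=9, seed=0).r_statistic
        assert r1 == pytest.approx(r2)

    def test_null_p_roughly_uniform_quick(self):
        rng = np.random.default_rng(12)
        ps = []
        for i in range(40):
            pts = rng.normal(size=(10, 4))
            res = anosim(square_dist(pts), ["a"] * 5 + ["b"] * 5, n_perm=99, seed=i)
            ps.append(res.p_value)
        assert 0.3 < np.mean(ps) < 0.7

    def test_matches_skbio_r_statistic(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(21)
        pts = rng.normal(size=(8, 3))
        pts[4:] += 1.0
        dist = square_dist(pts)
        labels = ["a"] * 4 + ["b"] * 4
        ours = anosim(dist, labels, n_perm=99, seed=0)
        theirs = sk_anosim(
            skbio.DistanceMatrix(dist.to_numpy()), grouping=labels, permutations=99
        )
        assert ours.r_statistic == pytest.approx(theirs["test statistic"])


class TestNMDS:
    def test_planar_points_low_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        coords, stress, _ = nmds(square_dist(pts), k=2, seed=0, n_restarts=5)
        assert stress < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        dist = square_dist(rng.normal(size=(8, 4)))
        a = nmds(dist, seed=3, n_restarts=3)
        b = nmds(dist, seed=3, n_restarts=3)
        assert np.array_equal(a[0].to_numpy(), b[0].to_numpy())
        assert a[1] == b[1]

    def test_full_dimension_near_zero_stress(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 5))
        coords, stress, _ = nmds(square_dist(pts), k=5, seed=0, n_restarts=3)
        assert stress < 1e-3

    def test_k_too_large_rejected(self):
        dist = square_dist(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="k must be"):
            nmds(dist, k=4)

    def test_stress_trace_non_increasing(self):
        # drive the single-start loop directly and watch the stress sequence
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 6))
        dist = square_dist(pts).to_numpy()
        iu = np.triu_indices(10, k=1)
        diss = dist[iu]
        order = np.argsort(diss, kind="stable")
        conf = rng.normal(size=(10, 2))
        stresses = []
        for _ in range(50):
            conf, stress, _ = ordination._nmds_single(
                conf, diss, order, iu, 10, max_iter=1, tol=0.0
            )
            stresses.append(stress)
        assert all(b <= a + 1e-12 for a, b in zip(stresses, stresses[1:]))


class TestLeadingLogFCMDS:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=20)
        logcpm = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=20)})
        coords, dist = mds_leading_logfc(logcpm, top_n=5)
        assert dist.loc["a", "b"] == 0.0
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-6)

    def test_top_n_all_equals_rms_oracle(self):
        rng = np.random.default_rng(7)
        logcpm = pd.DataFrame(rng.normal(size=(15, 4)))
        _, dist = mds_leading_logfc(logcpm, top_n=15)
        a, b = logcpm.iloc[:, 0], logcpm.iloc[:, 1]
        expected = np.sqrt(((a - b) ** 2).mean())
        assert dist.iloc[0, 1] == pytest.approx(expected)

    def test_group_separation(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(30, 8)) * 0.1
        base[:10, 4:] += 3.0  # group 2 shifted on 10 genes
        logcpm = pd.DataFrame(base)
        _, dist = mds_leading_logfc(logcpm, top_n=10)
        d = dist.to_numpy()
        within = np.concatenate([d[:4, :4][np.triu_indices(4, 1)],
                                 d[4:, 4:][np.triu_indices(4, 1)]])
        between = d[:4, 4:].ravel()
        assert between.min() > within.max()

    def test_top_n_clipped_with_warning(self):
        logcpm = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="using all genes"):
            mds_leading_logfc(logcpm, top_n=50)
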