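"""Normalized-ReliefF fusion: normalization, weighting, selection."""

import numpy as np
import pytest

from neurofuse.containers import FeatureLabel, FeatureMatrix
from neurofuse.fusion import (
    ReliefFConfig,
    fuse_concat,
    minmax_normalize,
    normalized_relieff,
    relieff_weights,
    select_features,
)
from neurofuse.synthetic import simulate_feature_tables


def make_fm(values, y=None, modality="eeg", prefix="f"):
    values = np.asarray(values, dtype=np.float64)
    labels = [FeatureLabel(modality, f"{prefix}{j}", "test", str(j))
              for j in range(values.shape[1])]
    return FeatureMatrix(values, labels, y=y)


def naive_relieff(values, y, k, seed=None, m="all"):
    """Reference O(m n^2 p) ReliefF: explicit loops for distances/neighbors."""
    values = np.asarray(values, float)
    y = np.asarray(y)
    n, p = values.shape
    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    span = values.max(axis=0) - values.min(axis=0)
    span = np.where(span > 0, span, np.inf)
    z = values / span
    omega = np.zeros(p)
    probes = (np.arange(n) if m == "all"
              else np.random.default_rng(seed).choice(n, size=m, replace=m > n))
    for s in probes:
        dists = np.array([np.sum(np.abs(z[s] - z[j])) for j in range(n)])
        for c in classes:
            members = [j for j in range(n) if y[j] == c and j != s]
            members.sort(key=lambda j: (dists[j], j))
            nearest = members[:k]
            contrib = np.abs(z[nearest] - z[s]).sum(axis=0)
            if c == y[s]:
                omega -= contrib
            else:
                omega += priors[c] / (1 - priors[y[s]]) * contrib
    return omega / (len(probes) * k)


@pytest.fixture
def six_sample_fixture():
    # feature 0 separates the classes perfectly; feature 1 is constant
    values = np.array(
        [[0.0, 5.0], [0.1, 5.0], [0.2, 5.0],
         [1.0, 5.0], [1.1, 5.0], [1.2, 5.0]]
    )
    y = np.array(["neutral"] * 3 + ["preferred"] * 3)
    return make_fm(values, y=y)


class TestMinMaxNormalize:
    def test_simple_column(self):
        fm = make_fm(np.array([[2.0], [4.0], [6.0]]))
        out = minmax_normalize(fm)
        assert out.values[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        fm = make_fm(np.array([[3.0, 1.0], [3.0, 2.0]]))
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(fm)
        assert np.all(out.values[:, 0] == 0.0)

    def test_idempotent(self, rng):
        fm = make_fm(rng.uniform(-5, 5, size=(20, 4)))
        once = minmax_normalize(fm)
        twice = minmax_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_held_out_reuse_of_training_stats(self, rng):
        train = make_fm(rng.uniform(0, 10, size=(20, 3)))
        fitted = minmax_normalize(train)
        test = make_fm(rng.uniform(0, 10, size=(5, 3)))
        out = minmax_normalize(test, stats=fitted.minmax_stats)
        mins, maxs = fitted.minmax_stats
        assert np.allclose(out.values, (test.values - mins) / (maxs - mins))


class TestFuseConcat:
    def test_column_concatenation(self, rng):
        y = np.array(["neutral", "preferred"] * 5)
        a = make_fm(rng.standard_normal((10, 4)), y=y, modality="eeg")
        b = make_fm(rng.standard_normal((10, 3)), y=y, modality="fnirs")
        fused = fuse_concat(a, b)
        assert fused.shape == (10, 7)
        assert fused.column_names()[:4] == a.column_names()

    def test_row_mismatch_named(self, rng):
        a = make_fm(rng.standard_normal((10, 2)))
        b = make_fm(rng.standard_normal((9, 2)), modality="fnirs")
        with pytest.raises(ValueError, match="10.*9"):
            fuse_concat(a, b)

    def test_label_mismatch_rejected(self, rng):
        a = make_fm(rng.standard_normal((4, 2)),
                    y=np.array(["neutral"] * 2 + ["preferred"] * 2))
        b = make_fm(rng.standard_normal((4, 2)),
                    y=np.array(["preferred"] * 2 + ["neutral"] * 2),
                    modality="fnirs")
        with pytest.raises(ValueError, match="labels disagree"):
            fuse_concat(a, b)

    def test_empty_matrix_passthrough(self, rng):
        a = make_fm(rng.standard_normal((5, 3)))
        empty = make_fm(np.empty((5, 0)), modality="fnirs")
        assert fuse_concat(a, empty) is a

    def test_collision_rejected(self, rng):
        a = make_fm(rng.standard_normal((5, 2)))
        b = make_fm(rng.standard_normal((5, 2)))
        with pytest.raises(ValueError, match="collision"):
            fuse_concat(a, b)


class TestReliefFWeights:
    def test_constant_feature_weight_exactly_zero(self, six_sample_fixture):
        w = relieff_weights(six_sample_fixture, ReliefFConfig(k=1))
        assert w.omega[1] == 0.0

    def test_six_sample_hand_trace(self, six_sample_fixture):
        w = relieff_weights(six_sample_fixture, ReliefFConfig(k=1, m="all"))
        ref = naive_relieff(six_sample_fixture.values, six_sample_fixture.y, k=1)
        assert np.array_equal(w.omega, ref)
        # hand trace: every hit diff is 0.1/1.2, every miss diff is >= 0.8/1.2
        hit = 0.1 / 1.2
        miss = np.mean([1.0, 0.9, 0.8, 0.8, 0.9, 1.0]) / 1.2
        assert w.omega[0] == pytest.approx(miss - hit, abs=1e-12)
        assert w.omega[0] > 0

    def test_matches_naive_reference_bit_exact(self, rng):
        for n, p in ((30, 5), (200, 50)):
            half = n // 2
            values = rng.standard_normal((n, p))
            y = np.array(["neutral"] * half + ["preferred"] * (n - half))
            values[y == "preferred", :3] += 1.0
            fm = make_fm(values, y=y)
            for m in ("all", 17):
                cfg = ReliefFConfig(k=5, m=m, seed=99)
                w = relieff_weights(fm, cfg)
                ref = naive_relieff(values, y, k=5, seed=99, m=m)
                assert np.array_equal(w.omega, ref)

    def test_label_independent_feature_has_null_weight(self):
        means = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            values = r.standard_normal((400, 1))
            y = np.array(["neutral"] * 200 + ["preferred"] * 200)
            fm = make_fm(values, y=y)
            w = relieff_weights(fm, ReliefFConfig(k=10, m=64, seed=seed))
            means.append(w.omega[0])
        assert abs(np.mean(means)) < 0.02

    def test_duplicated_columns_get_equal_weights(self, rng):
        values = rng.standard_normal((40, 2))
        values[:, 1] = values[:, 0]
        y = np.array(["neutral", "preferred"] * 20)
        w = relieff_weights(make_fm(values, y=y), ReliefFConfig(k=3))
        assert w.omega[0] == w.omega[1]

    def test_weight_scale_invariance_after_normalization(self, rng):
        values = rng.standard_normal((60, 4))
        y = np.array(["neutral", "preferred"] * 30)
        fm1 = minmax_normalize(make_fm(values, y=y))
        scaled = values.copy()
        scaled[:, 2] *= 1e6
        fm2 = minmax_normalize(make_fm(scaled, y=y))
        w1 = relieff_weights(fm1, ReliefFConfig(k=5))
        w2 = relieff_weights(fm2, ReliefFConfig(k=5))
        assert np.allclose(w1.omega, w2.omega, atol=1e-12)

    def test_separating_feature_approaches_plus_one(self, rng):
        # class separation nearly equal to the feature range -> omega -> +1
        n = 100
        y = np.array(["neutral"] * 50 + ["preferred"] * 50)
        values = np.concatenate([
            rng.uniform(0, 1e-3, size=(50, 1)),
            1.0 + rng.uniform(0, 1e-3, size=(50, 1)),
        ])
        w = relieff_weights(make_fm(values, y=y), ReliefFConfig(k=5))
        assert w.omega[0] > 0.99

    def test_small_class_rejected(self):
        y = np.array(["neutral"] * 3 + ["preferred"] * 10)
        fm = make_fm(np.random.default_rng(0).standard_normal((13, 2)), y=y)
        with pytest.raises(ValueError, match="smaller k"):
            relieff_weights(fm, ReliefFConfig(k=5))


class TestSelectFeatures:
    def test_minus_infinity_threshold_is_identity(self, six_sample_fixture):
        cfg = ReliefFConfig(k=1, threshold=-np.inf)
        w = relieff_weights(six_sample_fixture, cfg)
        out = select_features(six_sample_fixture, w, cfg)
        assert out.column_names() == six_sample_fixture.column_names()

    def test_zero_threshold_drops_constant_feature(self, six_sample_fixture):
        cfg = ReliefFConfig(k=1, threshold=0.0)
        w = relieff_weights(six_sample_fixture, cfg)
        out = select_features(six_sample_fixture, w, cfg)
        assert out.n_features == 1
        assert out.labels[0] == six_sample_fixture.labels[0]

    def test_top_n_takes_argmax(self, six_sample_fixture):
        cfg = ReliefFConfig(k=1, mode="top_n", n_keep=1)
        w = relieff_weights(six_sample_fixture, cfg)
        out = select_features(six_sample_fixture, w, cfg)
        assert out.labels[0] == six_sample_fixture.labels[0]

    def test_n_keep_too_large_rejected(self, six_sample_fixture):
        cfg = ReliefFConfig(k=1, mode="top_n", n_keep=10)
        w = relieff_weights(six_sample_fixture, cfg)
        with pytest.raises(ValueError, match="n_keep"):
            select_features(six_sample_fixture, w, cfg)


class TestNormalizedReliefF:
    def test_composition_equals_staged_calls(self, rng):
        y = np.array(["neutral", "preferred"] * 20)
        eeg = make_fm(rng.standard_normal((40, 6)), y=y, modality="eeg")
        fni = make_fm(rng.standard_normal((40, 4)), y=y, modality="fnirs")
        cfg = ReliefFConfig(k=3)
        res = normalized_relieff(eeg, fni, cfg)
        fused = fuse_concat(minmax_normalize(eeg), minmax_normalize(fni))
        w = relieff_weights(fused, cfg)
        staged = select_features(fused, w, cfg)
        assert np.array_equal(res.selected.values, staged.values)
        assert np.array_equal(res.weights.omega, w.omega)

    def test_scale_invariant_selection(self, rng):
        y = np.array(["neutral", "preferred"] * 30)
        base_eeg = rng.standard_normal((60, 5))
        base_fni = rng.standard_normal((60, 5))
        base_fni[:, 0] += 2.0 * (y == "preferred")
        cfg = ReliefFConfig(k=5)
        eeg = make_fm(base_eeg, y=y, modality="eeg")
        sel1 = normalized_relieff(
            eeg, make_fm(base_fni, y=y, modality="fnirs"), cfg
        ).selected.column_names()
        sel2 = normalized_relieff(
            eeg, make_fm(base_fni * 1e6, y=y, modality="fnirs"), cfg
        ).selected.column_names()
        assert sel1 == sel2

    def test_informative_features_dominate_top10(self):
        hits = []
        for seed in range(20):
            eeg_fm, fni_fm = simulate_feature_tables(
                seed=seed, n_samples=400, n_informative=10, n_noise=90
            )
            res = normalized_relieff(eeg_fm, fni_fm, ReliefFConfig(k=10))
            order = np.argsort(-res.weights.omega)[:10]
            fams = [res.weights.labels[i].family for i in order]
            hits.append(sum(f == "informative" for f in fams))
        assert np.median(hits) >= 8
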