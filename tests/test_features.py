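import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actilabel.features import (
    CHANNEL_FEATURES,
    FeatureMatrix,
    SensorRecording,
    channel_features,
    extract_feature_matrix,
    reduce_dimensions,
    segment_windows,
    triaxial_features,
    window_features,
)


def rec(n, fs=100.0, n_channels=1, labels=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return SensorRecording(
        channels={f"c{i}": rng.standard_normal(n) for i in range(n_channels)},
        sampling_rate=fs,
        labels=labels,
    )


class TestSegmentWindows:
    def test_two_second_window_quarter_overlap(self):
        # 10 s at 100 Hz: starts every 1.5 s -> 0, 1.5, ..., 7.5
        w = segment_windows(rec(1000), 2.0, 0.25)
        assert [a for a, _ in w] == [0, 150, 300, 450, 600, 750]
        assert all(b - a == 200 for a, b in w)

    def test_recording_of_exactly_one_window(self):
        assert segment_windows(rec(200), 2.0, 0.5) == [(0, 200)]

    def test_zero_overlap_is_contiguous(self):
        w = segment_windows(rec(1000), 2.0, 0.0)
        assert w == [(i * 200, (i + 1) * 200) for i in range(5)]

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="too short"):
            segment_windows(rec(150), 2.0, 0.25)

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            segment_windows(rec(1000), 2.0, 1.0)

    @given(
        n_windows=st.integers(1, 30),
        w=st.integers(10, 100),
        stride=st.integers(5, 100),
        slack=st.integers(0, 4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_formula(self, n_windows, w, stride, slack):
        """floor((T - w)/stride) + 1 windows for any valid geometry."""
        stride = min(stride, w)  # overlap fraction must lie in [0, 1)
        n = w + (n_windows - 1) * stride + min(slack, stride - 1)
        fs = 1.0
        windows = segment_windows(rec(n, fs=fs), float(w), 1.0 - stride / w)
        # guard: rounding of the overlap fraction must reproduce the stride
        assert windows[1][0] - windows[0][0] == stride if len(windows) > 1 else True
        assert len(windows) == (n - w) // stride + 1


class TestChannelFeatures:
    def names(self):
        return dict(zip(CHANNEL_FEATURES, channel_features(np.array([1.0, 2, 3]))))

    def test_hand_arithmetic_on_simple_window(self):
        f = self.names()
        assert f["mean"] == 2
        assert f["variance"] == 1
        assert f["std"] == 1
        assert f["peak_amplitude"] == 1
        assert f["peak_to_peak"] == 2
        assert f["range"] == 2
        assert f["energy"] == 14
        assert f["mad"] == pytest.approx(2 / 3)
        assert f["median"] == 2
        assert f["maximum"] == 3
        assert f["minimum"] == 1
        assert f["rms"] == pytest.approx(np.sqrt(14 / 3))

    def test_zero_rate_counts_zero_valued_samples(self):
        f = dict(zip(CHANNEL_FEATURES, channel_features(np.array([0.0, 1, 0, 2]))))
        assert f["zero_rate"] == 0.5

    def test_sign_change_rate_is_separate_and_optional(self):
        s = np.array([1.0, -1, 1, -1])
        vals = channel_features(s, include_sign_change_rate=True)
        assert len(vals) == len(CHANNEL_FEATURES) + 1
        assert vals[-1] == pytest.approx(3 / 4)

    def test_constant_window_has_zero_shape_moments(self):
        f = dict(zip(CHANNEL_FEATURES, channel_features(np.full(10, 3.0))))
        assert f["skewness"] == 0
        assert f["kurtosis"] == 0
        assert f["std"] == 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            channel_features(np.array([1.0]))

    def test_matches_straight_line_reimplementation(self, rng):
        """Every feature agrees with an independent plain-loop oracle."""

        def oracle(s):
            n = len(s)
            mu = sum(s) / n
            var = sum((x - mu) ** 2 for x in s) / (n - 1)
            sd = var**0.5
            skew = (sum((x - mu) ** 3 for x in s) / n) / sd**3 if sd else 0.0
            kurt = (sum((x - mu) ** 4 for x in s) / n) / sd**4 if sd else 0.0
            p = [(abs(x) + 1e-12) for x in s]
            tot = sum(p)
            p = [x / tot for x in p]
            return {
                "peak_amplitude": max(s) - mu,
                "median": float(np.median(s)),
                "mean": mu,
                "maximum": max(s),
                "minimum": min(s),
                "variance": var,
                "std": sd,
                "rms": (sum(x**2 for x in s) / n) ** 0.5,
                "peak_to_peak": max(s) - min(s),
                "zero_rate": sum(x == 0 for x in s) / n,
                "entropy": -sum(q * np.log(q) for q in p),
                "skewness": skew,
                "kurtosis": kurt,
                "energy": sum(x**2 for x in s),
                "range": max(s) - min(s),
                "mad": sum(abs(x - mu) for x in s) / n,
            }

        for _ in range(100):
            s = rng.standard_normal(rng.integers(2, 40))
            got = dict(zip(CHANNEL_FEATURES, channel_features(s)))
            want = oracle(list(s))
            for name in CHANNEL_FEATURES:
                assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-12), name


class TestTriaxialFeatures:
    def test_unit_vector_magnitude(self):
        mag, _ = triaxial_features(np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert mag == 1.0

    def test_angle_is_max_elevation(self):
        sx = np.array([1.0, 1.0])
        sy = np.zeros(2)
        sz = np.array([0.0, 1.0])
        _, ang = triaxial_features(sx, sy, sz)
        assert ang == pytest.approx(np.pi / 4)

    def test_vertical_sample_hits_arctan_limit(self):
        _, ang = triaxial_features(np.zeros(1), np.zeros(1), np.array([2.0]))
        assert ang == pytest.approx(np.pi / 2)
        _, ang = triaxial_features(np.zeros(1), np.zeros(1), np.array([-2.0]))
        assert ang == pytest.approx(-np.pi / 2)

    def test_window_features_appends_triaxial(self):
        s = np.array([1.0, 2, 3])
        v = window_features(s, triaxial=(s, s, s))
        assert len(v) == len(CHANNEL_FEATURES) + 2


class TestExtractFeatureMatrix:
    def test_channel_permutation_equivariance(self, rng):
        a, b = rng.standard_normal(400), rng.standard_normal(400)
        r1 = SensorRecording({"a": a, "b": b}, 100.0)
        r2 = SensorRecording({"b": b, "a": a}, 100.0)
        F1 = extract_feature_matrix(r1)
        F2 = extract_feature_matrix(r2)
        perm = [F2.feature_names.index(n) for n in F1.feature_names]
        np.testing.assert_allclose(F1.X, F2.X[:, perm])

    def test_window_label_majority_with_tie_to_first(self):
        labels = np.array(["a"] * 100 + ["b"] * 100)  # exact tie inside the window
        r = rec(200, labels=labels)
        F = extract_feature_matrix(r, 2.0, 0.0)
        assert list(F.labels) == ["a"]

    def test_no_nan_inf_and_temporal_order(self, rng):
        r = rec(1000, n_channels=2, rng=rng)
        F = extract_feature_matrix(r)
        assert np.all(np.isfinite(F.X))
        assert np.all(np.diff(F.window_start) > 0)

    def test_csv_round_trip(self, rng, tmp_path):
        F = extract_feature_matrix(rec(600, rng=rng))
        F.labels = None
        p = tmp_path / "f.csv"
        F.to_csv(p)
        G = FeatureMatrix.from_csv(p)
        np.testing.assert_allclose(F.X, G.X)
        assert G.feature_names == F.feature_names


class TestReduceDimensions:
    def test_pass_through_is_identity(self, rng):
        F = FeatureMatrix(rng.standard_normal((20, 5)), [f"f{i}" for i in range(5)])
        G = reduce_dimensions(F, method="none")
        np.testing.assert_array_equal(F.X, G.X)

    def test_umap_shape_and_determinism(self, rng):
        F = FeatureMatrix(rng.standard_normal((50, 10)), [f"f{i}" for i in range(10)])
        A = reduce_dimensions(F, n_components=2, seed=7)
        B = reduce_dimensions(F, n_components=2, seed=7)
        assert A.X.shape == (50, 2)
        np.testing.assert_array_equal(A.X, B.X)

    def test_too_many_components_rejected(self, rng):
        F = FeatureMatrix(rng.standard_normal((20, 5)), [f"f{i}" for i in range(5)])
        with pytest.raises(ValueError):
            reduce_dimensions(F, n_components=5)
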