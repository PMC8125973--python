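import numpy as np
import pytest

from _oracles import naive_series_stats
from phasicpain import fad
from phasicpain.fad import (
    DESCRIPTOR_LENGTH,
    STAT_NAMES,
    derivatives,
    fad_descriptor,
    feature_names,
    sample_features,
    series_stats,
)


class TestDerivatives:
    def test_linear_ramp(self):
        x = 0.7 * np.arange(10)
        d1, d2 = derivatives(x)
        np.testing.assert_allclose(d1, 0.7)
        np.testing.assert_allclose(d2, 0.0, atol=1e-12)

    def test_constant(self):
        d1, d2 = derivatives(np.full(8, 3.0))
        assert (d1 == 0).all() and (d2 == 0).all()

    def test_quadratic_second_derivative(self):
        x = np.arange(12, dtype=float) ** 2
        _, d2 = derivatives(x)
        np.testing.assert_allclose(d2, 2.0)

    def test_fps_scaling(self):
        x = np.sin(np.linspace(0, 3, 50))
        d1_a, d2_a = derivatives(x, fps=1.0)
        d1_b, d2_b = derivatives(x, fps=25.0)
        np.testing.assert_allclose(d1_b, 25 * d1_a)
        np.testing.assert_allclose(d2_b, 625 * d2_a)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            derivatives(np.array([1.0, 2.0]))


class TestSeriesStats:
    def test_constant_series_closed_form(self):
        c = -1.5
        expected = [c, c, 0, c, c, 0, 0, c, c, 0, 0, abs(c), 0, c, 0, 0]
        np.testing.assert_allclose(series_stats(np.full(30, c)), expected,
                                   atol=1e-12)

    def test_triangle_series(self):
        stats = dict(zip(STAT_NAMES, series_stats(np.array([0.0, 1.0, 0.0]))))
        assert stats["max"] == 1.0
        assert stats["range"] == 1.0
        assert stats["rel_argmax"] == 0.5
        assert stats["n_peaks"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            series_stats(np.array([]))

    def test_matches_naive_oracle_on_random_series(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(1, 60)
            x = rng.normal(size=n)
            got = series_stats(x)
            want = naive_series_stats(list(x))
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


class TestDescriptor:
    def test_length_48(self):
        rng = np.random.default_rng(0)
        assert fad_descriptor(rng.random(175), fps=25).shape == (DESCRIPTOR_LENGTH,)
        assert DESCRIPTOR_LENGTH == 48

    def test_constant_series_derivative_blocks_zero(self):
        v = fad_descriptor(np.full(50, 2.0))
        np.testing.assert_allclose(v[16:], 0.0, atol=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.random(80)
        c = 3.7
        base = fad_descriptor(x, smoothing_window=1)
        shifted = fad_descriptor(x + c, smoothing_window=1)
        location = {"mean", "median", "min", "max", "p10", "p90", "area"}
        for i, stat in enumerate(STAT_NAMES):
            if stat in location:
                assert shifted[i] == pytest.approx(base[i] + c, abs=1e-9), stat
            elif stat == "rms":
                assert shifted[i] == pytest.approx(
                    np.sqrt(np.mean((x + c) ** 2)), abs=1e-9)
            else:
                assert shifted[i] == pytest.approx(base[i], abs=1e-9), stat
        # derivative levels are shift-invariant wholesale
        np.testing.assert_allclose(shifted[16:], base[16:], atol=1e-9)

    def test_relative_time_stats_fps_invariant(self):
        t_a = np.linspace(0, 7, 175)
        x = np.exp(-((t_a - 3) ** 2))
        i_argmax = list(STAT_NAMES).index("rel_argmax")
        v25 = fad_descriptor(x, fps=25)
        v1 = fad_descriptor(x, fps=1)
        assert v25[i_argmax] == pytest.approx(v1[i_argmax])


class TestSampleFeatures:
    def test_length_816_and_layout(self, strong_dataset):
        sample = next(iter(strong_dataset.samples.values()))
        vec = sample_features(sample)
        assert vec.shape == (816,)
        assert len(feature_names()) == 816
        # AU-major layout: block i corresponds to AU i's own descriptor
        for i in (0, 7, 16):
            block = fad_descriptor(sample.series[i], fps=sample.fps)
            np.testing.assert_allclose(vec[i * 48:(i + 1) * 48], block)

    def test_deterministic_on_zero_matrix(self):
        from phasicpain.synthetic import AUSeriesSample

        z = AUSeriesSample(subject_id=0, label="B", fps=25,
                           series=np.zeros((17, 100)))
        a, b = sample_features(z), sample_features(z)
        np.testing.assert_array_equal(a, b)

    def test_wrong_row_count_rejected(self):
        with pytest.raises(ValueError):
            fad.sample_features(
                type("S", (), {"series": np.zeros((5, 40)), "fps": 25})()
            )

    def test_response_changes_pain_au_stats(self, strong_dataset):
        # a pain sample differs from a baseline sample of the same subject
        # in the max/range/slope entries of pain-related AUs
        man = strong_dataset.manifest
        sid_pain = man[(man["class"] == "E3") & (man.subject_id == 0)].sample_id.iloc[0]
        sid_base = man[(man["class"] == "B") & (man.subject_id == 0)].sample_id.iloc[0]
        fp = sample_features(strong_dataset.sample(sid_pain))
        fb = sample_features(strong_dataset.sample(sid_base))
        from phasicpain.constants import AU_NAMES

        i_au4 = AU_NAMES.index("AU04")
        i_max = list(STAT_NAMES).index("max")
        i_range = list(STAT_NAMES).index("range")
        base = i_au4 * 48
        assert fp[base + i_max] > fb[base + i_max]
        assert fp[base + i_range] > fb[base + i_range]


def test_feature_matrix_round_trip(tmp_path, strong_dataset):
    samples = list(strong_dataset.samples.values())[:5]
    matrix = fad.feature_matrix(samples)
    path = tmp_path / "features.csv"
    fad.write_feature_matrix(matrix, path)
    back = fad.read_feature_matrix(path)
    np.testing.assert_allclose(back.to_numpy(), matrix.to_numpy(), rtol=1e-12)
    assert list(back.index) == list(matrix.index)
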