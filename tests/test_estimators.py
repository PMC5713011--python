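import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ecgnoise.estimators import (
    BaselineWanderEstimator,
    BlockStdNoiseEstimator,
    NoiseEstimate,
    PowerlineInterferenceEstimator,
    decompose,
    estimate_bw,
    estimate_pli,
    estimate_sdn,
    naive_amplitude,
)
from ecgnoise.exceptions import (
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)

FS = 200.0


def interior(x, frac=0.1):
    """Central portion of a series, excluding filter/spline transients."""
    n = len(x)
    return x[int(frac * n) : int((1 - frac) * n)]


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBaselineWander:
    def test_zero_signal_gives_zero_estimate(self):
        est = estimate_bw(np.zeros(2000), FS)
        np.testing.assert_allclose(est.values, 0.0)

    def test_linear_ramp_recovered_exactly_on_interior(self):
        t = np.arange(int(30 * FS)) / FS
        x = 0.1 * t
        est = estimate_bw(x, FS)
        np.testing.assert_allclose(interior(est.values), interior(x), atol=1e-6)

    def test_tracks_slow_sinusoidal_drift(self):
        # tolerance frozen from a numeric oracle run (interior RMSE 0.0044 mV)
        t = np.arange(int(30 * FS)) / FS
        x = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        est = estimate_bw(x, FS)
        assert rms(interior(est.values) - interior(x)) <= 0.05

    def test_too_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_bw(np.zeros(int(2 * 0.8 * FS)), FS)  # only 2 windows


class TestPowerlineInterference:
    def test_dc_passes_the_notch(self):
        est = estimate_pli(np.ones(4000), FS)
        assert np.abs(interior(est.values)).max() <= 1e-6

    def test_pure_mains_tone_fully_attributed_to_noise(self):
        t = np.arange(int(20 * FS)) / FS
        est = estimate_pli(np.sin(2 * np.pi * 50 * t), FS)
        assert rms(interior(est.values)) == pytest.approx(1 / np.sqrt(2), rel=0.10)

    def test_mixture_residual_correlates_with_mains_component(self):
        t = np.arange(int(20 * FS)) / FS
        mains = 0.2 * np.sin(2 * np.pi * 50 * t)
        est = estimate_pli(np.sin(2 * np.pi * 1 * t) + mains, FS)
        r = np.corrcoef(interior(est.values), interior(mains))[0, 1]
        assert r >= 0.95

    def test_out_of_band_tone_untouched(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 5 * t)
        est = estimate_pli(x, FS)
        assert rms(interior(est.values)) <= 0.05 * rms(interior(x))

    def test_notch_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_pli(np.zeros(1000), fs=80.0, f0=50.0)


class TestBlockStdNoise:
    def test_constant_signal_gives_zero(self):
        est = estimate_sdn(np.full(3000, 2.5), FS)
        np.testing.assert_allclose(est.values, 0.0)

    def test_alternating_signal_hand_value(self):
        # fs=4, 0.5 s blocks of {0, 2}: sample std sqrt(2), zero spread across blocks
        x = np.tile([0.0, 2.0], 40)
        est = estimate_sdn(x, fs=4.0)
        np.testing.assert_allclose(est.values, np.sqrt(2), rtol=1e-12)

    def test_gaussian_noise_level(self):
        # interval frozen from a 200-rep Monte-Carlo oracle (mean 1.135)
        rng = np.random.default_rng(42)
        est = estimate_sdn(rng.normal(0, 1, int(60 * FS)), FS)
        assert 1.0 <= est.values.mean() <= 1.2

    def test_block_shorter_than_two_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_sdn(np.zeros(100), fs=2.0, block_s=0.5)

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        est = estimate_sdn(rng.normal(0, 1, 5000) - 10, FS)
        assert est.values.min() >= 0

    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 2000)
        a = estimate_sdn(x, FS).values
        b = estimate_sdn(x + shift, FS).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSharedProperties:
    @pytest.mark.parametrize(
        "make",
        [
            lambda x: estimate_bw(x, FS),
            lambda x: estimate_pli(x, FS),
            lambda x: estimate_sdn(x, FS),
        ],
        ids=["bw", "pli", "sdn"],
    )
    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_positive_homogeneity(self, make, scale):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 2000) + np.sin(2 * np.pi * 0.3 * np.arange(2000) / FS)
        np.testing.assert_allclose(make(scale * x).values, scale * make(x).values, atol=1e-9)

    @pytest.mark.parametrize(
        "make",
        [
            lambda x: estimate_bw(x, FS),
            lambda x: estimate_pli(x, FS),
            lambda x: estimate_sdn(x, FS),
        ],
        ids=["bw", "pli", "sdn"],
    )
    @pytest.mark.parametrize("n", [500, 1931, 2000])
    def test_length_preserved(self, make, n):
        rng = np.random.default_rng(5)
        assert make(rng.normal(0, 1, n)).values.shape == (n,)

    def test_nan_input_rejected(self):
        x = np.zeros(2000)
        x[100] = np.nan
        with pytest.raises(ValidationError):
            estimate_pli(x, FS)


class TestSklearnInterface:
    @pytest.mark.parametrize(
        "transformer",
        [
            BaselineWanderEstimator(fs=FS),
            PowerlineInterferenceEstimator(fs=FS),
            BlockStdNoiseEstimator(fs=FS),
        ],
        ids=["bw", "pli", "sdn"],
    )
    def test_fit_transform_multilead_and_cloning(self, transformer):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (2000, 2))
        out = clone(transformer).fit(X).transform(X)
        assert out.shape == X.shape
        # column-wise: each lead transformed independently
        single = transformer.fit(X).transform(X[:, :1])
        np.testing.assert_allclose(out[:, 0], single[:, 0])

    def test_get_params_round_trip(self):
        est = PowerlineInterferenceEstimator(fs=128.0, f0=60.0, bandwidth=2.0)
        assert est.get_params() == {"fs": 128.0, "f0": 60.0, "bandwidth": 2.0}


class TestNaiveAmplitudeAndDecompose:
    def test_naive_amplitude_definition(self):
        est = NoiseEstimate(component="bw", values=np.array([-0.2, 0.1, 0.0]), fs=1.0)
        np.testing.assert_allclose(naive_amplitude(est), [0.2, 0.1, 0.0])

    def test_idempotent_on_non_negative(self):
        vals = np.abs(np.random.default_rng(1).normal(size=100))
        est = NoiseEstimate(component="sdn", values=vals, fs=1.0)
        np.testing.assert_array_equal(naive_amplitude(est), vals)

    def test_decompose_zero_lead(self, clean_record):
        from ecgnoise.io import ECGRecord

        rec = ECGRecord(samples=np.zeros((4000, 1)), fs=FS, lead_names=["z"])
        result = decompose(rec)
        for arr in (result.bw.values, result.pli.values, result.sdn.values, result.residual):
            np.testing.assert_allclose(arr, 0.0)

    def test_residual_identity(self, clean_record):
        result = decompose(clean_record)
        np.testing.assert_allclose(
            result.residual,
            clean_record.lead(0) - result.bw.values - result.pli.values,
        )

    def test_pure_mains_tone_residual_small(self):
        from ecgnoise.io import ECGRecord

        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        result = decompose(ECGRecord(samples=x[:, None], fs=FS, lead_names=["l"]))
        assert rms(interior(result.residual)) <= 0.15 * rms(interior(x))

    def test_ramp_plus_mains_residual_small(self):
        from ecgnoise.io import ECGRecord

        t = np.arange(int(20 * FS)) / FS
        x = 0.05 * t + 0.5 * np.sin(2 * np.pi * 50 * t)
        result = decompose(ECGRecord(samples=x[:, None], fs=FS, lead_names=["l"]))
        assert rms(interior(result.residual)) <= 0.20 * rms(interior(x))
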