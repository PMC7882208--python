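"""Band filtering, symmetric orthogonalization, envelopes, AEC, baselining."""

import logging

import numpy as np
import pytest

from aecnet import (
    band_filter,
    baseline_fractional_change,
    envelope,
    orthogonalize,
    windowed_aec,
)
from aecnet.connectivity import BANDS, aec_pipeline, design_band_fir

FS = 600.0


class TestBandFilter:
    def test_in_band_tone_preserved(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = band_filter(x, "alpha", FS)
        mid = y[3000:-3000]
        assert abs(np.abs(mid).max() - 1.0) < 0.05

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = band_filter(x, "theta", FS)
        assert np.abs(y[3000:-3000]).max() <= 0.10

    def test_octave_stopband_attenuation(self):
        # >= 40 dB one octave outside every canonical band
        from scipy import signal as sps

        for name, (lo, hi) in BANDS.items():
            taps = design_band_fir(name, FS)
            w, h = sps.freqz(taps, worN=8192, fs=FS)
            for f in (lo / 2, min(2 * hi, FS / 2 * 0.98)):
                gain = np.abs(h)[np.argmin(np.abs(w - f))]
                assert gain < 10 ** (-40 / 20), (name, f, gain)

    def test_zero_input_zero_output(self):
        assert np.all(band_filter(np.zeros((2, 3, 1000)), "beta", FS) == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_filter(np.zeros(1000), (200.0, 350.0), FS)


class TestOrthogonalize:
    def test_output_is_exactly_uncorrelated(self, rng):
        x = rng.standard_normal((12, 2000))
        y = orthogonalize(x)
        c = np.corrcoef(y)
        np.fill_diagonal(c, 0)
        assert np.abs(c).max() < 1e-8

    def test_orthogonal_input_is_fixed_point(self, rng):
        # already-orthogonal zero-mean series come back unchanged up to scaling
        g = rng.standard_normal((500, 5))
        q, _ = np.linalg.qr(g - g.mean(axis=0))
        x = (q * np.array([3.0, 1.0, 2.0, 0.5, 4.0])).T
        y = orthogonalize(x)
        for xi, yi in zip(x - x.mean(1, keepdims=True), y):
            cos = abs(np.dot(xi, yi)) / (np.linalg.norm(xi) * np.linalg.norm(yi))
            assert cos > 1 - 1e-8

    def test_leaked_copy_is_removed(self, rng):
        x = rng.standard_normal(2000)
        yind = rng.standard_normal(2000)
        z = 0.7 * x + 0.3 * rng.standard_normal(2000)
        out = orthogonalize(np.stack([x, yind, z]))
        assert abs(np.corrcoef(out[2], out[0])[0, 1]) < 1e-8

    def test_near_optimality_against_random_rotations(self, rng):
        # no randomly sampled orthogonal-series matrix (with its optimal
        # per-series scaling) comes closer to the input than the solution
        x = rng.standard_normal((3, 400))
        a = (x - x.mean(1, keepdims=True)).T
        y = orthogonalize(x)
        d_opt = np.linalg.norm(a - y.T)
        for _ in range(1000):
            q, _ = np.linalg.qr(rng.standard_normal((400, 3)))
            d = np.einsum("ts,ts->s", a, q)
            assert np.linalg.norm(a - q * d) >= d_opt - 1e-9

    def test_rank_deficiency_rejected(self, rng):
        x = rng.standard_normal((3, 500))
        x[2] = x[0]  # duplicate series
        with pytest.raises(ValueError, match="rank"):
            orthogonalize(x)

    def test_more_nodes_than_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            orthogonalize(rng.standard_normal((50, 20)))


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(0, 10, 1 / FS)
        env = envelope(3.0 * np.sin(2 * np.pi * 10 * t))
        assert abs(env[600:-600].mean() - 3.0) < 0.06  # within 2% away from edges

    def test_am_demodulation(self):
        t = np.arange(0, 20, 1 / FS)
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        env = envelope(mod * np.sin(2 * np.pi * 10 * t))
        sl = slice(600, -600)
        assert np.corrcoef(env[sl], mod[sl])[0, 1] > 0.98

    def test_zero_signal(self):
        assert np.all(envelope(np.zeros(100)) == 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.array([1.0, np.nan]))


class TestWindowedAEC:
    def _times(self, n):
        return np.arange(n) / FS

    def test_identical_envelopes_give_unit_aec(self, rng):
        e = np.abs(rng.standard_normal(3000)) + 0.1
        env = np.stack([e, e])[None]
        aec = windowed_aec(env, self._times(3000), [(0.0, 5.0)])[(0.0, 5.0)]
        assert aec[0, 1] > 0.999

    def test_null_envelope_correlations_are_small(self, rng):
        env = rng.standard_normal((1, 30, 3000))
        aec = windowed_aec(env, self._times(3000), [(0.0, 5.0)])[(0.0, 5.0)]
        iu = np.triu_indices(30, 1)
        assert np.mean(np.abs(aec[iu]) < 0.06) >= 0.95

    def test_symmetry_exact(self, rng):
        env = np.abs(rng.standard_normal((4, 8, 3000)))
        aec = windowed_aec(env, self._times(3000), [(0.0, 5.0)])[(0.0, 5.0)]
        np.testing.assert_array_equal(aec, aec.T)
        np.testing.assert_array_equal(np.diag(aec), 0.0)

    def test_zero_variance_envelope_handled(self, rng, caplog):
        env = np.abs(rng.standard_normal((1, 3, 3000)))
        env[0, 1] = 2.0  # constant envelope
        with caplog.at_level(logging.WARNING, logger="aecnet.connectivity"):
            aec = windowed_aec(env, self._times(3000), [(0.0, 5.0)])[(0.0, 5.0)]
        assert aec[0, 1] == 0.0 and aec[1, 2] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_short_window_rejected(self, rng):
        env = np.abs(rng.standard_normal((1, 2, 3000)))
        with pytest.raises(ValueError, match="10 samples"):
            windowed_aec(env, self._times(3000), [(0.0, 0.01)])


class TestBaselining:
    def test_no_change_is_zero(self):
        m = np.full((3, 3), 0.4)
        out, mask = baseline_fractional_change(m, m)
        np.testing.assert_array_equal(out, 0.0)
        assert not mask.any()

    def test_fractional_change_arithmetic(self):
        out, _ = baseline_fractional_change(np.array([[0.3]]), np.array([[0.2]]))
        assert abs(out[0, 0] - 0.5) < 1e-12

    def test_small_baseline_guarded_and_masked(self):
        out, mask = baseline_fractional_change(
            np.array([[0.2]]), np.array([[1e-9]]), eps=1e-3
        )
        assert abs(out[0, 0] - 200.0) < 1e-6
        assert mask[0, 0]

    def test_negative_baseline_sign_preserved(self):
        out, _ = baseline_fractional_change(np.array([[0.1]]), np.array([[-0.2]]))
        assert abs(out[0, 0] - (0.3 / -0.2)) < 1e-12


def test_planted_edge_ranks_in_top_five_percent():
    """With coupling 0.6 against a null background, the planted pair sits in
    the top 5% of edge AEC values for nearly every simulated subject."""
    from aecnet import SyntheticSpec, generate_source_dataset

    spec = SyntheticSpec(
        n_nodes=15,
        n_subjects_per_group=6,
        n_trials=12,
        band="alpha",
        planted_edges=((0, 1),),
        coupling_by_group={"A": 0.6, "B": 0.6},
        seed=8,
    )
    subjects, _ = generate_source_dataset(spec)
    n_top = 0
    iu = np.triu_indices(15, 1)
    for s in subjects:
        sel = s.epochs.select(condition="Social")
        env = envelope(band_filter(sel.data, "alpha", sel.fs))
        aec = windowed_aec(env, sel.times, [(0.0, 17.0)])[(0.0, 17.0)]
        rank = (aec[iu] >= aec[0, 1]).sum()  # 1 = top edge
        n_top += rank <= max(1, int(0.05 * len(iu[0])))
    assert n_top >= 0.9 * len(subjects)


def test_pipeline_output_shapes_and_masks(mixed_null_subject):
    subject, _ = mixed_null_subject
    res = aec_pipeline(subject.epochs, bands=["beta"], condition="Social")
    for w in res.windows:
        m = res.baselined["beta"][w]
        assert m.shape == (20, 20)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert res.guard_mask["beta"][w].shape == (20, 20)
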