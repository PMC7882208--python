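"""Ground-truth properties of the coupled-envelope generator."""

import numpy as np
import pytest

from aecnet import (
    SyntheticSpec,
    envelope,
    generate_behaviour,
    generate_group_aec,
    generate_sensor_dataset,
    generate_source_dataset,
    mixing_matrix,
    windowed_aec,
)
from aecnet.connectivity import band_filter
from aecnet.synthgen import MotionEvent


def small_spec(**kw):
    base = dict(
        n_nodes=6,
        n_subjects_per_group=1,
        n_trials=6,
        band="alpha",
        seed=0,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(planted_edges=((0, 0),)), "itself"),
            (dict(planted_edges=((0, 99),)), "invalid node"),
            (dict(coupling_by_group={"A": 1.0, "B": 0.2}), "\\[0, 1\\)"),
            (dict(mixing_strength=1.5), "mixing"),
            (dict(band=(100.0, 400.0)), "Nyquist"),
        ],
    )
    def test_invalid_specs_rejected(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            small_spec(**kw).validate()


def test_identical_seed_reproduces_identical_data():
    a, _ = generate_source_dataset(small_spec(seed=5))
    b, _ = generate_source_dataset(small_spec(seed=5))
    c, _ = generate_source_dataset(small_spec(seed=6))
    np.testing.assert_array_equal(a[0].epochs.data, b[0].epochs.data)
    assert not np.array_equal(a[0].epochs.data, c[0].epochs.data)


def _task_aec(subject, band="alpha"):
    sel = subject.epochs.select(condition="Social")
    env = envelope(band_filter(sel.data, band, sel.fs))
    return windowed_aec(env, sel.times, [(0.0, 17.0)])[(0.0, 17.0)]


def test_uncoupled_unmixed_envelopes_are_independent():
    # no planted coupling, no mixing: off-diagonal AEC near zero
    spec = small_spec(n_nodes=8, n_trials=25, coupling_by_group={"A": 0.0, "B": 0.0})
    subjects, _ = generate_source_dataset(spec)
    aec = _task_aec(subjects[0])
    iu = np.triu_indices(8, 1)
    assert abs(aec[iu].mean()) < 0.05


def test_planted_coupling_calibrated_to_target():
    # target 0.6 measured on > 120 s of task signal per replicate
    vals = []
    for seed in range(5):
        spec = small_spec(
            n_nodes=4,
            n_trials=16,  # 8 social trials x 17 s = 136 s
            planted_edges=((0, 1),),
            coupling_by_group={"A": 0.6, "B": 0.6},
            seed=seed,
        )
        subjects, _ = generate_source_dataset(spec)
        vals.append(_task_aec(subjects[0])[0, 1])
    assert 0.5 <= np.mean(vals) <= 0.7


def test_realized_truth_tracks_target():
    spec = small_spec(
        n_nodes=4,
        n_trials=40,  # 20 social trials: ~340 s of modulator signal
        planted_edges=((0, 1),),
        coupling_by_group={"A": 0.6, "B": 0.3},
        seed=2,
    )
    _, truth = generate_source_dataset(spec)
    assert abs(truth.realized_coupling["A"][(0, 1)] - 0.6) <= 0.1
    assert abs(truth.realized_coupling["B"][(0, 1)] - 0.3) <= 0.1


class TestMixing:
    def test_unit_diagonal_and_row_strength(self):
        m = mixing_matrix(20, 0.5)
        np.testing.assert_allclose(np.diag(m), 1.0)
        off = m - np.eye(20)
        np.testing.assert_allclose(np.linalg.norm(off, axis=1), 0.5)

    def test_mixing_induces_raw_envelope_correlation(self, mixed_null_subject):
        subject, truth = mixed_null_subject
        aec = _task_aec(subject, band="beta")
        iu = np.triu_indices(aec.shape[0], 1)
        assert aec[iu].max() > 0.3  # leakage visible before correction

    def test_leakage_is_zero_lag(self, mixed_null_subject):
        # cross-correlation between neighbouring (mixed) nodes peaks at lag 0
        subject, _ = mixed_null_subject
        x = band_filter(subject.epochs.data[0], "beta", 600.0)
        a, b = x[0] - x[0].mean(), x[1] - x[1].mean()
        lags = np.arange(-30, 31)
        xc = [np.dot(a[30 + l : len(a) - 30 + l], b[30 : len(b) - 30]) for l in lags]
        assert lags[int(np.argmax(np.abs(xc)))] == 0


class TestSensorTier:
    def test_snr_must_be_positive(self):
        subjects, _ = generate_source_dataset(small_spec())
        with pytest.raises(ValueError, match="SNR"):
            generate_sensor_dataset(subjects[0], n_channels=10, snr=0.0)

    def test_channel_count_checked(self):
        subjects, _ = generate_source_dataset(small_spec())
        with pytest.raises(ValueError, match="n_channels"):
            generate_sensor_dataset(subjects[0], n_channels=3, snr=10.0)

    def test_events_and_leadfield_attached(self):
        subjects, _ = generate_source_dataset(small_spec(n_trials=4))
        rec = generate_sensor_dataset(subjects[0], n_channels=12, snr=10.0, seed=3)
        assert len(rec.events) == 4
        assert rec.lead_field.shape == (12, 6)
        np.testing.assert_allclose(np.linalg.norm(rec.lead_field, axis=0), 1.0)

    def test_scripted_motion_flags_trial(self):
        from aecnet import epoch, reject_motion

        subjects, _ = generate_source_dataset(small_spec(n_trials=4))
        n_samp = subjects[0].epochs.data.shape[2]
        ev = [MotionEvent(start=2 * n_samp + 4000, stop=2 * n_samp + 7000,
                          translation_mm=(12.0, 0.0, 0.0))]
        rec = generate_sensor_dataset(
            subjects[0], n_channels=12, snr=10.0, motion_events=ev, seed=3
        )
        eps = epoch(rec)
        out, disp = reject_motion(eps, rec.fiducials)
        assert not out.kept[2] and out.reasons[2] == "motion"
        assert out.kept[[0, 1, 3]].all()

    def test_spike_artefact_flags_trial(self):
        from aecnet import reject_amplitude

        spec = small_spec(n_trials=12, artefact_rates={"spike": 1.0}, seed=9)
        subjects, truth = generate_source_dataset(spec)
        out = reject_amplitude(subjects[0].epochs, threshold_ft=2500.0)
        assert set(np.nonzero(~out.kept)[0]) == set(truth.spike_trials[subjects[0].subject_id])
        assert (~out.kept).any()


class TestBehaviour:
    def test_noiseless_unit_slope_returns_rounded_strengths(self):
        strengths = np.array([0.2, 1.6, 2.5, 3.49])
        counts = generate_behaviour(
            strengths, ["A"] * 4, {"A": 1.0}, intercept=0.0, noise_sd=0.0
        )
        np.testing.assert_array_equal(counts, np.round(strengths))

    def test_counts_floored_at_zero(self):
        counts = generate_behaviour(
            np.array([5.0]), ["A"], {"A": -2.0}, intercept=0.0, noise_sd=0.0
        )
        assert counts[0] == 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_behaviour(np.array([1.0]), ["A"], {"A": 0.0}, noise_sd=-1.0)

    def test_strong_negative_slope_detected_by_interaction(self):
        """Power of the Group x Error interaction when counts are a strong
        negative readout of strength in group A only (n = 30/group).

        When counts are generated *from* strength and the GLM regresses
        strength back on counts, the interaction's non-centrality is
        bounded: with count signal variance a and count noise variance b,
        t^2 = 2n·ab/(a+2b)^2 <= n/4, i.e. |t| <= 2.74 at n = 30 and a
        ceiling of roughly 77% power at alpha = 0.05. The test runs at
        the information optimum (a = 2b) and requires >= 70% detection.
        """
        import pandas as pd

        from aecnet import strength_glm

        rng = np.random.default_rng(21)
        hits = 0
        n = 30
        for i in range(100):
            groups = np.array(["A"] * n + ["B"] * n)
            strength = rng.normal(4.0, 2.0, 2 * n)
            counts = generate_behaviour(
                strength, groups, {"A": -0.8, "B": 0.0},
                intercept=8.0, noise_sd=1.09, seed=3000 + i,
            )
            df = pd.DataFrame({"group": groups, "strength": strength, "errors": counts})
            hits += strength_glm(df)["p"].iloc[0] <= 0.05
        assert hits >= 70


def test_group_aec_sample_plants_delta():
    edges = [(0, 1), (2, 3)]
    a, b = generate_group_aec(200, 6, planted_edges=edges, delta=0.3, seed=0)
    assert np.allclose(a, a.transpose(0, 2, 1))
    for u, v in edges:
        assert abs((a[:, u, v].mean() - b[:, u, v].mean()) - 0.3) < 0.05
    assert abs(a[:, 0, 2].mean() - b[:, 0, 2].mean()) < 0.05
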