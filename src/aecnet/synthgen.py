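"""Synthetic two-group MEG-like datasets with known envelope coupling.

The generative model is the standard one for amplitude-envelope
coupling: each node carries a narrowband carrier (white noise FIR
filtered to the requested band and normalised to unit Hilbert
envelope), multiplied by a slow (< 1 Hz) strictly positive modulator.
The Hilbert envelope of the product is, to numerical accuracy, the
modulator itself, so envelope coupling between two nodes is planted by
giving their modulators a shared slow component: with modulators

    z_i = sqrt(c) * s + sqrt(1 - c) * u_i

(shared ``s`` slow and unit-variance, independent unit-variance ``u_i``)
the envelope Pearson correlation of a planted pair equals ``c`` up to
sampling noise, making the coupling target directly tunable. The
node-specific ``u_i`` mix the slow component with a faster one (up to
about a quarter of the band width), emulating the envelope fluctuation
spectrum of real band-limited oscillations and stabilising short-window
correlation estimates. The
sharing coefficient is time-resolved: pre-stimulus samples use the
baseline coupling target, post-stimulus samples the group-specific
target, and "Physical" trials stay at baseline coupling throughout —
emulating a task effect confined to the social condition.

Signal leakage is emulated by a zero-lag linear mixing matrix with unit
diagonal and exponentially decaying off-diagonal weights between index
neighbours; amplitude-spike artefacts are injected after mixing.
Sensor-level data are obtained by projecting sources through a random
unit-column lead field plus white noise, with scripted rigid-body
fiducial excursions for head-motion testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .connectivity import band_edges, design_band_fir
from .preprocess import ContinuousRecording, EpochSet

logger = logging.getLogger(__name__)

#: Depth of the slow amplitude modulation around its unit mean.
MODULATION_DEPTH = 0.3

#: Low-pass cutoff of the slow modulator, Hz.
MODULATOR_CUTOFF_HZ = 0.5


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-group dataset.

    Defaults follow the emulated study conditions: 90 atlas nodes,
    600 Hz sampling, −5..17 s epochs, ~22 usable trials per subject,
    and two groups of ~30 subjects.
    """

    n_nodes: int = 90
    n_subjects_per_group: int = 30
    n_trials: int = 22
    fs: float = 600.0
    epoch_window: tuple[float, float] = (-5.0, 17.0)
    band: str | tuple[float, float] = "beta"
    planted_edges: tuple = ()
    coupling_by_group: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.2})
    baseline_coupling: float = 0.0
    mixing_strength: float = 0.0
    artefact_rates: dict = field(default_factory=lambda: {"spike": 0.0, "motion": 0.0})
    spike_amplitude: float = 3000.0
    seed: int = 0

    def validate(self):
        lo, hi = band_edges(self.band)
        if hi >= self.fs / 2:
            raise ValueError(
                f"band edge {hi} Hz is at or above the Nyquist frequency {self.fs / 2} Hz"
            )
        for u, v in self.planted_edges:
            if u == v:
                raise ValueError(f"planted edge ({u},{v}) joins a node to itself")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"planted edge ({u},{v}) references an invalid node")
        for g, c in self.coupling_by_group.items():
            if not 0 <= c < 1:
                raise ValueError(f"coupling target for group {g} must be in [0, 1)")
        if not 0 <= self.baseline_coupling < 1:
            raise ValueError("baseline coupling must be in [0, 1)")
        if not 0 <= self.mixing_strength < 1:
            raise ValueError("mixing_strength must be in [0, 1)")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("empty epoch window")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    planted_edges: tuple
    realized_coupling: dict  # group -> {edge: envelope Pearson r, noiseless}
    mixing: np.ndarray  # node × node, unit diagonal
    seed: int
    groups: list  # per-subject group label
    spike_trials: dict  # subject id -> list of trial indices with spikes


@dataclass
class SubjectData:
    subject_id: str
    group: str
    epochs: EpochSet


def mixing_matrix(n_nodes: int, strength: float, n_neighbours: int = 3) -> np.ndarray:
    """Unit-diagonal zero-lag mixing with decaying neighbour leakage.

    Off-diagonal weights fall off exponentially with index distance
    (circular neighbourhood) and each row's off-diagonal block is scaled
    to Euclidean norm ``strength``, so ``strength`` is the total leakage
    coefficient per node.
    """
    m = np.eye(n_nodes)
    if strength == 0 or n_nodes < 2:
        return m
    k = min(n_neighbours, n_nodes - 1)
    w = np.zeros((n_nodes, n_nodes))
    for off in range(1, k + 1):
        val = np.exp(-(off - 1) / 1.5)
        idx = np.arange(n_nodes)
        w[idx, (idx + off) % n_nodes] += val
        w[idx, (idx - off) % n_nodes] += val
    w *= strength / np.linalg.norm(w, axis=1, keepdims=True)
    return m + w


def _lowpass_noise(rng: np.random.Generator, shape, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance Gaussian processes band-limited below ``cutoff`` Hz.

    The noise is generated with ~3/cutoff seconds of padding on each
    side before zero-phase filtering and cropped afterwards, so the
    filter's edge transient (seconds long for sub-Hz cutoffs) never
    contaminates the returned window.
    """
    pad = int(round(3.0 / cutoff * fs))
    x = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, x, axis=-1)[..., pad : pad + shape[-1]]
    sd = z.std(axis=-1, keepdims=True)
    return z / np.where(sd == 0, 1.0, sd)


def _slow_modulator(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """The shared (coupling-carrying) modulator: slow, < 1 Hz."""
    return _lowpass_noise(rng, shape, fs, MODULATOR_CUTOFF_HZ)


def _private_modulator(rng: np.random.Generator, shape, fs: float, band) -> np.ndarray:
    """Node-specific envelope fluctuations: equal-power mixture of the
    slow component and a faster one (up to ~band-width/4, capped at
    3 Hz). Band-limited oscillations carry envelope fluctuations up to
    roughly half their bandwidth, and including them stabilises
    short-window envelope-correlation estimates the way real data do.
    Unit variance, so modulator sharing still sets the planted
    correlation exactly."""
    lo, hi = band_edges(band)
    fast_cut = float(np.clip((hi - lo) / 4.0, MODULATOR_CUTOFF_HZ, 3.0))
    slow = _lowpass_noise(rng, shape, fs, MODULATOR_CUTOFF_HZ)
    fast = _lowpass_noise(rng, shape, fs, fast_cut)
    return np.sqrt(0.5) * slow + np.sqrt(0.5) * fast


def _unit_carrier(rng: np.random.Generator, shape, fs: float, band) -> np.ndarray:
    """Unit-envelope narrowband carriers with wandering frequency.

    Each carrier is ``cos(phi(t))`` with instantaneous frequency drawn
    as a slow Gaussian process centred mid-band and clipped to stay
    inside the band. The instantaneous envelope is exactly 1, so a slow
    multiplicative modulator becomes, to numerical accuracy, the Hilbert
    envelope of the product — which makes the planted envelope
    correlation equal the modulator-sharing coefficient. (A filtered
    white-noise carrier instead has Rayleigh envelope fluctuations that
    attenuate the achievable envelope coupling roughly twofold.)
    """
    lo, hi = band_edges(band)
    f0, bw = (lo + hi) / 2.0, hi - lo
    cutoff = max(min(bw / 4.0, 2.0), 0.25)
    jit = _lowpass_noise(rng, shape, fs, cutoff)
    f_inst = np.clip(f0 + (bw / 6.0) * jit, lo + 0.1 * bw, hi - 0.1 * bw)
    phase0 = rng.uniform(0, 2 * np.pi, size=shape[:-1] + (1,))
    phi = 2 * np.pi * np.cumsum(f_inst, axis=-1) / fs + phase0
    return np.cos(phi)


def _planted_components(n_nodes: int, edges) -> list[set]:
    """Connected components of the planted-edge graph (nodes sharing a
    modulator). Pairs within one component all reach the coupling target."""
    parent = list(range(n_nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for u, v in edges:
        parent[find(u)] = find(v)
    comps: dict[int, set] = {}
    for u, v in edges:
        comps.setdefault(find(u), set()).update((u, v))
    return list(comps.values())


def iter_source_subjects(spec: SyntheticSpec):
    """Yield ``SubjectData`` one subject at a time (memory-friendly).

    Use :func:`generate_source_dataset` for the materialised list plus
    ground truth.
    """
    yield from _generate(spec)[0]


def generate_source_dataset(spec: SyntheticSpec):
    """Generate the full two-group source-level dataset.

    Returns
    -------
    subjects : list of SubjectData
    truth : SyntheticTruth
        Includes realized (noiseless, pre-mixing) planted-edge envelope
        correlations per group, measured on the task samples of
        "Social" trials.
    """
    gen, truth = _generate(spec)
    return list(gen), truth


def _generate(spec: SyntheticSpec):
    spec.validate()
    fs = spec.fs
    t0, t1 = spec.epoch_window
    n_samp = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samp) / fs
    task_mask = times >= 0
    comps = _planted_components(spec.n_nodes, spec.planted_edges)
    node_comp = {u: i for i, c in enumerate(comps) for u in c}
    mix = mixing_matrix(spec.n_nodes, spec.mixing_strength)

    ss = np.random.SeedSequence(spec.seed)
    groups = sorted(spec.coupling_by_group)
    subject_seeds = ss.spawn(len(groups) * spec.n_subjects_per_group)

    truth = SyntheticTruth(
        planted_edges=tuple(tuple(e) for e in spec.planted_edges),
        realized_coupling={g: {} for g in groups},
        mixing=mix,
        seed=spec.seed,
        groups=[],
        spike_trials={},
    )
    # accumulate Fisher-z of noiseless modulator correlations per edge/group
    zacc = {g: {tuple(e): [] for e in spec.planted_edges} for g in groups}

    def subjects():
        k = 0
        for g in groups:
            coupling = spec.coupling_by_group[g]
            for j in range(spec.n_subjects_per_group):
                sid = f"{g}{j:03d}"
                rng = np.random.default_rng(subject_seeds[k])
                k += 1
                data = np.empty((spec.n_trials, spec.n_nodes, n_samp))
                conds = np.array(
                    ["Social" if i % 2 == 0 else "Physical" for i in range(spec.n_trials)],
                    dtype=object,
                )
                spikes = []
                for tr in range(spec.n_trials):
                    shared = _slow_modulator(rng, (max(len(comps), 1), n_samp), fs)
                    own = _private_modulator(rng, (spec.n_nodes, n_samp), fs, spec.band)
                    # time-resolved sharing coefficient
                    c_t = np.full(n_samp, spec.baseline_coupling)
                    if conds[tr] == "Social":
                        c_t[task_mask] = coupling
                    w = np.sqrt(c_t)
                    z = own.copy()
                    for node, ci in node_comp.items():
                        z[node] = w * shared[ci] + np.sqrt(1 - c_t) * own[node]
                    m = np.clip(1.0 + MODULATION_DEPTH * z, 0.05, None)
                    if conds[tr] == "Social":
                        for e in spec.planted_edges:
                            r = np.corrcoef(m[e[0], task_mask], m[e[1], task_mask])[0, 1]
                            zacc[g][tuple(e)].append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
                    carrier = _unit_carrier(rng, (spec.n_nodes, n_samp), fs, spec.band)
                    x = m * carrier
                    x = mix @ x  # zero-lag leakage
                    if rng.random() < spec.artefact_rates.get("spike", 0.0):
                        node = rng.integers(spec.n_nodes)
                        pos = rng.integers(n_samp - 6)
                        x[node, pos : pos + 6] += spec.spike_amplitude
                        spikes.append(tr)
                    data[tr] = x
                truth.groups.append(g)
                truth.spike_trials[sid] = spikes
                yield SubjectData(
                    subject_id=sid,
                    group=g,
                    epochs=EpochSet(data=data, times=times, fs=fs, conditions=conds),
                )
        for g in groups:
            for e, zs in zacc[g].items():
                truth.realized_coupling[g][e] = float(np.tanh(np.mean(zs))) if zs else np.nan

    return subjects(), truth


# ---------------------------------------------------------------------------
# sensor tier


@dataclass
class MotionEvent:
    """A scripted rigid-body excursion: translate all fiducials by
    ``translation_mm`` over samples [start, stop)."""

    start: int
    stop: int
    translation_mm: tuple = (0.0, 0.0, 0.0)


#: Nominal fiducial layout (nasion, LPA, RPA) in mm.
FIDUCIAL_LAYOUT = np.array(
    [[0.0, 90.0, 0.0], [-70.0, 0.0, 0.0], [70.0, 0.0, 0.0]]
)


def random_lead_field(n_channels: int, n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Random Gaussian lead field with unit-norm columns (fixed orientation)."""
    g = rng.standard_normal((n_channels, n_nodes))
    return g / np.linalg.norm(g, axis=0, keepdims=True)


def generate_sensor_dataset(
    subject: SubjectData,
    n_channels: int,
    snr: float,
    motion_events: list[MotionEvent] | None = None,
    seed: int = 0,
    gap_s: float = 0.0,
) -> ContinuousRecording:
    """Project one subject's source epochs to a continuous sensor recording.

    Sensor data are the lead-field projection of the concatenated source
    trials plus white noise at the requested SNR (ratio of mean signal
    variance to mean noise variance across channels). Event markers are
    placed at trial onsets; fiducial tracks carry the scripted rigid
    excursions. The lead field is stored on the recording.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    epochs = subject.epochs
    n_nodes = epochs.data.shape[1]
    if n_channels < n_nodes:
        raise ValueError(f"need n_channels ≥ n_nodes ({n_nodes}), got {n_channels}")
    rng = np.random.default_rng(seed)
    lf = random_lead_field(n_channels, n_nodes, rng)

    fs = epochs.fs
    n_samp = epochs.data.shape[2]
    gap = int(round(gap_s * fs))
    block = n_samp + gap
    total = block * epochs.n_trials
    onset_offset = int(round(-epochs.times[0] * fs))

    sensor = np.zeros((n_channels, total))
    events = []
    for tr in range(epochs.n_trials):
        lo = tr * block
        sensor[:, lo : lo + n_samp] = lf @ epochs.data[tr]
        events.append((lo + onset_offset, str(epochs.conditions[tr])))
    sig_var = sensor.var(axis=1).mean()
    noise_sd = np.sqrt(sig_var / snr)
    sensor += noise_sd * rng.standard_normal(sensor.shape)

    fid = np.repeat(FIDUCIAL_LAYOUT[:, :, None], total, axis=2)
    for ev in motion_events or []:
        lo, hi = max(ev.start, 0), min(ev.stop, total)
        fid[:, :, lo:hi] += np.asarray(ev.translation_mm, float)[None, :, None]

    return ContinuousRecording(
        data=sensor, fs=fs, events=events, fiducials=fid, lead_field=lf
    )


# ---------------------------------------------------------------------------
# behaviour


def generate_behaviour(
    strengths: np.ndarray,
    groups,
    slope_by_group: dict,
    intercept: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject error counts as a noisy linear readout of network strength.

    ``count_i = max(0, round(intercept + slope_g(i) * strength_i + eps))``
    with Gaussian noise of standard deviation ``noise_sd``. Group-specific
    slopes plant a Group × Error interaction for the brain–behaviour GLM.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    strengths = np.asarray(strengths, float)
    groups = np.asarray(groups)
    if strengths.shape[0] != groups.shape[0]:
        raise ValueError("one strength per subject required")
    rng = np.random.default_rng(seed)
    slopes = np.array([slope_by_group[g] for g in groups], float)
    raw = intercept + slopes * strengths + noise_sd * rng.standard_normal(len(strengths))
    return np.maximum(0, np.round(raw)).astype(int)


# ---------------------------------------------------------------------------
# matrix-level group samples (for NBS calibration / power studies)


def generate_group_aec(
    n_subjects_per_group: int,
    n_nodes: int,
    planted_edges=(),
    delta: float = 0.0,
    edge_mean: float = 0.1,
    edge_sd: float = 0.15,
    seed: int = 0,
):
    """Draw per-subject symmetric AEC matrices for two groups directly.

    Edges are independent Gaussian across subjects with common mean
    ``edge_mean`` and between-subject standard deviation ``edge_sd``;
    group A's planted edges have their mean shifted by ``delta``. This
    matrix-level generator is the fast surrogate for permutation
    calibration and power studies where full time-series synthesis is
    unnecessary.

    Returns ``(mats_a, mats_b)`` of shapes (n_subj, n, n).
    """
    rng = np.random.default_rng(seed)

    def draw(n_subj, shift_edges):
        tri = np.triu_indices(n_nodes, k=1)
        vals = edge_mean + edge_sd * rng.standard_normal((n_subj, len(tri[0])))
        if shift_edges:
            eidx = {tuple(sorted(e)): i for i, e in enumerate(zip(*tri))}
            for e in shift_edges:
                vals[:, eidx[tuple(sorted(e))]] += delta
        mats = np.zeros((n_subj, n_nodes, n_nodes))
        mats[:, tri[0], tri[1]] = vals
        mats += mats.transpose(0, 2, 1)
        return mats

    return draw(n_subjects_per_group, planted_edges), draw(n_subjects_per_group, ())
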