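# Methods

This note documents the models and numerical choices behind `aecnet`:
what each stage assumes, which parameters matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## Preprocessing

Continuous data are mean-centred per channel and filtered before
epoching, so filter transients never fall inside epochs. The band-pass
is a 4th-order Butterworth (1–150 Hz) applied forward–backward as
second-order sections; line noise is removed with IIR notch filters
(Q = 30) at 60 and 120 Hz, also zero-phase. Zero-phase filtering is a
deliberate choice: the downstream quantity is the amplitude envelope,
and phase distortion would shift envelope timing between nodes.
Sampling rates at or below 300 Hz are rejected because the 150 Hz edge
would reach Nyquist.

Epochs are half-open windows `[onset − 5 s, onset + 17 s)` — 13 200
samples at 600 Hz — so no boundary sample is counted twice by adjacent
metrics. Trial rejection applies two rules in a fixed order with
mutually exclusive reported reasons:

- **Amplitude**: a trial is rejected iff its peak absolute value
  strictly exceeds 2500 fT (a sample at exactly 2500 fT survives).
- **Head motion**: the three fiducial tracks are reduced to a
  per-sample displacement by fitting the optimal rigid transform
  (Kabsch, batched SVD) from the median fiducial configuration to the
  current one; displacement is the largest distance any fiducial is
  moved. Trials whose within-trial maximum exceeds 10 mm are rejected.
  Collinear fiducials make the fit degenerate and raise an error.

A trial failing both rules is reported once, as an amplitude
rejection. Referencing motion to the recording-wide median (not trial
start) follows the head-tracking convention of continuous head
localization. ICA-based ocular/cardiac artefact removal is out of
scope: it requires visual component selection, which has no
algorithmic specification; the amplitude criterion is the only
sensor-artefact guard here.

## LCMV beamforming

The spatial filter per node is the unit-gain minimum-variance solution
`w = Cr⁻¹L/(LᵀCr⁻¹L)` with diagonal loading `Cr = C + f·(tr C/n)·I`.
The regularization fraction `f` defaults to 0.05 — "5%" is interpreted
as 5% of mean sensor power, the common toolbox convention. The sensor
covariance uses all kept samples (baseline and task); rank deficiency
only warns, since loading handles it.

For free-orientation (3-column) lead fields the dominant orientation
is the principal eigenvector of the 3×3 source-power matrix
`(LᵀCr⁻¹L)⁻¹`; an SVD-of-weights variant would be equally defensible —
the power eigenvector was chosen and is tested. The eigenvector sign
is arbitrary, so orientation and weights are flipped together until
the weight vector's largest-magnitude element is positive; flipping
weights alone would turn the unit-gain constraint into `w·L = −1`,
which is why fixed-orientation weights (no sign freedom) are never
flipped. The neural activity index divides each weight vector by its
norm, mapping unit-variance sensor noise to unit source variance so
amplitudes are comparable across nodes; envelope correlations are
scale-invariant, so this affects only interpretability, not the
statistics.

## Connectivity

Pipeline order is fixed and tested: band filter → orthogonalize →
envelope → windowed correlation → baseline.

**Band filters** are odd-length linear-phase FIRs (Hamming window)
applied by centred convolution, i.e. zero delay. Tap counts scale with
the band: the transition width is half the low edge (capped by the
headroom to Nyquist), which yields ≥ 40 dB attenuation one octave
outside each band (theta needs ~991 taps at 600 Hz, gamma ~133).

**Symmetric orthogonalization** finds the closest matrix (Frobenius
norm) whose node series are mutually orthogonal, by alternating a
Procrustes rotation (polar factor of `A·diag(d)`) with per-node
rescaling `dᵢ = aᵢᵀoᵢ`. Input series are mean-centred first; because
every iterate stays in the column span of the centred data, the output
is exactly zero-mean and orthogonality equals zero Pearson correlation
to machine precision. Convergence is declared when the relative
residual changes by less than 1e-10 (max 100 alternations; typical
instances converge in well under 20). Rank-deficient input is an
error: leakage correction cannot manufacture the missing dimensions.
This correction removes *all* zero-lag correlation, genuine or
artefactual — the standard, deliberate trade of the leakage-robust
literature.

**AEC granularity.** Envelopes are full-rate Hilbert moduli (no
downsampling). Correlations are static Pearson coefficients per trial
within fixed windows (−5–0, 0–5, 5–10, 10–15 s), aggregated across
trials by Fisher-z mean. A sliding-window estimator is a plausible
alternative reading of "AEC time series"; the windowed form matches
the three reported task windows and is what the statistics consume.
Orthogonalization is applied once per trial over the full epoch, so
baseline and task windows share a single leakage correction rather
than window-dependent rotations.

**Baselining** is entrywise fractional change
`(task − baseline)/denom`, where `denom` clamps the baseline magnitude
at `eps = 1e-3` while preserving its sign; guarded entries are
reported in a mask. The guard only catches near-exact zeros. A more
consequential fact, documented because it shapes power: the *estimated*
per-subject baseline sits in the denominator, so when the true
baseline coupling is near zero the baselined values are unstable and
group differences in raw AEC can be diluted. With study-scale trial
counts (~20) and an appreciable baseline level the estimator is
well-behaved; the integration test runs exactly that regime.
Trial-aggregated matrices are baselined (aggregation before division),
and baselined matrices are what enter the network statistics.

## Network-Based Statistic

Edgewise two-sample t statistics (pooled variance by default — the
toolbox convention; Welch optional) are thresholded one-sided per
contrast direction at τ, default 2.7, the midpoint of the conventional
strict 2.5–3.0 range. Components are connected components of the
surviving edge graph and their statistic is extent (edge count), not
intensity. The null is the distribution of the maximal extent under
random exchange of group labels, re-running the full edgewise →
threshold → components chain each time; permutations are sampled
uniformly with replacement, and

    p_FWE = (1 + #{max extent ≥ observed}) / (1 + n_perm),

so the identity labelling is accounted for by the +1 terms and the
smallest attainable p is 1/(n_perm+1) (1/5001 at the default 5000).
For small samples an exhaustive enumeration over all label assignments
is available and the sampled null is tested against it. Zero-variance
edges are assigned t = 0 with a warning. Each contrast direction is
one analysis family: that is the unit for which the max-statistic
procedure controls family-wise error, and the unit at which the null
calibration suite measures it. Covariates are not supported in the
permutation scheme.

The edgewise t computation is vectorised across permutations (mask
matrix multiplication for group sums and sums of squares), and the
max-extent search uses a small union–find over surviving edges, so a
500-permutation analysis on 30 nodes takes ~10 ms.

## Brain–behaviour model

Node strength sums the AEC values over a component's edges incident to
each node; mean network strength averages over the component's node
set (nodes with at least one component edge), not all atlas nodes.
Mean strength is modelled as a Gaussian identity-link GLM on group,
error count and their interaction; the interaction p-value is the
quantity of interest and is corrected across (network, band) models by
Benjamini–Hochberg FDR. "Generalized linear model" admits many
families; Gaussian-identity was chosen because mean strength is
continuous and no link is reported — this is a design decision, not a
given. Error counts enter untransformed.

Demographic utilities: Welch t and Welch–Satterthwaite df from summary
statistics (means, sds, ns), and Pearson chi-square on 2×2 tables with
optional Yates correction. Reported integer df truncate the fractional
Welch value — the convention that reproduces the published IQ and age
rows (72.61 → 72, 78.58 → 78). The published birth-weight row
(t(54) = 24) is **not** reproducible from its printed summaries, which
give |t| = 23.50 and df = 53.8 under any rounding convention; the
corresponding acceptance check is left failing rather than adjusted,
since the discrepancy almost certainly reflects missing data (different
effective ns) upstream of the printed table. The printed chi-square
values for sex and SRS social cognition likewise match neither plain
Pearson nor Yates on the printed counts and are not asserted.

## Synthetic data generator

Each node carries `x(t) = m(t)·cos(φ(t))`: a narrowband carrier whose
instantaneous frequency wanders slowly inside the band (clipped to
stay there), multiplied by a strictly positive modulator
`m = clip(1 + 0.3·z, 0.05, ∞)`. Because the carrier has exactly unit
instantaneous envelope, the Hilbert envelope of the product is the
modulator itself, and planting coupling `c` by sharing a slow
component — `zᵢ = √c·s + √(1−c)·uᵢ` — makes the envelope correlation
of a planted pair equal `c` directly. A filtered-white-noise carrier
was rejected after measurement: its Rayleigh envelope fluctuations
attenuate the achievable envelope correlation roughly twofold, putting
targets above ~0.5 out of reach. The shared component `s` is < 1 Hz;
the private `uᵢ` mix the slow band with a faster one (~bandwidth/4,
capped at 3 Hz) because real band-limited envelopes fluctuate up to
about half the bandwidth — this stabilises 5-second-window correlation
estimates without changing the planted population correlation (all
components are unit variance). The sharing coefficient is
time-resolved: baseline samples use the baseline coupling target, task
samples the group target, and "Physical" trials stay at baseline
throughout, confining the planted effect to the social condition.
Nodes joined by planted edges share one modulator per connected
component of the planted graph, so all within-component pairs reach
the coupling target.

Leakage is a unit-diagonal mixing matrix with exponentially decaying
weights over the three nearest index neighbours (circular), each row's
off-diagonal block scaled to norm `mixing_strength`; mixing is
instantaneous, so the induced spurious correlation is strictly
zero-lag — exactly what symmetric orthogonalization removes, and the
basis of the leakage-suppression acceptance check. Amplitude spikes
are injected after mixing. The sensor tier projects sources through a
random unit-column lead field (fixed orientation — no 3-orientation
dipoles in the toy tier), adds white noise at a requested SNR, and
scripts rigid fiducial excursions for motion-rejection tests.

Defaults mirror the emulated study: 90 nodes, 600 Hz, −5..17 s epochs,
22 trials/subject, ~30 subjects/group. What the generator does *not*
emulate: 1/f spectral background, anatomy (head models, realistic lead
fields), inter-regional delays, condition-specific evoked responses,
or heavy-tailed artefact families. Passing tests therefore demonstrate
the correctness and calibration of the estimators under the generative
model's assumptions, not robustness to real-data violations of them.

Behavioural error counts are
`max(0, round(intercept + slope_group·strength + ε))`. One analytic
fact discovered while validating the power simulations: when counts
are generated *from* strength and the GLM then regresses strength back
on counts, the interaction's non-centrality is bounded —
`t² = 2n·ab/(a+2b)² ≤ n/4` with `a` the count signal variance and `b`
the count noise variance — giving |t| ≤ 2.74 and ~77% power at
α = 0.05 for n = 30/group *regardless of slope*. The generator's power
test therefore runs at the information optimum (`a = 2b`) and asserts
70%; the GLM acceptance simulation instead places the planted slope on
the strength response (errors as Poisson predictors, residual sd 0.2),
where power is effectively 1.

## Problem sizes in the test and acceptance suites

Simulation-based checks run at reduced but statistically adequate
scale, chosen as study design decisions: orthogonalization is verified
on 100 random instances up to 90 nodes × 3000 samples (a 5-s window at
600 Hz); leakage suppression on one 20-node subject with 10 trials;
NBS calibration on 200 null datasets of 20 + 20 subjects × 30 nodes
with 500 permutations (the permutation count scaled down from 5000,
keeping the p-value floor well below the 0.05 decision level); planted
network recovery on 50 such datasets; the GLM null on 200 datasets and
power on 100. The end-to-end pipeline test uses 8 subjects/group ×
20 nodes × 20 trials in the beta band. Matrix-level group samples
(Gaussian edges, between-subject sd 0.15 — a realistic spread for
baselined AEC) stand in for full time-series synthesis in the
calibration/power loops; the time-series path is exercised end to end
in the integration test and the leakage suite.

## Known limitations

- The fractional-change baseline is noise-sensitive when the true
  baseline coupling is small (see above); the raw matrices are always
  retained alongside the baselined ones.
- Orthogonalization requires more samples than nodes per trial (13 200
  vs ≤ 90 here); short-epoch, high-node-count designs would need a
  different leakage correction.
- The NBS implementation supports extent only, no intensity statistic
  and no covariates.
- The sensor tier's lead field is statistical, not anatomical; it
  exercises the LCMV algebra, not co-registration or head-model error.
- `generate_source_dataset` materialises each subject in memory
  (~200 MB at full study scale); use `iter_source_subjects` to stream
  subjects to HDF5 when generating large datasets.
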