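# Methods

## Spectral processing

Recordings are treated as clean multichannel arrays (channels × samples);
artifact screening is assumed done upstream. Epoching takes the first
`n_epochs` consecutive non-overlapping windows of `epoch_len` samples
(defaults 5 × 4096 at 625 Hz, i.e. 6.554 s each).

Band-pass filtering is frequency-domain masking: the epoch's real FFT is
zeroed outside `[f_lo, f_hi]` (edges inclusive, DC removed) and inverted.
This is zero-phase by construction and has hard band edges; an FIR or IIR
filter would trade edge sharpness for time-domain ringing and would shift
or smear phase near the band edges, so filter choice matters when comparing
absolute connectivity values across implementations. No samples are trimmed
after filtering by default (`trim` is available on phase extraction);
phase-slope checks in the tests evaluate the central 90% of the epoch.

Relative power uses the unwindowed periodogram (squared FFT magnitude) of
the full epoch. Each frequency bin belongs to the band whose interval
`(f_lo, f_hi]` contains it — lower-open so the six canonical bands
(delta 0.5–4, theta 4–8, lower alpha 8–10, upper alpha 10–13, beta 13–30,
gamma 30–45 Hz) partition the spectrum with no bin counted twice, and a
10 Hz component belongs to lower alpha. The denominator is total power over
the union of the analysed bands (0.5–45 Hz for the canonical set), so the
six fractions sum to 1. Per-subject values average over epochs, then
channels.

Instantaneous phase is the angle of the analytic signal
(`scipy.signal.hilbert`) of the band-filtered epoch, wrapped to [−π, π).
The Hilbert construction is the standard companion to the phase lag index;
it is only meaningful on band-limited input, which the pipeline guarantees
by filtering first.

## Phase lag index

PLI = |mean over samples of sign(sin Δφ)|, with Δφ wrapped to [−π, π]
(redundant under sign∘sin but kept explicit). Samples with Δφ exactly 0 or
±π carry no lag-direction information and contribute 0 via sign(0) = 0.
Per-subject band matrices are the element-wise mean of per-epoch matrices,
not the PLI of concatenated epochs. Known-bad channels can be masked by id
before matrix construction.

Finite-sample floor: for independent phases the PLI is |mean of N random
signs| ≈ √(2/πN) ≈ 0.0125 at N = 4096. Narrow-band filtering reduces the
effective number of independent samples roughly to the number of retained
frequency bins, so a 5 Hz-wide band at 4096 samples has a floor near 0.1.
Null-level expectations must therefore be stated per band; the package's
own null checks evaluate the PLI formula on raw broadband phases where the
iid approximation holds.

## Modularity and annealing

Q = Σ_s [l_s/L − (d_s/2L)²] with each undirected weight counted once in
l_s and L. Closed forms used as oracles: single module → Q = 0; m equal
modules with no inter-module weight → Q = 1 − 1/m.

The annealer starts from ⌈√N⌉ equiprobable labels. Each step proposes
moving one uniformly chosen node to one uniformly chosen different label in
[1, N]; the cost is C = −Q (the only cost consistent with accepting when
the proposal does not lower Q and returning the highest-Q partition);
acceptance probability is 1 if ΔQ ≥ 0, else exp(ΔQ/T). T starts at 1 and is
multiplied by 0.995 every 100 steps. ΔQ is evaluated incrementally in O(1)
per proposal by maintaining per-module strengths and each node's weight
into every module; the best labelling over the whole run (and over
restarts) is kept and returned — ties go to the first encountered, so the
result is deterministic given the seed. The returned Q is recomputed from
the labelling by the direct sum to remove incremental floating-point
drift. Only single-node moves are used; collective merge/split moves (used
by some annealing-based module finders) are out of scope. The reference
schedule is 10⁶ steps; the pipeline default is 10⁴, which on the problem
sizes the synthetic studies use (≤ ~30 nodes) reaches the same optima the
exhaustive oracle finds, while keeping full-cohort runs interactive. The
acceptance checks use 10⁵ steps on 7–10-node graphs.

`brute_force_partition` enumerates all set partitions (restricted-growth
order) and is guarded at N ≤ 10 (Bell-number growth).

## Node roles

With κ_i the node's summed weight into its own module: z_i standardises κ_i
by the mean and SD of κ over the module. The population SD (divide by
module size) is the default; the sample-SD alternative is selectable and
rescales z by √(n/(n−1)). Degenerate modules (size 1, or all-equal within-
strengths) give z = 0. PC_i = 1 − Σ_m (κ_im/k_i)², zero for an isolated
node; PC ≤ 1 − 1/m always. Between-module connectivity is the mean weight
to out-module nodes by default (comparable across module-size
configurations); the sum variant is selectable. Because z is standardised
within modules, its network-wide mean is ~0 and no global average is
meaningful; group analyses use it per sensor only.

## Synthetic generators

*Oscillators.* Each module has an independent band-limited Gaussian driver
(white noise masked to the carrier band, unit variance). Channel c observes
its module's driver delayed by c·d samples, where d = round(φ/(2π f_c)·fs)
(forced to ≥ 1 sample) realises the requested phase lag φ at the band
centre f_c — exact only at f_c and quantised to the sample grid. Within-
module pairs therefore differ by consistent non-zero lags, which is all the
PLI needs; filtered-noise drivers with fixed delays were chosen over
coupled-oscillator dynamics (e.g. Kuramoto) for analytic transparency.
Cross-module leakage adds the mean of the other modules' drivers scaled by
`coupling_between`; independent white noise of SD `noise_sd` is added per
channel. Lags of exactly 0 or π are rejected at spec construction — the PLI
is blind to them by design, so such a spec could never support a planted-
recovery test. A zero-lag mixing operator (output = M × input, sample-wise)
emulates volume conduction for the insensitivity checks. The generator
makes no attempt at 1/f spectra, sensor geometry, forward models, or
artifacts, so passing tests demonstrate correctness of the measures, not
realism of the signals.

*Planted graphs.* Block matrices with `w_in` inside and `w_out` between
modules, optional symmetric Gaussian weight noise, clipped to [0, 1], zero
diagonal; returned with the ground-truth partition and its Q.

*Cohorts.* sex ~ Bernoulli(0.5); head surface ~ N(231, 19) cm²; VO₂ max ~
N(52, 7) ml·kg⁻¹·min⁻¹ for men, N(40, 5.5) for women; IQ mean 108 with
residual SD 13 — marginals chosen to resemble a healthy middle-aged cohort.
The mediation chain is metric/mediator/IQ linear in VO₂ max with
independent Gaussian errors, so the planted indirect effect is exactly
a·b. Default noise SDs (mediator 10, IQ 13) place the default planted
slopes of 0.5 at standardised path strengths near 0.4 — moderate effects a
cohort of a few hundred detects reliably, which is the regime the power and
size simulations probe. Every generator is a pure function of its spec
including the seed.

*Synthetic studies.* `synthesize_study` couples the two layers: each
subject's inter-module coupling in a chosen carrier band increases linearly
with VO₂ max around the cohort mean, centred at 0.3 so the whole cohort
stays on the linear range instead of clipping at zero. Higher fitness thus
plants lower modularity in that band, giving the end-to-end regression a
known sign to recover.

## Group statistics

OLS via statsmodels with explicit rank checks (collinear designs are
rejected, not silently dropped); t-based 95% CIs and two-sided p-values.
BH-FDR is the standard step-up at level q (statsmodels backend; the test
suite verifies it against an exhaustive cutoff search). Sensor maps run one
regression per sensor on wide `metric_sensor` columns and emit both B and t
per sensor, since either may serve as the mapped statistic.

Mediation fits a from mediator ~ x + cov, b and c′ from
y ~ x + mediator + cov, and c from y ~ x + cov; the indirect effect is a·b
and c = c′ + a·b holds exactly for OLS with shared covariates (asserted in
the tests at 1e-9). The bootstrap resamples subjects (cases) with
replacement and refits all paths; the percentile interval is the default
and a bias-corrected variant is selectable — the two differ when the a·b
bootstrap distribution is skewed, which is common near the null.
Standardised coefficients z-score x, mediator, and y before fitting.

## Pipeline

Per subject and band: epoch → band-filter → PLI per epoch → anneal per
epoch → roles → average. Subjects failing validation are excluded with a
counted, logged reason rather than aborting the study. All stage seeds
derive from the single global seed via
`SeedSequence([seed, subject_idx, band_idx(, epoch_idx)])`, bootstrap seeds
via `SeedSequence([seed, 999999, mediation_idx])`; the scheme is recorded
in the run manifest together with a config hash, so a rerun from the
manifest reproduces every table byte for byte. The statistics stage can be
rerun alone from the cached subject-metrics table and yields identical
results. Signals are plain text or `.npy`; vendor MEG formats are not
parsed.

## Problem sizes and limitations

The validation studies run at desk scale by design: tens of subjects,
8–12 channels, 2–5 epochs, 10³–10⁵ annealing steps, 10³ bootstrap draws —
sizes at which every planted structure is comfortably identifiable and the
annealer provably reaches exhaustive-search optima. Scaling to a full
cohort (hundreds of subjects, ~150 channels, 10⁶ steps, 5·10³ draws) is a
config change, not a code path change. Known limitations: the oscillator
model's sample-quantised lag is exact only at the band centre; hard
spectral edges ring for signals with strong out-of-band energy; PLI null
levels depend on bandwidth (see above); the annealer's single-node moves
can need many steps on large networks with near-degenerate optima; and
synthetic cohorts encode linear, homoscedastic effects only.
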