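# Methods

## Signal model and scope

The package treats an ambulatory ECG lead as

x(t) = x_c(t) + n_bw(t) + n_pli(t) + n_sdn(t) + e(t),

where x_c is the (unobservable, never estimated) noiseless ECG, the three
n_v are quantitative noise components and e collects everything else. The
components are not independent in practice — slow drift leaks into the
block-std statistic and vice versa — and the model is used descriptively,
not as a generative claim. Because the SDN term is a block-wise envelope
statistic rather than an additive waveform, the reported decomposition
residual is `x − n_bw − n_pli` only; subtracting SDN would not be
meaningful. Denoising/reconstruction is explicitly out of scope: the goal is
to characterize where and how badly a recording is corrupted.

## Estimators

**Baseline wander.** One node per non-overlapping window of `window_s`
(default 0.8 s): the node value is the window *median* (robust to QRS
spikes, which would drag a mean node toward the R peak), placed at the
window center. A cubic spline through the nodes is evaluated at every
sample; outside the node span the spline is clamped to the first/last node
value, since unconstrained cubic extrapolation can blow up within half a
window of the edges. A trailing partial window shorter than half a window is
dropped, otherwise it contributes a node at its own center. Signals shorter
than three windows are rejected.

**Powerline interference.** A second-order IIR notch (center `f0`, default
50 Hz; −3 dB bandwidth 1 Hz, i.e. quality factor f0/bandwidth = 50) applied
forward–backward (`filtfilt`) so the output is zero-phase and the residual
`x − filtered(x)` is time-aligned with the input. When no mains interference
is present this residual is a tiny wide-band remnant, so its amplitude
histogram concentrates near zero — the informative part of the distribution
is its tail. Requires `fs > 2·f0`.

**SDN.** Sample standard deviations (denominator N−1, used consistently
throughout the package) over `block_s` = 0.5 s blocks; per group of 10
blocks, mean + 2·std of the block values, assigned to every block in the
group and expanded piecewise-constantly to per-sample resolution. Leftover
samples that do not fill a block fold into the final block; a trailing group
with a single block merges into the previous group (a std of one value is
undefined), otherwise it is processed with its actual count. The statistic
is translation-invariant, non-negative and positively homogeneous.

Accuracy assertions on filters and splines exclude the first and last 10% of
samples (transient region); tolerances were frozen from numeric oracle runs
recorded in the test docstrings (e.g. BW tracking of a 0.5 mV, 0.2 Hz drift:
interior RMSE 0.0044 mV against an asserted bound of 0.05 mV).

## Thresholds and quantization

Amplitude-to-level quantization uses three cut points per component with
intervals closed on the left threshold (a = t maps to the lower level; the
convention is arbitrary but fixed and documented). The original workflow set
thresholds manually from pooled amplitude histograms to match expert maps;
that judgment is not algorithmically reproducible, so thresholds are a
first-class object with two construction paths: a reproducible quantile rule
(`t_free = Q(0.25)` to hold the near-zero mass, `t_hard = Q(0.95)` to
isolate the heavy tail, `t_mid` the midpoint — mirroring the stated
rules-of-thumb) and a verbatim manual override. The API supports deriving
once on a reference corpus and applying to any recording, which is how the
event-recorder-derived thresholds were reused for Holter data. Quantitative
quantization never produces level 4; "other" events are identifiable only
from a clinical track or synthetic ground truth. Degenerate (all-equal)
amplitude pools raise an error advising manual thresholds.

## Maps, bars and their invariants

Noise maps are maximal run-length encodings over half-open intervals
`[start, end)`; the half-open convention removes boundary double counting
from every duration sum. Gaps (event recorders store discontinuous bursts)
are declared on the record and preserved through the map rather than
zero-filled.

Noise bars anchor their phase at the map's first labeled instant; within
each bar, per-level durations are normalized by the bar's *labeled*
duration, so a bar partially covered by a gap is normalized by its non-gap
time and is blank only when it contains no labeled time at all. The partial
final bar is kept and normalized by its own duration — this preserves exact
duration conservation (summing `durations` over bars returns each level's
total map duration), which is a tested property. Bars store both raw
durations and fractions so the conservation check does not round-trip
through a division.

Rendering uses one shared five-color palette (blue, green, yellow, red,
black for levels 0–4), stacking lower levels at the bottom of each bar.

## Conditional histograms, summaries, kappa

Conditional histograms assign each amplitude sample the level of the map
segment covering its start time; counts are scaled by the sampling period so
the vertical axis reads seconds of signal, and priors are level durations
over the labeled total. The mixture identity (per-bin sum over levels equals
the marginal histogram) holds exactly by construction and is property-tested
with a dyadic sampling rate so the scaling is exact in floating point.
Uncovered samples are excluded and their count logged. Default binning is
Freedman–Diaconis on the covered amplitudes; a log-scaled vertical axis is a
rendering flag only — stored counts are always linear.

Cohen's kappa is the unweighted coefficient on duration-weighted confusion
matrices; weighting by minutes rather than beats is immaterial because kappa
is invariant to positive rescaling (tested). Neighbor-class partial credit
is deliberately not implemented. Class merging sums rows and columns within
the groups of a partition; merging everything into one class is rejected
(kappa undefined), as is a chance agreement of 1.

One published worked example is internally inconsistent: the five
event-recorder per-level duration strings sum to 46 606 s and give a
low-noise share of 23.33%, while the printed share is 25.67% (the five
printed percentages sum to 102.34%). The package reports the value implied
by the durations; the corresponding assertion against the printed figure is
kept in the acceptance tests and fails, documenting the discrepancy rather
than hiding it. The analogous Holter strings are fully self-consistent.

## Synthetic generator

The generator exists to exercise every pipeline stage deterministically:
(config, seed) fully determines the output. The clean signal is a repeating
template beat of Gaussian bumps (P: 0.15 mV / 25 ms; R: 1 mV / 12 ms; T:
0.3 mV / 60 ms) with 3% multiplicative RR jitter — adequate for testing
estimators and plumbing, *not* physiological (no QRS substructure, no
rhythm pathology, no electrode/torso modeling). Two canned profiles mirror
the target devices: event-recorder bursts (200 Hz, 30–300 s) and
Holter-style stretches (128 Hz, hours).

Scheduled episodes are additive (sinusoidal baseline drift at a random
0.1–0.3 Hz frequency; a mains tone; EMG-like high-passed Gaussian noise
normalized to a target std) or replacement (flat line; saturation at a
constant 5 mV; calibration pulses of 1 mV/200 ms at 1 Hz, a common Holter
convention). Ground-truth severity operationalizes the qualitative taxonomy
with fixed magnitude cut-offs: replacement → 4; additive magnitude ≥ 3 mV
(3× the R peak, QRS obliterated) → 3; ≥ 0.3 mV (2× the P amplitude, P/T
masked) → 2; > 0.03 mV (visible) → 1; else 0. These constants are documented
configuration choices, not a claim to replicate expert labeling, so passing
recovery tests show the pipeline is self-consistent on synthetic data — they
do not certify performance on clinical recordings, whose noise is
non-stationary, patient-specific and not a sum of clean archetypes.

## Problem sizes and numerical choices

Tests run on recordings of seconds to 10 minutes at 128–200 Hz — long enough
for ≥ 100 SDN blocks and stable quantiles, small enough that the full suite
completes in seconds. The hard-burst recovery check (≥ 80% of samples inside
injected hard bursts reaching quantized SDN level ≥ 2 under self-derived
thresholds) was frozen after a 12-seed Monte-Carlo run that observed a rate
of 1.0 throughout; the mains-localization check (episode RMS ≥ 5× outside
RMS) observed ratios near 700×. Quantile assertions use n = 10⁵ samples with
±0.02 bands verified against closed-form uniform/exponential quantiles.

File formats are text-based: CSV signals (metadata line with fs, lead-name
header; optional comma-decimal dialect with `;` separators), a minimal WFDB
subset written by this package (header + format-16 int16 `.dat` at 1000 ADC
units/mV, i.e. 0.0005 mV round-trip precision), TSV label tracks, CSV
noise-bar and confusion-matrix tables, and YAML for thresholds and synthesis
scenarios. Proprietary device formats are out of scope.

## Known limitations

* Severity classification of real recordings still requires a clinical label
  track; automatic clinical-severity classification is future work.
* The quantile defaults do not reproduce the original unpublished manual
  thresholds; they are a reproducible stand-in with the same structure.
* The notch-residual PLI estimate is sensitive to wide-band artifacts
  (disconnection, saturation), which leak into its tail.
* The WFDB subset covers single-segment, single-`.dat`, format-16 records
  only.
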