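# Methods

This note documents the models, estimators and numerical choices in
`striephys`, what the synthetic generators do and do not emulate, and
the known limitations.

## Spontaneous PSC detection

**Baseline.** Voltage-clamp traces drift on second time scales
(seal/leak changes). A centered 1-s moving median is subtracted;
edges use truncated windows. For long traces the median is evaluated
every window/128 samples and linearly interpolated — the baseline it
tracks varies far more slowly than the grid, and the interpolation
error is well under the noise floor.

**Thresholds.** All detectors scale their thresholds with the robust
SD (1.4826 × MAD), which is insensitive to the events themselves. On
noise-free synthetic traces the MAD is zero; the plain SD is used as
a fallback so that clean examples remain detectable.

The slope detector accumulates the (0.2 ms-smoothed) negative slope
within runs; the accumulated quantity is an amplitude (pA), so its
threshold is 4 robust SDs *of the baseline-corrected trace*. The MAD
of the accumulated trace itself was evaluated and rejected: it is
dominated by small early-run values and fires at tens of Hz on pure
noise, whereas the trace-scaled rule gives < 0.05 Hz.

The amplitude detectors threshold at 4.5 robust SDs of the filtered
trace (zero-phase 4th-order Butterworth throughout; forward-backward
filtering avoids onset-time bias). Crossing candidates use hysteresis
(re-arm at 25% of threshold) plus a 1 ms debounce: without hysteresis,
the decay of each event hovers around threshold and spawns one or two
spurious candidates 2–3 ms after the true onset. A final vetting pass
drops events with amplitude below 3 robust SDs of the trace or with
measured 20–80% rise times outside 0.1–10 ms, standing in for the
manual curation step of interactive workflows.

**Measurement.** Amplitude is |extremum − local baseline| within
10 ms of onset (truncated at the next onset), with the local baseline
the median of the 2 ms pre-onset. Rise time is 20–80% with linear
interpolation of the crossings. The decay constant comes from a
log-linear least-squares fit of the falling phase (samples above 10%
of the amplitude); fits on segments shorter than 3 ms or with
non-negative slope report NaN and the event is retained. On noise-free
biexponential events (τ_rise 0.5 ms, τ_decay 5 ms) the fitted τ is
within 1.5% of truth.

**Operating characteristics** (synthetic, amplitude/noise = 5, 2 Hz
events, 25 kHz): recall ≥ 0.97, precision ≥ 0.95 with ±2 ms matching;
false-event rate on pure noise ≤ 0.03 Hz.

## Evoked short-term plasticity

Per-pulse amplitude uses a per-pulse local baseline (median of the
2 ms pre-stimulus), 1 ms artifact blanking, and an extremum search
capped at 20 ms post-stimulus — evoked PSC peaks arrive within a few
ms, and searching the full 50 ms inter-pulse window would add a
noise-maximum bias to small late-train responses. Re-measuring the
baseline each pulse keeps errors < 10% even when decays overlap
(τ_decay 20 ms at 20 Hz). Classification (depressing / facilitating /
neutral) compares the mean normalized amplitude of pulses 2–8 against
1 with a ±0.05 margin; the margin reflects that classification is
qualitative.

## Bootstrap E–I contrasts

Each iteration draws 75% of each group's cells *without replacement*
(the literal reading of the resampling procedure; classical
with-replacement resampling is available via `replace=True`), computes
group means, and records their ratio or difference. The summary is
the mean over 1000 iterations, its SD, the ±3 SD noise band, and a
95% percentile interval.

**Significance rule.** A contrast is significant when the null value
(1 for ratios, 0 for differences) lies outside the ±3 SD noise band.
The alternative "null outside the 95% percentile interval" was
evaluated and rejected as the default: 75%-of-n subsampling without
replacement produces a resampling distribution whose SD is ~0.61× the
true sampling SD of the group-mean contrast, so the percentile
interval rejects ~25% of null datasets. The ±3 SD band under the same
subsampling rejects ~8.6% (measured over 800 null datasets at
n = 30/group) — close to a conventional 5% level and the rule the
noise-band presentation implies. `significance_rule="ci"` restores the
percentile rule for users who combine it with `replace=True` (that
combination is calibrated at ~5%).

Zero-mean sham resamples in ratio mode are redrawn; more than 10%
redraws aborts the contrast.

## Spike metrics and classification

The ISI-violation metric is the percentage of inter-spike intervals
below 2 ms (curation threshold < 0.5%). SNR is waveform peak-to-peak
over the robust SD of the waveform's edge samples. The noise cutoff —
low-edge height of the spike-amplitude histogram relative to its mode
— requires per-spike amplitudes and reports 0 when only a mean
waveform is available.

Autocorrelograms count ordered spike pairs at lags in (0, 50] ms with
1 ms right-closed bins (an exact 5 ms lag lands in the (4, 5] bin),
verified against a brute-force all-pairs oracle. The burst index uses
raw count sums over the (2, 10] ms head and (35, 50] ms tail; for a
homogeneous Poisson train the flat-ACG expectation is
(8 − 15)/(8 + 15) = −7/23 ≈ −0.304, reproduced within ±0.01 at 10^5
spikes.

Classification standardizes trough-to-peak time, trough half-width
and log mean rate, embeds with PCA and splits with 2-means
(deterministic given the seed); the cluster with the smaller mean
trough-to-peak is labeled the putative PV-interneuron class. Identical
feature vectors or fewer than four units are refused with a
diagnostic rather than arbitrarily split.

## LFP analysis

Preprocessing decimates to 1 kHz (polyphase anti-aliasing) and
band-passes 1–475 Hz zero-phase. Artifact handling is caller-supplied
as a boolean mask; `default_artifact_mask` flags samples beyond 8
robust SDs. Spectra use K = 5 Slepian tapers at time-bandwidth 3 on
10-s segments (0.1 Hz grid), averaged over tapers then segments, and
are normalized to the mean over 1–90 Hz excluding 48–52 Hz; after
normalization that mean is exactly 1. The 4 Hz exclusion width is a
convention choice (only the 50 Hz center is dictated by the line
frequency); normalization averages linear power, not dB.

**Burst events.** The band-passed analytic envelope is compared, in
dB, with the band's background level (median envelope). Detection
runs on an envelope smoothed by a 3.5-period moving average: the raw
envelope of band-limited Gaussian noise exceeds 2× its median ~6% of
the time, which floods a median-referenced 6 dB threshold with
~1.6 events/s; the smoothing window was chosen from a measured
noise-floor/duration-bias tradeoff (683, 206, 64, ~35, 19 and 2
background events per 600 s at 1, 2, 3, 3.5, 4 and 6 periods) and
plays the role that long-window envelope conditioning plays in
published burst-detection toolboxes (the upstream parameters qlong,
qdrop, qglitch are recorded verbatim in the config for provenance but
their undocumented semantics are not reproduced). An epoch above the
2 dB boundary threshold becomes an event if it reaches 6 dB and lasts
at least one band-center period; epochs separated by less than half a
period merge. Event boundaries are then refined as the 2 dB crossings
of a one-period envelope (undoing the smoothing-induced widening) and
the peak time is the squared-excess centroid of that envelope, which
jitters far less than an argmax against background fluctuations.
Recovery on synthetic 10 dB beta bursts (100 in 600 s): count within
±16%, median duration within ±8%, median peak error 14–19 ms.

Event-aligned spectrograms use a complex Morlet wavelet with ~6
cycles (pywt `cmor1.8238-1.0`); each frequency row is normalized to
its own maximum per event before averaging. Band-power time courses
use Hann-windowed periodograms on sliding windows, normalized to the
mean over a declared baseline interval; power scales with amplitude
squared, so a doubled oscillation reads as 4.

## Synthetic data: what it emulates, and what it does not

PSC traces are sums of peak-normalized difference-of-exponentials
kernels at Poisson times with lognormal amplitudes, on a sinusoidal
(optionally random-walk) drifting baseline with white noise; EPSCs
are inward (holding −70 mV), IPSCs outward (0 mV) with slower
kinetics. Evoked trains follow a deterministic resource-depletion /
facilitation recurrence (release fraction u, resource R, recovery
τ_rec, facilitation increment and τ_facil) with additive measurement
noise. Spike trains are homogeneous Poisson (refractory-thinned) or
burst processes (Poisson onsets, geometric counts, jittered 5 ms
intra-burst ISIs). Waveform templates are two-Gaussian biphasic
shapes with trough-to-peak 0.3 ms (narrow) / 0.8 ms (wide); narrow
units fire ~15 Hz, wide ~3 Hz. LFP backgrounds are inverse-FFT 1/f^α
syntheses with randomized phases; bursts are Gaussian-envelope
sinusoids whose peak is calibrated in dB over the band's median
background envelope, with ground-truth boundaries at the envelope's
2 dB points. The generator's default burst amplitude is 10 dB:
because bursts add to the background with random phase, bursts
calibrated only 1–2 dB above the 6 dB detection threshold are pushed
below it by destructive interference a material fraction of the time,
and the default is meant to represent clearly supra-threshold events.

Not emulated: correlated (non-Poisson) synaptic input, series-
resistance filtering and its compensation artifacts, electrode drift
nonstationarity beyond slow drift, spike-sorting errors and waveform
collisions, spike–LFP coupling, volume-conduction structure, or any
mechanistic link between the modalities. Passing tests therefore
demonstrate correctness of the estimators under these statistical
models, not robustness to every pathology of real recordings.

Default problem sizes in the test and acceptance benchmarks (100-s
detection traces, 600-s LFP, 10^5-spike trains, 200 bootstrap
datasets, a 6-cell/condition demo study with 30-s traces at 10 kHz)
are chosen so each stage's sampling error is small relative to its
tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

- The bootstrap noise-band calibration (~8.6%) is moderately above
  the nominal 5% and is estimated with ±2% SE when checked over 200
  datasets, so individual calibration runs fluctuate.
- Detector recall is quoted at amplitude/noise = 5; smaller events
  are increasingly captured only by the multi-band method and vetting
  trims genuine events below 3 noise SDs.
- Burst duration/peak conventions are tied to the 2 dB boundary
  level; other toolboxes report different (e.g. half-maximum)
  conventions and will disagree systematically.
- The pipeline resamples at the cell level; hierarchical
  (cell-within-animal) structure is not modelled.
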