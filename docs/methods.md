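# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `orgephys`, and what the synthetic-data validation does
and does not establish about real recordings.

## Data model

Spike times are float64 seconds everywhere inside the package; sample
indices exist only at I/O boundaries (Kilosort-style directories carry
20 kHz sample indices, converted once on load). Positions are micrometres
with the origin at the array corner and x along the 3.85 mm axis of the
sensing area. Voltages are microvolts. Unit curation removes units with an
ISI-violation fraction above 0.3, a firing rate below 0.05 Hz, or an SNR
below 5 — strictly above/below, so values exactly at a threshold are
retained. The ISI-violation metric itself (violations of a refractory
window divided by total spikes) depends on a refractory window that
upstream sorters define differently; it is exposed as
`isi_violation_refractory_ms` (default 1.5 ms) rather than hard-coded.

## Synthetic recordings

The generator produces the statistical structure the estimators assume,
not biophysics:

* **Baseline firing** — per-unit gamma renewal ISIs (shape 1 = Poisson;
  large shapes approach periodic firing) warped through the integrated
  rate so a shared burst envelope modulates every unit. Defaults: 2 Hz
  baseline, Poisson shape.
* **Population bursts** — Gaussian rate bumps (σ = 50 ms) at times drawn
  with ≥ 1 s separation, 12 per minute, multiplicative gain 5. These sit
  on a substantial baseline, so the burst regime is milder than a
  silent-background culture: the 10%-of-peak extent rule then runs to its
  ±2 s search cap, and burst windows are wide. Each bump adds
  `gain·√(2π)·σ` seconds of extra rate, a closed form the tests verify.
* **Directed connections** — per source spike, an independent Bernoulli
  transmission (no synaptic depression) places a follower spike at a
  Normal(5 ms, jitter) latency truncated above 0.5 ms; a 2 ms absolute
  refractory period is enforced by deleting the later spike. Followers do
  not retransmit by default, keeping ground-truth directionality
  unambiguous (`allow_chaining` enables polysynaptic chains).
* **LFP** — per channel, a theta sinusoid whose amplitude is
  `baseline + depth × burst envelope` with a per-channel phase offset,
  over 1/f noise made by spectral shaping of seeded white noise. The
  generator gates theta *amplitude* on bursts; it does not phase-reset
  theta at burst peaks, so burst-anchored signal averages partially cancel
  by design — phase-reset inputs for testing the spread/average estimators
  are constructed explicitly in the tests.
* **Phase coupling** — spikes of coupled units are thinned with acceptance
  probability `exp(κ(cos(θ−µ)−1))`, so κ = 0 keeps every spike and the
  surviving spike phases follow a von Mises profile around µ.

Everything is driven by one integer seed; simulation is bit-reproducible,
and the pipeline's output tables are byte-identical across reruns with the
same configuration and seed.

What passing the synthetic suite shows: the estimators recover what was
injected under the stated noise model. What it does not show: robustness
to drifting electrodes, sorting errors (lost/merged units), non-stationary
firing, or LFP sources beyond a narrowband oscillation in 1/f noise.

## Estimator conventions and numerics

**ISI statistics.** The 8–100 ms ISI range filter and the 3-minute /
30-spike qualification are applied before µ, σ, CV and the exponential
fit alike (the filter can be disabled; note that it truncates an
exponential distribution and pulls the CV of Poisson firing well below 1,
so limit checks use the unfiltered CV). Histograms are normalized to unit
sum, not density; the amplitude parameter absorbs the scale. R² is
1 − RSS/TSS over binned values. Fits run at most 1000 function
evaluations at 1e−10 tolerance; non-convergence and degenerate histograms
(< 2 nonempty bins) are reported as failed fits, never exceptions.

**Population rate and bursts.** All smoothing kernels are unit-area
(Gaussian truncated at ±4σ), so total spike count is conserved except
within a kernel half-width of the trace edges. The burst threshold is
2× the rms of the full trace, bursts included — the simplest reading;
excluding bursts from the rms is left to the caller via `peak_factor`.
Burst-extent search is limited to ±2 s around the peak to prevent run-on
extents in data with a strong baseline. In the burst-pair similarity, the
5 ms moving average is applied before the 5 ms Gaussian (the order is a
free choice; both are near-commuting unit-area kernels).

**STTC.** Tiling windows are clipped to [0, duration]; the tiling fraction
uses an exact interval union. Pairs with an empty train are undefined
(NaN) and excluded. When P·T = 1 (a train tiles the whole recording and
every spike of the other is matched) the term is set to 1, the limit of
(P−T)/(1−PT) for identical dense trains. The implementation is required,
in tests, to match a brute-force oracle to 1e−12.

**Latency gating.** Latencies are nearest-spike, signed, measured from the
source train's spikes, within ±20 ms; the matching rule is one-directional
(the symmetric variant is a documented alternative). FWHM comes from a
1 ms histogram with linear interpolation at half the modal height. Pairs
with fewer than 10 matched latencies are unconnectable. The mean-latency
estimator carries a small negative bias under chance coincidences: spikes
without a true transmission still match a background spike with symmetric
near-zero latency, diluting the transmission cluster. At the validation
conditions (2 Hz baseline, bursts as above, p = 0.6 at 5 ms) the bias is
about −0.9 ms; recovery experiments therefore average several seeded
replicates when checking the ±1 ms recovery band.

**Dip test.** The dip statistic is computed exactly via the
greatest-convex-minorant / least-concave-majorant iteration; the test
suite validates it against an independent LP formulation of
"closest unimodal CDF" (mode at or between data points, an atom allowed at
the mode) and against the closed form 1/(2n) for an equally spaced sample.
p-values are Monte-Carlo against Uniform(0,1) nulls of equal n
(B = 2000, cached per size). Inside graph construction, where thousands of
distinct sample sizes occur, p-values come from a precomputed null table
over an n-grid with √n-scaling interpolation; the two modes agree to
within ~0.1 in p on random samples, far finer than the 0.1 gating
threshold's needs. Note that heavily tied samples (e.g. zero-jitter
latencies, which differ only by float dust) look discrete to the dip and
are rejected as multimodal — a property of the statistic, shared by
reference implementations.

**Edge-strength models.** Fits are least-squares on the binned fractions
with fixed bins (0.35–1.0, width 0.05); AIC uses the RSS surrogate
n·ln(RSS/n) + 2k because the fits are curve fits, not likelihoods.
Models needing k parameters require k+1 nonempty bins; failures are
excluded from ranking and flagged.

**Null models.** The burst-shuffle surrogate permutes the unit labels of
spikes within each burst window, leaving every spike time in place — the
1 ms population count vector is preserved exactly, which the tests assert
bitwise. The degree-preserving null performs 10×|E| undirected double
edge swaps and then reassigns each edge's direction uniformly at random;
strictly direction-preserving swaps could never change sender/receiver
classes, so the reassignment step is what makes the node-class null
informative.

**Filters and phase.** The band-pass is a windowed-sinc FIR (Hamming,
numtaps ≈ 3·fs/low-cutoff, odd, shortened when the trace is short),
applied forward–backward; zero group delay is asserted by checking that
in-band sinusoid peaks do not move. Phase is the analytic-signal angle,
0 at the oscillation maximum. The 10 µV theta floor masks samples by
envelope; electrodes with > 90% masked samples are dropped. Cross-
correlations z-score each channel on its valid samples, normalize each lag
by the number of jointly valid samples, and search ±2 periods; periodic
signals tie at full-period shifts, so the smallest |lag| among near-maxima
is reported.

**Imaginary coherence.** The imaginary cross-spectrum is assembled from
explicit real products (Im_i·Re_j − Re_i·Im_j) rather than a complex
multiply, so proportional channels give a bitwise-zero imaginary part
(FMA in the complex product otherwise leaves ~1e−18 residue; non-dyadic
amplitude scalings still leave FFT rounding at that level). The absolute
imaginary part is averaged over the band's frequency bins (the signed
variant is a one-line change); regional strength is the Fisher-Z mean of
each row. Pocket detection clusters the thresholded matrix's connection
profiles, not electrode coordinates; `min_connections` (200, chosen for a
~1000-electrode array) auto-scales with the electrode count when no node
passes.

**Rayleigh test.** z = nR² with Zar's finite-sample series for p. The
approximation is slightly conservative (~4.3% empirical type-I at
α = 0.05), which the calibration tests bound rather than correct.

**Classes and components.** Sender/receiver use strict > 0.8 imbalance;
isolated nodes (degree 0) are brokers so the three fractions always sum
to 1. Components are computed on the direction-ignored graph; the largest
and second-largest with ≥ 2 nodes are reported.

## Validation problem sizes

Recovery and calibration experiments run at desk scale, chosen to finish
in minutes on one core while leaving clear statistical margins: 50 units ×
300 s for network recovery (10 embedded edges, p = 0.6, 5 ± 2 ms), 1000
replicates for type-I calibration of the Rayleigh (n = 100) and dip
(n = 50) tests, 20 s sinusoid pairs for coherence invariants, 300 s ×
8 Hz units for phase-locking recovery, and a 12-unit / 80 s configuration
for byte-identical determinism of the full pipeline.

## Known limitations

* The mean-latency bias above is inherent to nearest-spike matching; a
  mixture-model latency estimator would remove it but is not part of the
  analysis this package reproduces.
* The dip null table assumes √n scaling between grid sizes; exact-n
  Monte-Carlo is available everywhere precision matters.
* `min_connections` and the 90th-percentile threshold interact on small
  arrays; pocket detection below ~30 electrodes is fragile and reports a
  warning path instead of clusters.
* The pipeline's external-data path consumes spike CSVs and LFP HDF5; raw
   20 kHz traces are supported only through `extract_lfp`, and spike
  detection/sorting are out of scope (the package consumes sorter output).
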