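# Methods

This note documents the models, numerical choices and limitations of the
`nanocoa` workflow: what each stage assumes, which parameters matter, and
what the synthetic-data experiments do and do not demonstrate.

## Signal model and simulator

A recording is modeled as an open-pore baseline current I₀ plus additive
white Gaussian noise, interrupted by translocation events: ideal square
pulses of depth ΔI and width Δt, shaped by the acquisition low-pass
filter. Per analyte class the generator draws

* event arrivals from a Poisson process with rate CF·c (CF in
  events·s⁻¹·μM⁻¹, concentration c in μM) — event rates scale linearly
  with concentration, which is also what makes count-based abundance
  estimation possible;
* dwell times from a log-normal distribution parameterized by its
  arithmetic mean and SD (in seconds);
* blockade depths from a normal distribution (pA).

Optionally a class carries within-event structure — a sinusoidal ripple
(amplitude, frequency, random phase per event) or extra in-event white
noise — used to emulate the shape differences between real molecular
species without changing the dwell/blockade marginals.

Events are placed by rejection-resampling of arrival times so that no two
events overlap (a 2 ms guard gap keeps flanking baseline clean for the
classifier input); configurations whose expected occupancy exceeds 50% of
the trace are rejected as infeasible. All draws come from one seeded
generator in a documented order, so identical seeds give bit-identical
traces and annotations.

Default acquisition constants: 500 kHz sampling, 100 kHz 4-pole Bessel
acquisition filter (applied zero-phase so ground-truth annotations stay
aligned with the rendered pulses), +120 mV bias annotation.

**Open-pore current.** The default is I₀ = 580 pA, the current expected
for α-hemolysin (~2.9 nS) in 3 M KCl at +200 mV. With the calibrated
blockade distribution ΔI ~ N(400, 30) pA this puts the in-event level at
180 ± 30 pA, far below the 65% detection threshold (377 pA), so detection
is clean: every simulated event is found exactly once. An alternative
sometimes considered — a baseline chosen so the relative blockade is only
~0.4 — places the in-event level within one SD of the threshold; the
depth distribution then straddles the threshold, a few percent of events
fragment into threshold-chatter pieces, and the extracted dwell
statistics are biased low by ~10%. No plausible noise level fixes that
regime, so it is not the default.

**Baseline noise.** Default 30 pA SD (white, pre-filter), i.e. ≈22 pA RMS
within the 100 kHz acquisition bandwidth and ≈8 pA after the 80 kHz
digital filter and decimation — a typical clean bilayer recording. At
this SNR the processing chain produces no false events on pure baseline
(measured false-positive rate < 10⁻³/s).

**Dwell-time defaults.** Only the cA₆ statistics are calibrated
(315 ± 26 μs at +200 mV in 3 M KCl). The cA₃/₄ and cA₅ defaults
(110 ± 40 μs, 180 ± 60 μs) are configuration, not truth: they reproduce
the qualitative dwell ordering cA₃/₄ < cA₅ < cA₆ that identifies the
stoichiometries. All classes share the blockade default 400 ± 30 pA,
reflecting that ring size changes dwell time, not blockade depth.

## Detection chain

1. **Digital low-pass**: 4-pole Bessel at 80 kHz, applied
   forward-backward (`sosfiltfilt`). Zero-phase application keeps event
   boundaries unshifted; the cost is a squared magnitude response, which
   the filter-attenuation tests account for explicitly.
2. **Median-conserving decimation** to 80 kHz: consecutive windows whose
   lengths follow the repeating pattern of the rational rate ratio
   (500→80 kHz ⇒ [6, 6, 6, 7], mean 6.25), one median per window.
   Medians suppress isolated outlier samples that a mean would smear.
3. **Open-pore estimate**: median of all samples above 80% of the trace's
   90th percentile. A high-quantile anchor is used rather than the global
   median because a median anchor cannot detect blockade-dominated traces
   (a majority of samples below 0.8× the median is impossible by
   definition of the median); traces with >50% of samples below the
   anchor are rejected.
4. **Event extraction**: maximal runs of samples strictly below 65% of
   the open-pore current; samples exactly at the threshold count as
   baseline; no hysteresis. Runs shorter than 2 samples (25 μs at
   80 kHz) are discarded as single-sample spikes. ΔI is the open-pore
   current minus the mean in-event current. The implementation is
   verified sample-for-sample against a brute-force threshold scan.

At the default conditions the chain recovers the configured cA₆ dwell
mean within ~1% (the residual is edge smearing by the filters, ~2 μs per
edge, partially cancelled by decimation quantization) and the blockade
mean within ~1% (in-event edge samples slightly reduce the measured
depth).

**Dwell summary statistics.** Histogram-level summaries use maximum
likelihood fits: log-normal for dwell times (closed-form MLE on log
durations, with the implied arithmetic mean/SD reported and a KS statistic
as a goodness summary), normal for blockades. The dwell time constant τ
is obtained by fitting S(t) = exp(−(t − t₀)/τ) (τ, t₀ free) to the
empirical survival curve by nonlinear least squares (initialized at
t₀ = min, τ = mean − min), repeated over 1000 bootstrap resamples; the
reported uncertainty is the SD of the bootstrapped τ. Resamples whose fit
fails to converge are dropped and counted; >10% failures is an error.

## Classifier

Input: 251 values per event — the event plus 47 flanking baseline points
per side, centered on the flank mean (so the offset between flanks and
event encodes the relative blockade), scaled by the segment SD,
zero-padded on the right to 250 points, plus the log₁₀ dwell time
z-scored by training-set statistics as the final feature. Events within
47 samples of a trace edge, longer than 156 samples, or with zero segment
variance are skipped with a logged warning and counted.

Architecture: conv1d(10 filters, width 25, ReLU) → batch-norm → dropout
0.2 → conv1d(10, 25, ReLU) → batch-norm → dropout 0.2 → max-pool(10) →
dense → softmax. The default class set is (cA₃/₄, cA₅, cA₆): cA₃ and cA₄
produce indistinguishable events in this assay and are merged; the output
dimension is configurable. The network is a self-contained numpy
implementation (im2col convolutions, hand-written backprop and Adam);
training a few hundred events for 100 epochs takes tens of seconds on one
CPU core, and identical seeds give bit-identical trained weights.

Training protocol: Adam at learning rate 10⁻³ on the cross-entropy loss,
100 epochs, minibatches of 32. Before every epoch minority classes are
oversampled with replacement up to the majority count (re-drawn each
epoch). Five random restarts are run and the one with the highest
training accuracy is kept; there is no early stopping or internal
validation split. Zero-padding positions are not masked in convolution.

Validation: k-fold cross-validation grouped by trace — events of one
trace never appear in both training and test folds, so trace-specific
characteristics (baseline level, noise realization) cannot inflate the
accuracy estimate. Fold partitions that leave a training fold without
some class are re-randomized (up to 20 attempts). The confusion matrix
reports relative prediction frequencies per ground-truth class,
mean ± SD over folds; overall accuracy pools all out-of-fold
predictions. The baseline comparator is a KNN (k = 3, majority vote,
ties broken by the nearest tied neighbor) on z-scored
(relative blockade, log₁₀ dwell) features.

## Quantification

Because event rates differ between classes at equal concentration, raw
counts are corrected: abundance_x ∝ count_x / (time · CF_x), normalized
to fractions. Correction factors are estimated from monodisperse
calibration traces as CF = events / (concentration × time), pooled per
class; their uncertainty is the SD over per-trace estimates (Poisson
√N-based for a single trace). The calibrated values shipped as defaults
are 0.17 ± 0.05, 0.62 ± 0.7 and 0.12 ± 0.3 events·s⁻¹·μM⁻¹ for cA₃/₄,
cA₅ and cA₆; note the latter two uncertainties exceed their values as
printed, which makes propagated yield bounds very wide.

95% prediction intervals for composition estimates are computed from the
k cross-validation fold models as mean ± t₀.₉₇₅,k₋₁ · SD of the per-fold
fractions — a t-based construction chosen because the fold estimates are
few and approximately exchangeable. Classes absent from the predictions
get fraction 0 with a degenerate interval.

Absolute yield per CRISPR complex:
(r_e · fraction_x / CF_x) gives the flow-cell concentration in μM
(events/s divided by events·s⁻¹·μM⁻¹); multiplying by the dilution
factor d and dividing by the complex concentration (μM) gives molecules
per complex. Any molar-to-molecule constant cancels in this ratio.
Uncertainties use first-order propagation with independent Gaussian
errors; shared inputs (r_e, d, complex concentration) are propagated
through the total's partial derivatives rather than summed per class.
With the calibrated inputs this reproduces ≈890 and ≈2860
molecules/complex for the type III-A and III-B examples.

LC-MS: mixture concentrations are (PA_mix / PA_mono) × 50 μM per
species, with monodisperse 50 μM solutions as calibration; ratios are
concentrations normalized to 100%. Peak detection/integration is out of
scope — input starts at tabulated peak areas.

## Statistics

Welch (unequal-variance) statistics throughout, since composition
estimates from different samples have no reason to share variances. The
difference test is the two-sided Welch t-test. Equivalence uses TOST: H₀₁
(μx − μy ≤ −δ) and H₀₂ (μx − μy ≥ +δ) are each tested one-sided at α;
equivalence is declared iff both are rejected, which is identical to the
(1 − 2α) confidence interval for the mean difference lying inside
(−δ, δ). The default margin for fraction comparisons is δ = 0.15, the
workflow's conservative resolution limit for population sizes. Degenerate
zero-variance inputs resolve by convention (equal means → p = 1 for the
difference test; |difference| < δ → equivalent) with a logged warning. No
multiple-testing correction is applied across class pairs; outputs say
so.

## Scaled experiment designs

The end-to-end experiments in `nanocoa.experiments` choose problem sizes
for single-CPU runtimes:

* `ca6_event_recovery`: one 40 s trace at the full 500 kHz rate with an
  arrival rate of 15 events/s (~600 events) — enough that Monte-Carlo
  error on the mean dwell is ≈0.3%.
* `correction_factor_recovery`: 600 s at 10 μM and CF 0.17 in twenty
  30 s chunks (chunking bounds memory; 300M samples would otherwise be
  held at once), ~1000 events, Poisson SE ≈ 3%.
* `mixture_recovery` and `cnn_vs_knn` run at a reduced 100 kHz
  acquisition rate (30 kHz acquisition filter, 25 kHz digital filter,
  decimation to 80 kHz) so that training-set simulation plus CNN training
  complete in minutes. Training uses 60 epochs × 2 restarts
  (`mixture_recovery`) and 30 × 2 (`cnn_vs_knn`).

The mixture construction uses dwell distributions 95 ± 25, 180 ± 35 and
330 ± 28 μs — ordered and adjacent-overlapping like the real classes —
plus a weak class-specific ripple (35 pA at 5/10/15 kHz) standing in for
the within-event shape differences a CNN exploits in measured events.
With it, the three validation mixtures (80:10:10, 50:40:10, 50:25:25 by
abundance) are recovered within the 15-point resolution limit, with
residual misclassification concentrated between adjacent classes. Two
caveats follow from the construction. First, fraction errors are
amplified by correction-factor ratios (a cA₅ event misassigned to cA₆ is
re-weighted by 0.62/0.12 ≈ 5), so mixtures whose rare class neighbors an
abundant one — 50:40:10 in particular — are intrinsically the hardest;
classes overlapping as strongly as the real calibration data can exceed
the 15-point limit on that design. Second, the ripple is a stylized
surrogate: passing these experiments shows the pipeline is correct and
the CNN can exploit event shape, not that real cOA events carry this much
shape information.

`cnn_vs_knn` makes the complementary point: with identical dwell and
blockade marginals and only within-event structure differing, the
two-feature KNN is at chance while the CNN is not.

## Known limitations

* The simulator is statistical, not biophysical: no electro-osmosis, no
  pore geometry, no capacitive transients, no baseline drift; events are
  isolated by construction (no overlapping translocations, no sub-state
  structure).
* The detector has no hysteresis; depth distributions that straddle the
  threshold fragment events (see the open-pore discussion above).
* Reported dwell times are quantized at the decimated 12.5 μs sample
  period; events shorter than 2 decimated samples are invisible.
* The stated "80 kHz (25 μs time resolution)" convention found in some
  descriptions is internally inconsistent (80 kHz sampling is 12.5
  μs/sample); this package follows the 80 kHz rate. Similarly a 47-point
  flank is 587.5 μs at 80 kHz, not milliseconds; the 47-point count is
  what is implemented.
* ABF (Axon Binary Format) input is not implemented; traces enter
  through the HDF5/CSV dialects or the simulator.
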