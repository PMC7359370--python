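# Methods

This note documents the models, parameter choices and numerical decisions
behind `caensemble`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic benchmarks do and
do not establish about real recordings.

## Event detection

**Input model.** The detector consumes non-denoised single-cell
fluorescence traces as produced by source extraction from miniscope video
(cells × frames, 15–20 fps acquisition). Traces are assumed to be a
quiescent baseline with approximately Gaussian noise, interrupted by
positive-going transients with fast-indicator kinetics (GCaMP6f-like:
linear rise ~0.1 s, exponential decay with half-time t_half = 0.2 s).

**Z-scoring.** The silent threshold is the pooled 0.50 quantile of all
fluorescence values in the FOV; each cell's silent timepoints are its
frames below that threshold. The per-cell centre is the silent-timepoint
mean *corrected for truncation*: for Gaussian baseline noise the
sub-quantile mean underestimates the baseline by `σ·φ(Φ⁻¹(F))/F`, where
`F` is the cell's silent fraction, so that amount is added back
(`truncation_correction=True`). Without the correction a mostly-quiet
trace is mis-centred by ≈ −0.8 σ, which floods the detector with
threshold crossings. The per-cell noise scale σ is the robust estimate
1.4826·MAD about the median (options: s.d. of silent points, or plain
trace s.d.), chosen because transients barely inflate the MAD. On pure
noise the resulting z-traces have s.d. ≈ 1 and mean ≈ 0.

**Rate conversion.** Z-scoring happens at the acquisition rate, where the
noise model is cleanest; the z-traces are then block-averaged to the 5 fps
analysis rate. Averaging suppresses analysis-rate noise by
`1/√factor` (σ₅ = 0.5 at 20→5 fps) while transients, wider than one
200-ms bin, largely survive — this is what makes a 2 s.d. amplitude
criterion usable at all: with unit white noise *at the analysis rate* the
same thresholds fire on ≈ 6 spurious envelopes per cell per 3 minutes.

**Amplitude on the native scale.** Block averaging attenuates a
transient's peak bin by a computable factor: averaging the reference
kernel into 200-ms bins and averaging over peak phase gives a peak-bin
value g₁ ≈ 0.69 and following-bin value g₂ ≈ 0.41 (`kernel_bin_profile`).
Event amplitudes are therefore estimated with the two-tap least-squares
template `(g₁·x_peak + g₂·x_next)/(g₁² + g₂²)`, which is unbiased on the
native amplitude scale and has better noise rejection than the raw peak
(effective noise 0.62 σ vs 0.72 σ per native unit). The 2 s.d. acceptance
threshold is applied to this estimate. On traces already at the analysis
rate (no downsampling) the raw peak is used unchanged.

**Envelopes and the duration rule.** A candidate transient spans a
contiguous supra-baseline (0.5 s.d.) run; a return to baseline is
confirmed only after 0.4 s (two analysis frames) below it, because
single-frame dips are common at σ₅ = 0.5 and should not split one
physical transient. Envelope duration is measured between linearly
interpolated baseline crossings, not as a frame count. The envelope is
accepted iff its template amplitude reaches 2 s.d. *and* its duration
reaches `t_half·log2(A/A0)` evaluated at the amplitude *as observed on
the analysis-rate trace* (envelope and peak attenuate together, so the
comparison is like-with-like). Within an accepted envelope, additional
rising peaks with prominence ≥ 1.5 s.d. (native scale) and separation
≥ 1 s are emitted as separate events; each event's time is its peak frame
time.

**Measured operating point** (default study conditions: amplitudes
N(4, 1) in noise-s.d. units, unit noise at 20 fps, 2 events/min): recall
0.90 and precision 0.93 against planted event times (0.6-s matching),
≈ 0.4 false events per cell per 180 s on pure noise. The residual misses
are ≈ 3% amplitude-limited (events planted near or below the 2 s.d.
threshold are undetectable by definition), ≈ 3% events closer than the
1-s peak separation, and ≈ 2% noise-truncated envelopes. Degenerate cells
(zero noise estimate, e.g. constant traces) are flagged and excluded as
empty trains rather than erroring, keeping FOV denominators intact.

## Correlation graphs

Event trains are binarized into half-open 1-s bins (occupancy, not
counts). Pearson's R is computed per pair; pairs with a constant series
(silent cells) are undefined and can never form edges. Two edge rules:

* **fixed** — edge iff R strictly > 0.3 (the conventional threshold;
  strictness matters only on exact ties);
* **shuffle / shuffle-bonferroni** — each cell's occupied bins are
  redrawn uniformly (event count preserved) 1000 times; the pair's
  threshold is the empirical (1−α) quantile, α = 0.05 or α/n_pairs.
  Because binary-raster R has a *discrete* null, a strict-quantile rule
  is conservative (measured rejection 0.015–0.03 at nominal 0.05 for
  realistic event counts). The builder therefore uses the randomized
  permutation test — p = (#{null > obs} + U·(1 + #{null = obs}))/(n+1),
  edge iff p ≤ α — which has exact size for discrete statistics. Tie
  randomization is seeded and can be disabled (`randomize_ties=False`)
  to recover the strict-quantile behaviour. Measured calibration:
  significant-pair fraction 0.048–0.052 at α = 0.05; Bonferroni
  family-wise rate ≈ 0.02.

Node metrics on the thresholded graph: correlated pair ratio
(degree / total cells in FOV — silent cells stay in the denominator),
clustering coefficient (0 when degree < 2), component membership
(component size ≥ 3), and the FOV-level component probability. These are
verified exactly against brute-force enumeration on 1000 random graphs.
A state-restriction mask (e.g. non-freezing bins; a bin is frozen iff
more than half of it overlaps a freezing interval) drops raster columns
before correlation. Analyses refuse FOVs with fewer than 20 cells unless
overridden.

## Stimulus-responsive cells

A cell is responsive to a window set (shock: onset→onset+6 s; tones: the
20-s periods, pooled; opto: the first 6 s of each 30-s pulse) iff its
pooled in-window rate exceeds the mean of a 1000-iteration timing-shuffle
null by 1 s.d. (uniform redraw of event times; circular shift available).
The 1-s.d. rule is deliberately permissive: on unmodulated Poisson cells
it flags the null's own upper-tail mass, ≈ 0.17 at the default rates, and
the implementation's false-positive rate matches that tail within
binomial error — the null model, not an arbitrary constant, sets the
specificity. Sensitivity is information-limited by in-window counts: at a
6-s window and 2/min background, a cell with a k-fold elevation can be
flagged at most `1 − exp(−k·0.2)` of the time (45% at k = 3), so
reliable detection requires burst-like responses; the generator plants
k = 15 (≈ 3 in-window events), for which measured sensitivity is ≈ 0.94.

The opto heatmap averages event-filtered activity (non-transient
timepoints zeroed, ±1 s around each peak kept) across LED onsets in
200-ms bins over [−6, +6) s, min–max normalizes over the whole matrix
(per-row option), and sorts rows by mean(ON) − mean(OFF).

## Ensemble partitioning and cohort statistics

Shock cells are classified in A1; the A2 graph defines their partners
(non-shock cells with ≥ 1 significant A2 edge to a shock cell); classes
are disjoint and exhaustive (shock cells are never partners). Per-cell
metric deltas are taken against A1 for cells tracked in both sessions.

**Partner-selection bias control.** Partners by definition have an A2
edge, which alone inflates their A2 metrics. The control resamples
size-matched sets from non-partners that also have ≥ 1 A2 edge (10,000
iterations) and reports the add-one empirical p,
`(1 + #{null ≥ obs})/(1 + n)`. Two caveats established on synthetic
nulls: (i) the partner class mean is positively biased *by construction*
even with fully independent activity — this is the bias the control
exists to absorb, so "partner deltas > 0" alone is never evidence;
(ii) under sparse graphs the control is slightly anti-conservative,
because cells with higher A2 degree are more likely to have a shock edge,
making real partners size-biased relative to the eligible pool (measured
~25% rejection at nominal 5% in an edge-sparse null). With exchangeable
partner labels the control is exactly calibrated (measured 0.05). Dense
FOVs reduce caveat (ii); it should be kept in mind when partner effects
are marginal.

**Freezing and regression.** Percent freezing is total merged-interval
time over the window. Across animals, the mean A2−A1 metric change of
{shock ∪ partner} cells is regressed on the change in % freezing (OLS;
slope, R², F on (1, n−2) df, two-sided p). The union class follows how
the per-FOV summary is defined; a class-restricted option exists.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions.
Per cell: homogeneous Poisson background (2 events/min default — typical
for ventral CA1 pyramidal cells). Planted ensembles are latent Poisson
sources (rate 6/min) whose events are copied into each member with
participation p and Gaussian jitter (0.2 s, keeping co-events mostly in
the same 1-s bin); amplitudes are drawn once per latent event and shared,
so a p = 1, jitter = 0 module yields identical trains. Shock cells run at
background × 15 inside the shock window (178–184 s of a 184-s A1; the
multiplier *replaces* the base rate there). Traces are rendered at 20 fps
with the linear-rise/exponential-decay kernel, amplitudes N(4, 1) in
noise-s.d. units (so the 2 s.d. criterion is exercised near threshold)
and unit white Gaussian noise.

The default FOV has 40 cells: 8 shock cells; one A2-only retrieval module
(4 shock + 8 non-shock members, p = 0.8) that models the
encoding→retrieval emergence of shock-partner ensembles; and eight
stable two-cell assemblies active in all sessions whose pairwise R sits
near the 0.3 threshold — they provide the baseline co-activity real FOVs
show (eligible cells for the bias control, flickering pair turnover) and
two of them involve shock cells so partner-like cells exist even without
a retrieval module. Cohorts (default 12 animals) spread freezing changes
evenly over 0.05–0.5 (fraction of session time); planted ensemble
strength is `0.5 × freezing_change + 0.1·ε`, and the retrieval module's
participation scales with strength, so regressing recovered deltas on
freezing change has a known ground truth. Freezing bouts (mean 8 s,
minimum 1 s) are placed at random non-overlapping positions and trimmed
to the target fraction exactly.

**What the benchmarks do not show.** The generator's noise is white and
Gaussian, transient kinetics exactly match the detector's reference
kernel, events are Poisson, and cross-session cell identity is perfect.
Real recordings violate all four (neuropil contamination, kinetic
variability, burstiness, registration errors), so the measured
recall/precision and recovery rates are upper bounds on real-data
performance, not estimates of it. What the benchmarks *do* establish is
internal correctness: the statistics are computed as specified, the
permutation machinery is calibrated, and planted effects of realistic
size are recovered through the full chain.

## Determinism and problem sizes

Every random stage takes an explicit seed; a fixed run seed makes the
full pipeline byte-identical across runs (seeds are derived through
`numpy.random.SeedSequence`). The default benchmark sizes — 520 cells
for detection recovery, 50 FOVs for edge calibration, 500 + 1000 cells
for the classifier, 50 runs for ensemble recovery, 200 replicates for
regression coverage, 12-animal cohorts — were chosen to keep every
Monte-Carlo standard error a few times smaller than the effect being
checked while the whole suite runs in minutes on one CPU.

## Known limitations

* No trace smoothing or deconvolution; heavily overlapping transients
  closer than the 1-s peak separation merge.
* The minimum-duration bracket is implemented as the decay time
  `t_half·log2(A/A0)`; other readings of the printed bracket are
  dimensionally inconsistent.
* The bias control's size-bias caveat (above) under sparse graphs.
* Cross-session identity is assumed given; no registration is performed.
* Timelines, not video, are the behavioural input; freezing scoring is
  upstream of this package.
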