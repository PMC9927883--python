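# Methods

This note documents the models, estimators and parameter choices behind
`eegsift`, the assumptions each one makes, and what the synthetic cohort
does and does not emulate.

## Scope and data model

The pipeline starts from *region-level* time courses: one matrix of shape
`[n_regions, n_samples]` per subject, nominally the 68 Desikan–Killiany
cortical regions sampled at 128 Hz for 5 minutes (38 400 samples).
Everything upstream of that — sensor-space preprocessing, artefact removal,
source reconstruction and parcellation — is out of scope; an EDF reader is
provided only as an ingestion convenience. Units are arbitrary: every
feature used downstream is either scale-free (relative power, LZC, PTE,
graph ratios) or z-scored before classification.

## Feature definitions

**Band power.** Signals are cut into 4-s epochs with 50 % overlap (149
epochs at the default length). Each epoch gets a single Hamming-tapered
periodogram (0.25 Hz resolution), log₁₀-transformed with floor 1e-20 so
silent bins stay finite. Absolute band power is the mean log-power over
the band's bins on the closed interval [f_low, f_high], averaged over
epochs; with the canonical edges (δ 2–3.75 … γ 30–44) the bands tile the
2–44 Hz domain without overlap. Relative power is computed on *linear*
power — in-band sum over 2–44 Hz sum, per epoch, then averaged — because a
ratio of log powers would depend on the arbitrary signal scale. The six
relative powers therefore sum to 1 per epoch. PSDs are taken from the
broadband signal with band-wise bin averaging; the Chebyshev band filters
are applied only where a band-limited *time course* is needed (LZC, PTE).

**Band filtering.** Chebyshev type-II band-pass, 40 dB stop-band, stop-band
edges 0.5 Hz beyond the band, applied forward–backward (`sosfiltfilt`) so
the phase response cancels exactly — a zero-phase path matters because PTE
consumes instantaneous phases. The default order is 12: at 128 Hz an
order-8 design leaves the passband edges several dB down (the six filtered
bands then recover only ~87 % of 2–44 Hz white-noise variance), while order
12 recovers ~99 % and still meets the stop-band spec. Order, ripple and
transition width are configurable.

**Lempel–Ziv complexity.** Per band and region, consecutive non-overlapping
20-s epochs (15 per recording). The analytic-signal envelope is compared
with its own epoch mean (each epoch self-normalizes, making the measure
invariant to positive rescaling); the resulting bit string is parsed with
the exhaustive-history LZ76 scheme, and the word count is normalized by
log₂(n)/n, the asymptotic rate of an i.i.d. fair-coin sequence, so values
are comparable across epoch lengths (random sequences sit near 1, strongly
rhythmic signals far below). Epoch values are averaged.

**Phase transfer entropy.** On 4-s *contiguous* epochs (75 per recording),
phases are the analytic-signal arguments of the band-filtered signals,
discretized into uniform bins over (−π, π]. For each ordered pair,
TE_{x→y} = H(y⁺, y) − H(y) − H(y⁺, y, x) + H(y, x) with plug-in entropies
(natural log, 0·log 0 = 0), clipped at zero and averaged over epochs.
Defaults: prediction delay 1 sample; **6 phase bins**. The bin count is the
one genuinely consequential choice: a rule tuned for 1-D histograms of long
recordings (e.g. exp(0.626 + 0.4 ln(n−1)) ≈ 23 bins at n ≈ 500) yields
12 000+ trivariate cells for 500 samples, and the estimator becomes
bias-dominated — unidirectional couplings are then recovered barely above
chance. Six bins keep roughly 2–3 samples per occupied cell and recover
planted coupling direction in ≥98 of 100 simulations. Both the bin count
and the delay are per-call configurable; the long-sequence rule is exported
as `otnes_enochson_bins`. Note the raw plug-in value carries a positive
finite-sample bias that *shrinks* with epoch length; the consistent
directional quantity is the contrast TE_{x→y} − TE_{y→x}.

**Information flow.** IF_O(i) and IF_I(i) are the row and column sums of
the PTE matrix excluding the diagonal; their grand totals are identical by
construction (each edge counted once per side), which the tests assert as
an exact identity.

**Graph metrics.** The directed weighted PTE network is proportionally
thresholded, retaining the top fraction of off-diagonal weights (weights
preserved, not binarized — strength and efficiency are meaningless on
binary graphs; ties at the cut are all kept, making thresholding
idempotent). The sweep runs 0.90 → 0.10 in 0.025 steps (33 points) and
metrics are arithmetic means over the sweep. Definitions: Fagiolo's
directed weighted clustering coefficient (geometric triangle intensity);
global efficiency from Dijkstra shortest paths on lengths 1/w (disconnected
pairs contribute 0); strength = node mean of in+out weight sums; modularity
of the symmetrized matrix (W+Wᵀ)/2; participation coefficients
1 − Σ_m (κ_im/κ_i)² in in- and out-strength form against the same
partition, node-averaged (zero-strength nodes contribute 0). The partition
maximizes Newman modularity exactly (exhaustive set-partition search) for
graphs of ≤6 nodes, and uses greedy agglomerative optimization above that —
exact search keeps the tiny-graph oracle tests bias-free, while the greedy
method is deterministic at scale. An entirely empty graph returns zeros
(modularity defined as 0, with a warning).

## Selection and classification protocol

1. **Screen** — per-feature equal-variance two-sample t-test, retain
   P < 0.05, uncorrected. Constant features are dropped with a warning.
   Under a null cohort this retains ~5 % of features by design.
2. **NCA weighting** — features are z-scored over the full sample and fed
   to diagonal (feature-weight) neighbourhood component analysis: weights
   w_r enter a weighted L1 distance Σ w_r²|Δ_r|, the objective is expected
   leave-one-out accuracy of the soft nearest-neighbour rule (kernel
   exp(−d/σ), σ = 1) minus λΣw_r² with λ = 1/n, optimized by L-BFGS.
   The fit is repeated (default 1000×) from random positive initializations
   on random 80 % subsamples; weights are averaged and features kept when
   the mean weight exceeds τ = 0.05 of the maximum (τ configurable — the
   retention rule is a relative-to-max cut because an absolute threshold
   has no natural scale). The chosen set is sanity-checked by repeated
   stratified 5-fold CV of a linear SVM (C = 1).
3. **Step-down** — greedy backward elimination: repeatedly drop the feature
   whose removal maximizes CV accuracy; stop when the best candidate falls
   more than 0.5 percentage points below the running best.
4. **Hold-out** — repeated stratified 70/30 splits (default 5000), linear
   SVM (C = 1) fitted per split; accuracies, TPR/TNR and confusion counts
   averaged. Per-class training counts use largest-remainder rounding with
   the floor of the overall 70 % total, which reproduces a 99/90 train and
   43/39 test split for 142 controls / 129 patients. "Positive" is the
   clinical condition (patients; high distress).

Z-scoring before selection uses the full sample, mirroring the protocol's
stated order; note this leaks distributional information across the later
hold-out splits, so reported hold-out accuracies are evaluations of the
protocol as specified, not leakage-free generalization estimates. The
distress contrast splits patients at TQ < 30 (low) vs. TQ > 38 (high),
excluding the mid-range.

## Synthetic cohorts

The generator replaces unavailable clinical recordings. Each region's
baseline signal is synthesized in the frequency domain: a 1/f^α background
(α = 1, above 0.5 Hz) carrying half the variance, plus one band-limited
stochastic oscillation per canonical band (Tukey-tapered spectral mask,
each 1/12 of the variance), standardized so baseline variance is 1.
Between-subject variability enters as log-normal amplitude jitter per
(subject, band, region), SD 0.2 in natural log.

Planted effects, per `EffectSpec` with standardized effect size d:

- *power* (abs/rel PSD): oscillation amplitude × exp(0.2·d). Because the
  planted shift and the between-subject spread are attenuated by the same
  background-dilution factor, the realized standardized difference of the
  extracted log-power feature tracks the requested d (recovered 1.5 ± 0.3
  in simulation).
- *complexity*: oscillation bandwidth × exp(±0.35·d) — broader band-limited
  noise has a less regular envelope and higher LZC.
- *coupling / information flow*: a delayed copy of the source region's band
  component added to the target (lag 8 samples ≈ 62 ms, coefficient
  0.25·d, so d = 2 gives the reference coupling of 0.5); `if_in`/`if_out`
  effects wire three partner regions into/out of the named region.
- Effects are carried either by the patient group (default) or by the
  high-distress stratum (`modulated_by="distress"`).

TQ scores are drawn from a three-stratum mixture (below 30 / 30–38 /
above 38) with default proportions 51:22:56 per 129 patients; ages and
gender proportions follow the cohort demographics of the study design
(controls 47 ± 17 y, patients 50 ± 15 y).

What the generator does *not* emulate: volume conduction and field spread
(synthetic regions are independent unless explicitly coupled, so PTE null
levels are cleaner than in real source-reconstructed EEG), artefacts,
non-stationarity across the recording, realistic spatial covariance, and
any physiologic link between distress and spectra beyond the planted
effects. Passing tests therefore demonstrate that the estimators and the
selection/classification machinery behave correctly and recover known
ground truth — not that the specific features would win on clinical data.

## Determinism and numerics

All randomness flows from integer seeds through `numpy` `SeedSequence`
spawning (one child stream per subject; per-stage seeds derived from the
pipeline seed), so identical configurations reproduce artifacts
bit-for-bit; HDF5 datasets are written with timestamps disabled for the
same reason. Numerical conventions: log floor 1e-20 for silent PSD bins;
TE clipped at 0; 1/∞ = 0 for disconnected efficiency pairs; zero-strength
nodes contribute 0 to participation; empty graphs return zero metrics with
a warning; the phase of an all-zero signal is an error.

## Problem sizes in the shipped checks

The test-suite and `scripts/acceptance.py` run the study protocol at
reduced scale — typically 2–8 regions, 24–60-s recordings, 10–48 subjects,
NCA/CV repetitions of 5–50 and 200–500 hold-out splits — chosen so the
full battery completes comfortably on a single CPU while every structural
constant of the full protocol (epoch counts 149/15/75, 33 sweep points,
2076-feature census) is still asserted exactly. `PipelineConfig` defaults
retain the full-study settings (68 regions, 300 s, 128 Hz, 1000 NCA and CV
repetitions, 5000 hold-out splits).

## Known limitations

- The plug-in PTE estimator is biased at 4-s epoch lengths; only
  comparisons (between directions, groups or conditions at fixed n) are
  meaningful, never absolute values.
- Exact modularity is exponential in n and only used for ≤6 nodes; larger
  graphs rely on greedy optimization, which can miss the optimum but is
  deterministic.
- Full-sample z-scoring before selection (see above) is faithful to the
  protocol but optimistic; a train-only scaler is the obvious variant for
  deployment studies.
- The NCA variant is the diagonal/feature-weight form; what the repetitions
  randomize (initialization and subsampling) is a design choice, as the
  protocol's repetition scheme is underdetermined.
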