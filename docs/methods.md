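# Methods

This note documents the models implemented in `arcnet`, the parameter
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Spike time tiling coefficient (STTC)

For spike trains A and B over a common recording of length D,

    STTC = 1/2 [ (P_A − T_B)/(1 − P_A T_B) + (P_B − T_A)/(1 − P_B T_A) ]

with T_X the Lebesgue measure of the union of ±Δt tiles around X's spikes
(clipped at the recording boundaries) divided by D, and P_X the fraction of
X's spikes within ±Δt of any spike of the other train.  Δt defaults to
50 ms, the standard choice for dissociated-culture data at this time scale.
The statistic is insensitive to firing-rate differences (verified by
simulation: independent Poisson pairs at 0.1 vs 1.0 Hz average to 0 within
±0.01 over 200 seeds) and equals +1 for identical non-degenerate trains.

Undefined pairs — either train empty, or a denominator 1 − P·T within 1e−12
of zero — are stored as NaN in adjacency matrices and excluded from all
means and classifications; they contribute 0 to node strengths ("total
flow").  Fabricating zeros in means would bias group comparisons, so
missingness is propagated instead.  The diagonal is always excluded.

Implementation: tiles are unioned by a single sorted sweep; nearest-spike
distances use binary search.  Both are checked against independent oracles
(a 1 ms fine-grid measure for T on millisecond-aligned trains, an O(n²)
min-distance loop for P) to 1e−6.

## Correlation-change classification

A pair is a *positive-change* correlation when its CI moves from [0, 0.5)
at baseline into [0.5, 1] after stimulation, and a *negative-change*
correlation under the mirrored rule ([0.5, 1] → [0, 0.5)).  Band edges are
closed on the high side, as written.  The Arc–Arc pair fraction is reported
against a CI threshold grid, using the final CI for positive-change pairs
and the initial CI for negative-change pairs.

## Intrinsic Connectivity Distribution (ICD)

Node strength is the sum of incident CIs with negative values floored at
zero (survival analysis of a signed quantity is ill-posed; negative CIs are
retained everywhere else), normalised by n − 1 so strengths lie in [0, 1].
The survival curve s(τ) — the fraction of nodes with normalised strength
above τ — is fitted with a stretched exponential

    d(τ) = exp(−α τ^β),   α, β > 0

by bounded nonlinear least squares (trust-region reflective, x0 = (1, 1),
tolerances 1e−10).  The ICD *difference curve* is the baseline fit minus
the after fit on a common τ grid, so a global CI decrease yields a positive
peak; differencing the fits rather than the empirical staircases removes
grid noise (an empirical option exists).  The default τ grid is 201 evenly
spaced points on [0, 1]: weakly correlated networks concentrate all
strengths below ~0.06, and a coarser grid can leave too few interior points
for a stable fit.

The difference curve is summarised by: peak height (global maximum), peak
location (its τ), width at half-peak height (outermost linearly
interpolated crossings of height/2, clamped to the grid ends), and the
trapezoidal AUC of the positive part.  A culture is *refined* when width
≥ width_min AND peak location ≥ location_min.  No universal thresholds
exist for this rule; the shipped defaults (width_min = 0.07,
location_min = 0.05) were calibrated once on the synthetic benchmark, where
refined cultures span widths 0.094–0.212 and non-refined ones stay below
0.046, and are always overridable.  AUC is computed and reported but not
used in the classification rule — on the benchmark (as in the motivating
data) it separates the classes less reliably than width and location.

## Mixture thresholding

Marker positivity is decided per channel and per culture.  A two-component
1-D normal mixture is fitted by EM (median-split initialisation, 1e−6
log-likelihood tolerance, ≤500 iterations, variance floor at 1e−6 of the
data SD); components are ordered by mean and the positivity cut is
μ₋ + 3σ₋, i.e. above 99.7% of the negative population; comparisons are
strict (ties are measure-zero).  The EM is implemented in-package because
the per-iteration log-likelihood trace is part of the tested contract
(monotone nondecreasing); sklearn's `GaussianMixture` and a direct
multi-start ML optimisation serve as independent cross-checks in the test
suite.  Collapsed fits (component means within one SD) trigger a warning
rather than an error: unimodal channels occur in degenerate scenarios and
the caller decides.  Fitting is per-culture; pooling across cultures would
mix staining batches with different gains.

## Trace correction and spike inference

The background at each frame is the mean raw fluorescence of the
least-active 10% of cells (activity = temporal variance of the raw trace;
silent cells track the shared background and photobleach).  With 20 cells,
exactly 2 define the background.  After subtraction, traces are normalised
to ΔF/F with F0 the per-cell 10th percentile of the subtracted trace; when
F0 is numerically zero (a silent cell) the divisor falls back to 1 so the
trace remains a plain subtraction instead of blowing up.  A
`subtract_only` mode stops at the subtraction for workflows that treat the
subtracted trace itself as the activity signal.

Spike inference maximises the MAP objective of an AR(1) calcium model with
Gaussian noise and a sparse nonnegative spike prior:

    min_{s ≥ 0}  1/2 ‖y − K s‖² + λ ‖s‖₁

where K is the AR(1) impulse-response convolution (decay γ per frame; the
default γ = exp(−0.2) corresponds to a 1 s decay constant at 5 Hz).  The
problem is solved by accelerated projected gradient (FISTA), which is
equivalent to coordinate-wise descent on the same objective but fully
vectorised; λ = sparsity_weight · σ̂ · ‖k‖₂ with σ̂ a robust
first-difference noise estimate, so λ → 0 on noiseless traces and the
solve becomes an exact nonnegative least squares.  Spike mass above 10% of
its maximum is discretised to spike times at frame centres.  On the test
conditions (0.2 Hz Poisson spikes, 60 s at 5 Hz, amplitude/noise = 10) the
inference reaches F1 ≥ 0.8 against ground truth within ±1 frame, and
localises noiseless impulses exactly.  Firing rate is spike count over
recording time; per-neuron normalized changes ((r_epoch − r_base)/r_base)
are averaged per network, excluding neurons silent at baseline (logged).

## Peak detection and segmentation

Network-level transients are local maxima of the summed trace passing a
prominence of twice the MAD-based robust SD and a 5-frame separation —
explicit, portable defaults for an otherwise tool-specific step.  Nuclei
segmentation is a global Otsu threshold, connected components, and an area
filter of [50, 5000] px, with no watershed splitting: the synthetic
fixtures are non-touching, and the stage is deliberately simple and
swappable.  Coordinates are 0-based with x = column, y = row; ROI masks are
stored as label images.

## Synthetic cultures: what they emulate, and what they don't

The generator produces fields of ~10²–10³ cells (default 100 neurons plus
15% silent non-neuronal nuclei) in a 1007 × 1007 px frame (0.8 μm/px,
0.64 mm²), recorded 60 s at 5 Hz at three epochs.  Network bursts are a
homogeneous Poisson process (0.3 Hz); each neuron joins a burst with a
per-epoch participation probability, emits one spike jittered by 20 ms SD,
and fires independent background spikes (0.2–0.3 Hz).  Participation is the
correlation dial: pairwise STTC is monotone in it.  The same neurons
persist across epochs; only participation and background change.

Two culture types define the benchmark.  *Refinement* cultures start
well-synchronised (participation 0.5) and collapse to 0.15 after
stimulation except for the designated refined subset, which rises to 0.95;
the refined set coincides with the Arc⁺ truth set and its nuclei are placed
inside a 150 px cluster.  *Non-refinement* cultures start weakly
synchronised (0.22) and barely change (0.18) — mirroring the interculture
variability of initial correlation states seen in real preparations, where
little-changing cultures are the ones not called refined.  Marker
intensities are bimodal normals (negatives N(100, 10²), positives
N(300, 20²)); 16.2% of neurons express Arc and/or c-Fos and 82.7% of Arc⁺
cells are also c-Fos⁺, the reported cell-population proportions, used here
as generator defaults.

Deliberately not modelled: biophysical neuron or GCaMP dynamics beyond the
linear AR(1) transient, excitatory/inhibitory cell types, burst-internal
spike structure (one spike per burst per neuron), staining-intensity
spatial gradients, and touching nuclei.  Passing tests therefore
demonstrate correctness of the analysis chain under a known generative
model with realistic magnitudes — not robustness to every artefact of real
recordings (overlapping nuclei, non-stationary noise, slow drifts beyond a
shared exponential bleach).

During stimulation the generator raises both burst participation and
background rate, so firing rates rise while correlations begin to fall; in
the post-stimulation epoch of refinement cultures the bulk network trades
burst spikes for background spikes, leaving rates roughly flat — the
dissociation between rate and correlation is the property the benchmark
preserves, not any particular rate magnitude.

## Cohort regression

The stepwise linear model regresses the per-culture Arc-positive fraction
on candidates {firing rate initial/final/change, network CI
initial/final/change, refinement status}.  Selection is forward/backward by
partial-F p-values with p_enter = 0.05 and p_remove = 0.10 (the documented
defaults of the tool family this emulates); perfectly collinear candidates
are never co-selected.  OLS fitting is statsmodels; the selection loop is
in-package.  The regression benchmark generates n = 17 cohorts from
arc% = 1 − 0.269 · final CI + 0.250 · refinement + N(0, 0.05²) and requires
both terms selected with coefficients within 3 SEs in ≥90% of replicates.
(The source material for this benchmark prints the model line with
coefficient −0.269 but an estimate-table row of −0.0269; the benchmark uses
the model-line value and does not attempt to resolve the discrepancy.)

## Problem sizes and benchmark scaling

The refinement-recovery benchmark runs 50 cultures (25 refined / 25 not) of
100 neurons with the pipeline consuming the generator's ground-truth spike
trains directly; deconvolution accuracy is benchmarked separately per
trace, and the full image → segmentation → extraction → deconvolution chain
is exercised end-to-end on single cultures.  This keeps each stage's
benchmark focused on its own error source: classification accuracy is a
property of the STTC/ICD stages, not of spike inference, and mixing the two
would blur attribution.

## Known limitations

- The refinement thresholds are benchmark-calibrated, not universal; real
  cultures need their own calibration or visual verification.
- The stretched-exponential fit is unweighted least squares on the survival
  curve; no uncertainty is propagated to the difference-curve metrics.
- The ΔF/F reading of "background-subtracted" traces is one of two
  defensible conventions; both are exposed (`dff_mode`).
- Change classification uses fixed CI bands at 0.5; pairs hovering at the
  band edge flip class under small perturbations.
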