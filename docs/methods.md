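# Methods

## The measurement and the identification problem

A single-molecule break junction (SMBJ) experiment repeatedly forms and
breaks a metal–molecule–metal contact: an STM tip is driven into a gold
substrate until the current saturates the preamplifier (~100 nA) and
retracted until the current reaches the noise floor (~10 pA), recording
current versus time for each pull. When no molecule bridges the gap the
retraction current is a bare tunneling signal — a predominantly
exponential decay. When a molecule binds, the trace shows steps and
plateaus at molecule-specific conductance levels. Aggregated over many
valid pulls, the log-conductance histogram of a molecular species is a
reproducible fingerprint, and the identification problem is: given a
histogram built from a modest number H of valid traces, decide which of
a known panel of species (here, short DNA/RNA duplexes and controls)
produced it.

## Signal conditioning

Each raw current trace passes through a fixed chain:

1. **Clipping** to the preamplifier window [10 pA, 100 nA]. Values
   outside this range are electronics artifacts, not signal.
2. **Validity test.** A pure exponential `I(t) = a·exp(−t/τ)` is fitted
   by ordinary least squares of `ln I` on `t` (tunneling decay is exactly
   linear in log-current, so the fit is closed-form and deterministic),
   and the coefficient of determination R² of that fit is computed in
   log space. A trace is **accepted as valid iff R² ≤ β** (default
   β = 0.95): a near-perfect exponential fit means no molecule was
   captured. The fit uses no additive offset; amplitude and τ are
   reported for audit but unused downstream. A zero-variance log trace
   (flat line) is defined to have R² = 0 — it is the least
   exponential-like signal — with a small numerical floor on the total
   sum of squares so that float rounding in a constant trace cannot
   masquerade as variance.
3. **Low-pass filtering** with a zero-phase 4th-order Butterworth
   filter (forward–backward), cutoff at 60 % of the folding (Nyquist)
   frequency: 9 kHz for 30 kHz acquisitions, 3 kHz at 10 kHz.
   Zero-phase filtering preserves plateau edge positions. Filtering may
   overshoot slightly outside the clip window near sharp steps; values
   are converted as-is (non-positive values, if any, fall into the
   trimmed guard bin downstream).
4. **Linear interpolation** by an integer factor, used to bring a
   10 kHz acquisition to the common 30 kHz effective rate (factor 3).
5. **Conductance conversion** `G/G₀ = I / (V_bias · G₀)` with
   G₀ = 2e²/h = 7.748 × 10⁻⁵ S.

## Featurization

Conductance samples of H valid traces (default H = 30) are pooled and
counted into `n_bins` bins (default 600) spaced uniformly in
log₁₀(G/G₀) over [−7, 0]. The range covers every conductance reachable
inside the preamplifier window at the study's bias voltages
(0.01–0.30 V); it is a package choice, as is log spacing (conductance
histograms are peaked on log axes). Out-of-range and non-positive
samples are absorbed into the two terminal bins; those bins collect the
spikes that clipping piles up at the window edges and are therefore
dropped, leaving a feature vector of length `n_bins − 2` (598 at the
default) which is renormalized to a probability simplex after trimming.

Design matrices are built by drawing `N_hist` histograms per target
class (defaults 700 train / 300 test). Dataset labels that a labeling
scheme maps to the same class are merged into one trace pool before
drawing, so e.g. the six-class by-strand scheme over ten datasets gives
6 × 700 = 4200 training rows. Within one histogram the H member traces
are drawn uniformly without replacement; across draws, traces are
reusable. Per-trace bin counts are precomputed once so a draw is an
integer sum — numerically identical to pooling raw samples (the
count-mixture property is tested). Train/test splits are made at the
trace level, per class, so no trace contributes to histograms on both
sides.

## Classification

The primary model is an XGBoost gradient-boosted tree ensemble with
deliberately shallow settings: 200 trees of depth 2, shrinkage 0.3
(library default), softmax cross-entropy objective, single-threaded and
seeded for reproducibility. An exhaustive validation grid search over
tree count and depth is provided (grids 10–700 trees, depths 1–20, ties
broken toward the smaller model).

Evaluation follows a repeated-random-split protocol: for each repeat, a
fresh 70/30 trace split, fresh histogram sets, training, and a
confusion matrix on the test design. Confusion counts are summed across
repeats; per-class and overall accuracies are means of per-repeat
values. `mean_predict_time` is recorded for information only — it is
hardware-dependent and never asserted.

**Tandem architecture.** Two classes that differ by a single base
mismatch produce nearly identical fingerprints and dominate the
multiclass error. The tandem classifier routes them through a second
stage: whenever the multiclass stage predicts a member of the routed
pair, a binary RBF-kernel SVM trained only on that pair makes the final
call; predictions outside the pair are never modified. Stage 2 reuses
the stage-1 histogram features, standardized per bin on its own
training rows, with the kernel scale set by the median heuristic
(γ = 1/(2·median² pairwise distance)) — the scale-sensitive RBF kernel
needs both choices, and neither is data-peeking (both are computed on
the training fold only). Routing is by stage-1 *prediction*, not by
ground truth.

## Synthetic trace generator

The experimental corpus the pipeline was designed around is not
publicly deposited, so the package ships a simulator that reproduces
the two trace phenotypes with known ground truth:

- **Invalid traces**: `I(t) = I₀·exp(−t/τ)` from just below saturation
  (I₀ = 90 nA), multiplied by log-normal noise (default 0.05 decades),
  clipped to the preamp window. Default τ = 0.1 s over a 0.5 s trace
  (~5 e-folds, staying above the floor clip).
- **Valid traces**: the same background interrupted by
  max(1, Poisson(2)) plateaus; each plateau's log-conductance is drawn
  from the class's lognormal mixture (centers/widths in decades), its
  current is G·V_bias, and its duration is uniform in 5–40 % of the
  trace. A trace is valid with probability p (`plateau_prob`), directly
  instantiating the H/p experiment-budget formula.

Ten presets mimic the acquisition design of a ten-dataset duplex study:
the study's bias voltages, 30 kHz sampling (10 kHz for S10), a control
with a single pronounced low-conductance peak (placed at 10⁻⁵ G₀), a
near-identical pair whose signatures differ by one peak center
(0.15 decades, the single-mismatch analog), same-strand datasets
sharing a common motif, and an overlapping pair/singleton structure.
Peak placements are illustrative, not fitted to measurements: passing
tests demonstrate that the *pipeline* recovers whatever class structure
the generator encodes, not that the generator is spectrally faithful to
any real molecule. Real SMBJ data additionally contains drift, tilted
plateaus, multi-level noise and contact-geometry variability that the
simulator does not model.

## Canned studies and their problem sizes

Three end-to-end studies are exposed as functions (and recomputed by
`scripts/acceptance.py`):

- **Parameter recovery**: 3 single-peak classes with centers at −5.5,
  −4.0, −2.5 (≥ 1 decade apart), 400 traces/class, p = 0.8, baseline
  conditioning and classification, 700/300 histograms, 10 repeats.
  Expected: ≥ 99 % mean overall accuracy. Pool size matters here:
  with ~5× fewer traces or ~4× fewer training histograms the protocol
  shows genuine train/test distribution shift within a class (each
  side's plateau-level sample is small enough for the boosted trees to
  overfit one side), the same data-scarcity failure mode that harsh
  filtering produces in practice. The chosen sizes reflect the scale
  of a real corpus while staying desk-runnable.
- **Tandem comparison**: 4 classes, routed pair offset 0.15 decades
  with 0.2-decade widths, 300 traces/class, 300/150 histograms, 10
  paired repeats (both architectures see identical splits, draws and
  stage-1 models).
- **Chance-level control**: all classes share one signature, so labels
  carry no information. The split protocol is *not* used for the null:
  a finite per-class pool has an idiosyncratic fingerprint (its
  particular plateau-level draws) shared by every histogram built from
  it, making within-class predictions perfectly correlated — the
  observed accuracy then swings far above or below 1/k and the
  binomial error model is invalid. Instead the trained model is scored
  on histograms drawn from a single shared pool of fresh traces with
  round-robin labels; features are then independent of labels and the
  hit count is exactly Binomial(n, 1/k), so a 3-standard-error band
  applies. This is a property of repeated-split protocols worth
  remembering when interpreting real-data accuracies: the protocol
  certifies discrimination of *trace pools*, which equals class
  identity only insofar as the pools are representative.

## Numerical choices and degenerate inputs

- R² is clamped to [0, 1]; acceptance is the exact comparison
  R² ≤ β, no tolerance.
- Binning uses floor((log₁₀v − low)/width) with index clamping, so
  edge values and out-of-range values are deterministic; a histogram
  whose interior bins are all empty raises rather than returning NaN.
- Splits use `round(train_fraction · n)` and refuse empty sides.
- Sweep rows whose swept value leaves a class with fewer than H valid
  test-side traces are flagged (`status` column) rather than fatal —
  with harsh β, data scarcity is an expected outcome.
- Grid-search ties break toward fewer trees, then shallower trees.
- All randomness flows through `numpy.random.default_rng` seeds;
  XGBoost runs single-threaded with a fixed seed, making every
  reported number bit-reproducible.

## Known limitations

- The simulator's plateaus are flat segments with multiplicative
  noise; real plateaus slope, fluctuate between levels, and correlate
  with tip displacement (not modeled; no 2-D conductance–displacement
  histograms).
- Preset signatures are qualitative. No claim is made that accuracies
  on the synthetic presets transfer to the corresponding real
  datasets.
- The tandem stage-2 feature space and kernel parameters are package
  choices; only the architecture (multiclass stage re-decided by a
  pair-specific binary stage) is inherited from the study design.
- β is global; per-class thresholds are left to user-driven sweeps.
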