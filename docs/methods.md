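# Methods

This note documents the models, conventions and numerical choices behind
striatype, in the order data flows through the pipeline.

## Recording model and quality control

A recording is one cell's set of current-clamp sweeps under a rectangular
step protocol: 1 s steps from −200 to +200 pA in 50 pA increments, with
200 ms of zero-current baseline before and after the pulse. Units are fixed
package-wide (mV, pA, s for durations, Hz for rates). The acquisition rate is
not dictated by the protocol; the package default is 20 kHz, a typical
current-clamp rate, and everything downstream reads the rate from the file.

Quality control excludes a cell when any of three criteria fails, and lists
*all* failing reasons:

* series resistance > 25 MΩ (amplifier-reported; `rs_unknown` is recorded
  when absent and the other checks still run);
* resting membrane potential more depolarized than −50 mV, i.e. the signed
  baseline mean exceeds −50;
* baseline fluctuation > 10%. The source criterion does not define the
  measured quantity; we use the coefficient of variation of per-sweep
  baseline means across sweeps, with |mean| in the denominator because
  baselines are negative. The threshold and the quantity are configurable.

QC is monotone by construction: relaxing every threshold can only turn
failures into passes (property-tested).

## Ground-truth generators

Three generators provide synthetic data with known answers; they are
first-class, tested code, not fixtures.

**AdEx simulator.** The adaptive-exponential integrate-and-fire model
(C dV/dt = −g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) − w + I;
τ_w dw/dt = a(V−E_L) − w) is integrated with fixed-step explicit Euler at
dt = 0.05 ms (finer if the sampling interval demands it; the sampling grid is
always an integer decimation of the integration grid). When V reaches the
detection ceiling `V_cut`, a spike is logged, the recorded sample nearest the
spike time is stamped at `V_cut` (so downstream detection has a peak to
find), V resets and w increments by b. The exponential argument is clipped
at its value at `V_cut`, which bounds the blow-up step without affecting
subthreshold dynamics. Measurement noise is additive white Gaussian on the
recorded samples only, so noise never changes the dynamics and ground-truth
spike times remain exact. Verification: with a = b = 0 the trace matches the
closed-form RC response within 0.1 mV, and spike times track an independent
scalar integration at half the step within ~0.1 ms per spike (tests allow a
cumulative 1 ms-per-spike envelope, since Euler spike-time error grows
linearly with spike index).

Three shipped presets (`msn`, `thin`, `fan`) are *illustrative* phenotypes —
hyperpolarized/high-rheobase, depolarized/low-rheobase, and strongly
adapting — chosen so each expresses its phenotype inside the ±200 pA
protocol. They are not fits to published per-type measurements (those are in
a companion dataset not available here). The `fan` preset uses
τ_w = 3000 ms ≫ pulse duration so spike-triggered adaptation accumulates
monotonically through the sweep and the ISI sequence strictly increases.

**Analytic AP composer.** Piecewise-linear spike trains whose amplitude,
half-width (= (rise+fall)/2 for linear flanks), AHP depth, maximal slopes
and adaptation ratios are exact closed forms. One deliberate deviation from
a naive sketch: during the pulse the trace sits on a depolarized inter-spike
plateau (default threshold − ahp_depth/2) rather than returning to resting
baseline. A resting return would put the post-spike minimum at baseline
whenever baseline lies below the AHP trough, making the stated AHP
unmeasurable; real cells under suprathreshold current likewise sit
depolarized between spikes. The lead ramp into each spike stays below the
detection criterion so threshold localization is well-posed.

**Feature-table sampler.** Each class is an independent Gaussian over the 12
features. The shipped benchmark (`presets/benchmark.yaml`) encodes plausible
whole-cell values per class with every class pair separated by ≥ 3 pooled
SDs on ≥ 3 features. What a green classifier gate establishes: the training
machinery (stratified folds, leak-free standardization, the 13-unit
architecture) realizes the separability present in the benchmark. What it
does not establish: performance on real recordings, where features are
correlated, heavy-tailed and occasionally missing — none of which the
sampler emulates.

## Feature extraction

Definitions are package defaults, each overridable and recorded with the
output; the authoritative upstream definitions are not published alongside
the source protocol, so ours are declared, not attributed:

* spike detection: first sample where 3-point-smoothed dV/dt ≥ 20 mV/ms
  before each peak; 2 ms refractory; sub-10 kHz sweeps warn;
* amplitude is threshold-to-peak; half-width at the threshold/peak midpoint
  with linear interpolation of both crossings; AHP is threshold-to-trough
  within 50 ms post-peak (bounded by the next spike); max fall rate is
  reported as a positive magnitude;
* passive features: R_in from the least-squares slope of steady-state ΔV
  (last 100 ms of the pulse, relative to each sweep's own baseline) vs
  current over non-spiking steps; τ from a single-exponential fit to the
  first 300 ms of the −50 pA onset; C = τ/R_in; sag = V_steady − V_min on
  the −200 pA sweep, clipped at 0;
* adaptation ratios on the smallest step with ≥ 10 spikes; when no step
  reaches 10 spikes both are NaN with `adaptation_defined = False`.

Missing-feature policy: NaN plus a boolean flag, never silent omission.
Downstream clustering excludes incomplete rows by default; the pipeline can
median-impute instead (its default, so adaptation-undefined cells still
appear in every output).

## Unsupervised analysis

Features are z-scored (sample SD, ddof = 1); PCA is computed by SVD with a
deterministic sign convention (largest-|loading| entry positive per
component); the default projection keeps 3 components and reports their
cumulative variance. The source protocol names neither linkage nor metric;
we default to Ward on Euclidean distances in PC space, both configurable and
echoed into every output. Cluster number is chosen by mean silhouette over
k = 2…10, ties toward smaller k, singletons scoring 0. Note that z-scoring
normalizes by *total* spread (between- plus within-cluster), so a separation
stated in within-cluster SDs is diluted by standardization — the cluster
acceptance checks therefore run in the generator's own coordinates.

## Classifier and explanations

A 12 → 13 (logistic) → 3 (softmax) network, trained with full-batch L-BFGS,
L2 penalty 1e−3, ≤ 500 iterations (all unstated upstream; recorded in model
metadata). Accuracy is estimated by stratified 10-fold cross-validation with
the standardizer fit on each training split only; both pooled accuracy
(total correct / n, our headline number) and the per-fold mean are reported,
since the upstream aggregation is ambiguous. The deployed model is refit on
all rows and serialized as a plain JSON weight container, so inference has
no training-backend dependency.

Explanations follow the tabular local-surrogate recipe: ~5000 unit-variance
Gaussian perturbations around the standardized instance, scored with the
model's probability for the predicted class, kernel-weighted by
exp(−d²/w²) with w = 0.75·√12, then a weighted ridge fit (penalty 1e−3).
Signed coefficients are the feature weights; the weighted R² is reported as
local fit quality. On an exactly linear probability model the surrogate
recovers the coefficients (tested to 2e−3).

## Morphometrics

SWC trees are validated strictly (unique ids, single root, parents before
children, positive radii). The 23 global features follow the conventions
common to whole-neuron metric suites — frustum lateral surface/volume per
segment, branches as maximal unbranched paths between root/bifurcations/
tips, contraction = euclidean/path per branch, Van Pelt partition asymmetry —
but the exact upstream list is unrecoverable, so ours is a declared,
documented approximation. Two conventions worth flagging: a branching soma
root counts as a bifurcation (so a depth-2 symmetric binary tree has 3), and
overall width ≥ height ≥ depth are extents along the node cloud's principal
axes, making all 23 features invariant to rigid motion (tested to 1e−9).
Sholl intersections count edges whose endpoint distances straddle each
concentric sphere (min < r ≤ max, spheres centered on the soma centroid,
default step 10 µm); a chord passing through a sphere between two interior
endpoints is not counted — impossible for straight segments, by convexity.
All 23 features and the Sholl counts are cross-checked against an
independent graph-library-based re-implementation on 50 random trees.

## Pipeline and reproducibility

`run_pipeline` chains simulate → QC → extract → cluster → train → classify →
explain, echoes the effective config into the run directory, logs per-stage
provenance, halts on the first stage failure (retaining earlier artifacts)
and is byte-identical under fixed seeds. Every stochastic entry point takes
an explicit seed; nothing reads global RNG state.

## Known limitations

* AdEx spikes are reset events: their half-widths (~one sample) and rise/
  fall rates reflect the marker, not biophysical waveforms — kinetics ground
  truth comes from the composer, not the simulator.
* The classifier benchmark is Gaussian and axis-aligned; its near-perfect
  accuracy is an upper bound, not a field estimate.
* The 23-feature set and the 12-feature definitions approximate, but cannot
  reproduce bit-for-bit, the upstream tools they stand in for.
* ABF/NWB support requires optional extras and real amplifier metadata
  (holding current, epochs); the internal JSON container is the tested path.
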