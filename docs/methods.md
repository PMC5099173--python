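# Methods

## Model

The output channel is modeled as a multiple-input, single-output,
linear time-invariant moving-average (FIR) system:

    y[n] = Σ_{i=1..d} Σ_{m=0..p-1} s_i[n−m] h_i[m] + ε[n].

Assumptions: synchronous, regular sampling across channels; linearity
and time-invariance over the analyzed record; stable subsystems, so each
impulse response decays and can be truncated at `p` taps.  The model is
deliberately agnostic about the inputs' own dynamics — inputs may be
arbitrarily cross-correlated, which is the situation the estimator is
designed for.

Stacking `p` delayed copies of each input gives the block design
`A = [A_1 … A_d]` with `A_k ∈ R^{(N−p)×p}` (delay `j` in column `j`,
entries repeating along diagonals); the first `p` output samples are
dropped rather than zero-padded, so no boundary artifacts enter the fit.

## Per-block estimation

For channel `k`, the other channels' blocks `A_(k)` span the
interference subspace.  Let `Q_(k)` be the orthogonal projector onto the
complement of `span(A_(k))`.  Multiplying the regression by `Q_(k)`
eliminates the other channels exactly, and the smoothness-penalized
solution is

    h_k = (A_k' Q_(k) A_k + γ Γ'Γ)^+  A_k' Q_(k) y,

with `Γ` the (p−1)×p first-difference operator.  At `γ = 0` the fitted
contribution `A_k h_k` is the oblique projection of `y` onto
`span(A_k)` along `span(A_(k))`: idempotent, non-symmetric, annihilating
the other channels.  The projector itself is never materialized in the
solver; only `Q`-weighted Gram products are formed.  For records longer
than `implicit_threshold` rows (default 2000) `Q` is applied implicitly
as the residual of a least-squares solve against `A_(k)` — identical
algebra at O(N·p) memory instead of O(N²).

**Baseline handling.**  Input channels are mean-centered before the
design is built (a scalar mean per channel, which preserves the
delayed-copy structure).  The output is *not* centered; instead a
constant column is kept inside every block's reference subspace, so
`Q_(k)` annihilates baselines exactly.  This matters: centering the
output by its own mean leaves a small constant misfit that biases every
impulse response at the 1e-4 level, while the constant reference
regressor leaves the noise-free decomposition exact to machine
precision.  The fitted baseline is reported separately
(`SignalDecomposer.baseline_`) and the residual is defined net of it.

**Pseudoinverses.**  All pseudoinverses are SVD-based with a relative
cutoff `max(dim)·eps·σ_max`, where `dim` includes the data row count for
Gram matrices `A'QA` — the rounding floor of a Gram product scales with
the number of rows summed over, and a cutoff based only on the small
Gram dimension retains noise singular values when the true rank is
deficient.

**Ill-posed partitions.**  If `rank([A_k A_(k)]) < rank(A_k) +
rank(A_(k))` the target and reference subspaces overlap, the oblique
projection is ill-defined, and an `IllPosedProjectionWarning` (naming
the offending channel) is emitted; computation proceeds via the
pseudoinverse and regularization mitigates the instability.

## Order and regularization selection

`(p, γ)` are chosen by K-fold cross-validation with **contiguous,
non-overlapping time blocks** (default 10 folds) — rows are never
shuffled, out of respect for serial dependence.  For each fold, impulse
responses are fitted on the training rows with `Q` built from
training-row regressors, and scored on held-out rows as

    e = (1/N_v) ‖Q_v y_v − Q_v A_k h‖²  +  (γ/p) ‖Γ h‖²,

summed over blocks, with `Q_v` built from validation-row regressors of
the other blocks.  The smoothness term is weighted by the candidate `γ`
(normalized by `p`), mirroring the fitting objective; a fixed weight
independent of `γ` would make the criterion strictly decreasing in `p`
on clean data (the penalty is `‖Γh_true‖²/p`) and no candidate order
could ever achieve zero error.  Ties within a relative band of 1e-12
(with an absolute floor at 1e-12 of the output variance, so
numerically-zero errors tie) break toward smaller `γ`, then smaller `p`
— less bias, fewer parameters.  The default `γ` grid is 13 points,
log-spaced over 1e-6…1e3 and scaled by the mean of `trace(A_k'QA_k)/p`
so the same relative grid works across signal scales.

One global `γ` is shared by all blocks by default (a per-block override
exists).  The impulse-response decay threshold is *not* used for
automatic order choice; a tail-mass diagnostic (fraction of |h| in the
last 10% of taps) is reported instead.

## Synthetic benchmark

`generate_benchmark` draws three band-limited pseudo-random binary
(±1) inputs (band 0–0.3 half-cycles/sample), mixes in a fourth reference
PRBS at correlation ρ = 0.5 (standardize both, `ρ·x₄ + √(1−ρ²)·xᵢ` — the
square root is required for the stated correlation to be realized),
filters them through three Butterworth subsystems (3rd-order low-pass at
0.15; band-passes 0.1–0.2 and 0.05–0.15), mixes a low-passed copy of the
reference into the output at correlation 0.3 (before output noise), and
adds zero-mean uniform noise at 4 dB SNR to every channel, with the
noise realization rescaled so the SNR is met exactly.  N = 1024 samples;
all ground truth (clean inputs, true FIRs, per-channel components,
contamination, noise) is retained, and the generator is deterministic
from its seed.

Design choices worth knowing:

* **PRBS construction.**  Sign of zero-phase low-pass-filtered white
  noise.  Clipping spreads spectral power, so the pre-clip cutoff is
  0.4× the band edge; this keeps ≥ 90% of the clipped signal's power in
  band (measured ≥ 91.6% over 100 seeds), which a cutoff at the band
  edge does not (~83%).
* **FIR ground truth at 50 taps.**  The Butterworth subsystems are IIR;
  their impulse responses truncated at 1e-6 relative magnitude are 62,
  246 and 318 taps long — far beyond the 50-tap MA order of the study
  design (the narrow band-pass still has ~7% relative magnitude at tap
  50).  The generator therefore uses the 50-tap truncation as the
  *generative* truth, so the fitted model class contains the
  data-generating process and exact-recovery statements are meaningful.
  The full-length truncated responses remain available from
  `subsystem_filters()`.
* **Noise is uniform**, matching the benchmark's description in words
  ("uniformly distributed"), with variance set from the target SNR.

`generate_physio_scenario` emulates a neonatal-style record at 1/3 Hz: a
blood-pressure-like input (baseline 45 + band-limited random walk + slow
oscillation), a saturation-like input (baseline 97% with smooth
−12-point desaturation events), and an oxygenation output driven by
known smooth gamma-shaped FIR kernels (20 taps) plus Gaussian background
noise.  It is entirely synthetic and stands in for patient data in
tests.

What the generators do *not* emulate: nonstationarity and slow drift of
the transfer paths, movement artifacts, quantization and dropout of
clinical monitors, nonlinear autoregulation dynamics.  Passing tests on
these benchmarks demonstrate correctness of the estimator under the
stated linear, stationary conditions — not clinical performance.

## Coupling validation

A decomposition is validated by the input-by-component coupling matrix:
entry (j, i) measures information transfer from input j to component i,
and a successful decomposition is diagonal.  The default estimator is a
transfer-entropy-style corrected conditional-entropy difference on
uniformly quantized signals (6 levels): the reduction in conditional
entropy of the component's next sample, given 3 samples of its own
past, when the source enters the conditioning set.  Two design elements
are essential, both chosen because the couplings of interest flow
through ~50-tap linear subsystems:

* the source enters through a **matched linear summary** — the best
  linear map of its last 51 lags onto the target, refitted for every
  evaluation including surrogates — because coupling spread thinly over
  many lags is invisible to any short raw-lag embedding;
* **own-past conditioning** (3 terms) discounts smooth shared trends,
  which are predictable from the component itself; with fewer terms a
  small residue of slow shared structure survives.  Together with the
  singleton-pattern correction (fraction of once-seen patterns times the
  marginal entropy, added to each conditional entropy), weak and
  spurious couplings are biased to exactly zero, reproducing the
  zero/nonzero reading such coupling tables get in short-record
  practice.

Significance uses circular time-shift surrogates (199 shifts of at
least 50 samples, threshold at the 95th percentile), which preserve each
signal's marginal distribution and autocorrelation.  A sensitive linear
variance-reduction metric (`metric="linear"`; R² on the source's lags)
is provided for questions of the form "is there any leakage at all" —
note that with correlated inputs even a *perfect* decomposition shows
nonzero linear cross-coupling, because the components genuinely share
the common source; the entropy metric's conditioning is what makes the
diagonal pattern recoverable.

## Numerical and interface choices

* Tolerances are centralized in `ToleranceConfig` and echoed into every
  run manifest.
* All public indices are 0-based; trimmed outputs carry their time axis.
* CSV is the only file format (header row, '.' decimal, optional
  time column; strictly increasing, regular within 1% of the median
  step).  Non-finite samples are an error by default; runs of up to a
  configured length can be linearly interpolated, logged.
* Output files contain no wall-clock timestamps; a rerun from the same
  seed and configuration is bit-identical (manifests echo the
  user-supplied paths and differ only there).
* Problem sizes in the test-suite and acceptance runs: 100 random
  designs for the projector suites, 100 seeds for the decoupling
  comparison, 20 seeds for the coupling-pattern and CV checks, 100
  replicates for the confidence-band comparison — chosen as the standard
  replication counts for these Monte-Carlo checks.

## Known limitations

* A single shared order `p` for all inputs (per-input orders are not
  supported).
* No recursive/online updating; each record (or each fixed-length
  segment via `decompose --segment-length`) is processed in one batch.
* The coupling estimator's absolute values depend on its quantization
  and embedding settings; only patterns (zero/nonzero, diagonal
  dominance, surrogate significance) are meaningful across settings.
* Near-collinear inputs (e.g., an input that is itself a filtered copy
  of the output) make the oblique projection ill-posed; the solver warns
  and regularization only partially compensates.
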