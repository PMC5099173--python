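# sideobsp

Additive decomposition of a measured biosignal into the partial linear
contributions of correlated input channels, via oblique subspace
projections on a block-Hankel FIR design with difference-operator
Tikhonov regularization.

## The problem

Bedside monitoring produces many synchronously sampled signals.  A
near-infrared spectroscopy (NIRS) tissue oxygenation index (TOI), for
instance, reflects cerebral blood flow — but only while arterial oxygen
saturation (SaO₂) is stable; a desaturation episode shows up in the TOI
and masks the blood-pressure-driven dynamics a clinician wants to read.
This package separates such an output channel into per-input components,

    y[n] = Σᵢ (sᵢ * hᵢ)[n] + ε[n],

where each input channel `sᵢ` (MABP, SaO₂, HR, EtCO₂, pump flow, …)
drives the output through an unknown finite impulse response `hᵢ`, so
that `ŷᵢ = sᵢ * ĥᵢ` is the sole linear influence of channel `i` on `y`.

The difficulty is that physiological inputs are correlated: fitting each
channel separately (an orthogonal projection of `y` onto that channel's
delay subspace) assigns shared dynamics to every channel at once.  The
estimator here instead projects *obliquely* — onto the target channel's
subspace **along** the subspace spanned by all other channels — which
removes the cross-talk exactly in the noise-free case.

## The estimator

Each input's delay embedding (its block of the block-Hankel design
matrix, `p` taps) is a subspace `span(A_k)`.  With
`Q_(k) = I − A_(k)(A_(k)ᵀA_(k))⁺A_(k)ᵀ` the orthogonal projector onto the
complement of the other channels' joint subspace, the per-channel
impulse response solves the regularized normal equations

    ĥ_k = (A_kᵀ Q_(k) A_k + γ ΓᵀΓ)⁺ A_kᵀ Q_(k) y,

where `Γ` is the first-difference operator, so the penalty `γ‖Γh‖²`
enforces the smoothness expected of physiological impulse responses.  At
`γ = 0` the fitted contribution `A_k ĥ_k` equals the oblique projection
`P_{k·(k)} y` of the output.  The order `p` and constant `γ` are chosen
by blocked (contiguous-in-time) cross-validation.  A constant regressor
is always kept in the reference subspace, so baselines can never leak
into impulse responses.

The package is organized as scikit-learn-style estimators —
`SignalDecomposer` (fixed `order`, `gamma`) and `SignalDecomposerCV`
(cross-validated) with `fit` / `transform` / `predict` — plus thin
functional wrappers (`side_obsp`, `cross_validate`), a synthetic
benchmark generator with full ground truth, an information-transfer
coupling metric for validating decompositions, CSV I/O, and a CLI.

## Worked example

```python
import numpy as np
from sideobsp import generate_benchmark, side_obsp

# three correlated band-limited binary inputs through known filters,
# noise-free variant: the decomposition is exact
bench = generate_benchmark(seed=1, rho=0.5, snr_db=None, output_contamination=0.0)
res = side_obsp(bench.sigset, p=50, gamma=0.0)
print("max impulse-response error:", np.abs(res.h - bench.true_h).max())
print("residual / output RMS:     ",
      np.sqrt((res.residual**2).mean()) / np.sqrt((res.y_trimmed**2).mean()))
```

```
max impulse-response error: 8.423817199343375e-15
residual / output RMS:      8.516420817408423e-15
```

Even though the three inputs share a common source (pairwise correlation
0.25), every impulse response and every partial contribution is
recovered to machine precision — per-channel ordinary least squares on
the same record misassigns the shared dynamics and is wrong in the
second digit.

From the shell, the same pipeline is:

```bash
side-obsp simulate --scenario benchmark --seed 1 --out sim/
side-obsp decompose --input sim/signals.csv --target y --inputs x1,x2,x3 \
                    --order 50 --gamma auto --out dec/
side-obsp evaluate --input sim/signals.csv --components dec/ --out eval/
```

`decompose` writes time-aligned components (`y_x1`, `y_x2`, `y_x3`),
impulse responses, amplitude spectra and a run manifest; `evaluate`
writes the input-by-component coupling table, which for a successful
decomposition is diagonal.

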