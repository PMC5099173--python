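"""Regularized per-block decomposition of a measured output signal.

Given ``d`` input channels and one output, the output is modeled as a sum
of FIR-filtered inputs, ``y[n] = sum_i (s_i * h_i)[n] + eps``.  For each
input the impulse response is estimated from the normal equations of the
Q-weighted regression,

    h_k = (A_k' Q A_k + gamma * G'G)^+  A_k' Q y,

where ``Q`` annihilates the subspace spanned by every other input's Hankel
block and ``G`` is the first-difference operator.  The Q-weighting is what
realizes the oblique projection — the estimated contribution of channel k,
``A_k h_k``, equals the oblique projection of ``y`` onto span(A_k) along
the other channels' subspace when ``gamma = 0`` — while the difference
penalty encodes the physiological prior that impulse responses are smooth.
The oblique projector itself is never materialized.

The estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``transform``, trailing-underscore fitted attributes) and compose with
sklearn tooling; the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import DEFAULT_TOLERANCES, ToleranceConfig
from .hankel import RegressorDesign, SignalSet, build_design, partition
from .projections import (
    IllPosedProjectionWarning,
    _pinv_with_report,
    _warn_if_overlapping,
    apply_complement,
    complement_projector,
)

__all__ = [
    "RegularizerSpec",
    "DecompositionResult",
    "FrequencyResponse",
    "regularization_matrix",
    "solve_block",
    "side_obsp",
    "cross_validate",
    "frequency_response",
    "SignalDecomposer",
    "SignalDecomposerCV",
]


def regularization_matrix(p: int) -> np.ndarray:
    """First-difference operator of shape ``(p-1, p)``.

    Row ``i`` holds ``-1`` at column ``i`` and ``+1`` at column ``i+1``, so
    the penalty ``||G h||^2`` is the summed squared increments of the
    impulse response; constants lie in its null space.
    """
    if p < 2:
        raise ValueError("difference operator needs order p >= 2")
    G = np.zeros((p - 1, p))
    idx = np.arange(p - 1)
    G[idx, idx] = -1.0
    G[idx, idx + 1] = 1.0
    return G


@dataclass(frozen=True)
class RegularizerSpec:
    """Tikhonov penalty: constant ``gamma`` and difference operator."""

    gamma: float
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("regularization constant gamma must be >= 0")

    @classmethod
    def first_difference(cls, p: int, gamma: float) -> "RegularizerSpec":
        return cls(gamma=float(gamma), Gamma=regularization_matrix(p))


@dataclass(frozen=True)
class DecompositionResult:
    """Per-input impulse responses and additive output components.

    ``components[:, i] = A_i h_i`` with mean-centered inputs;
    ``residual = y_trim - components.sum(axis=1)`` where ``y_trim`` is the
    trimmed output minus the fitted baseline ``y_mean``.
    """

    h: np.ndarray
    components: np.ndarray
    residual: np.ndarray
    p: int
    gamma: float
    names: list
    fs: float = 1.0
    cv_trace: list = field(default_factory=list)
    y_mean: float = 0.0
    time: np.ndarray | None = None
    tail_mass: np.ndarray | None = None

    @property
    def y_trimmed(self) -> np.ndarray:
        """Centered, trimmed output reconstructed from the bookkeeping."""
        return self.components.sum(axis=1) + self.residual

    @property
    def input_names(self) -> list:
        return self.names[:-1]

    @property
    def output_name(self) -> str:
        return self.names[-1]


@dataclass(frozen=True)
class FrequencyResponse:
    """Amplitude of the DFT of each estimated impulse response."""

    freqs: np.ndarray
    amplitude: np.ndarray
    names: list


def _augment_intercept(A_rest, n_rows):
    """Append a constant column to the reference block.

    With a constant in the reference subspace, Q annihilates baselines,
    so DC offsets in the output can never leak into impulse responses.
    """
    return np.hstack([A_rest, np.ones((n_rows, 1))]) if A_rest.size else np.ones((n_rows, 1))


def _block_normal_eq(A_k, A_rest, y_trim, mode, threshold, intercept=False):
    """Return ``G = A_k'QA_k`` and ``b = A_k'Qy`` for one block.

    ``mode`` selects whether Q is materialized ("explicit") or applied as
    least-squares residuals against ``A_rest`` ("implicit"); "auto" picks
    by row count.  ``intercept`` augments the reference with a constant
    regressor.
    """
    n_rows = A_k.shape[0]
    if intercept:
        A_rest = _augment_intercept(A_rest, n_rows)
    if mode == "auto":
        mode = "implicit" if n_rows > threshold else "explicit"
    if mode == "explicit":
        Q = complement_projector(A_rest)
        QA = Q @ A_k
        Qy = Q @ y_trim
    elif mode == "implicit":
        QA = apply_complement(A_rest, A_k)
        Qy = apply_complement(A_rest, y_trim.reshape(-1, 1)).ravel()
    else:
        raise ValueError(f"unknown projector mode {mode!r}")
    return A_k.T @ QA, A_k.T @ Qy


def solve_block(
    part,
    y_trim: np.ndarray,
    reg: RegularizerSpec,
    projector: str = "auto",
    intercept: bool = False,
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
) -> np.ndarray:
    """Regularized impulse-response estimate for one input block.

    Implements ``h = (A_k'QA_k + gamma*G'G)^+ A_k'Q y`` with ``Q`` the
    complement projector of the remaining blocks.  At ``gamma = 0`` this is
    the plain oblique-projection estimate.
    """
    y_trim = np.asarray(y_trim, dtype=float).ravel()
    A_k, A_rest = part.A_k, part.A_rest
    if y_trim.shape[0] != A_k.shape[0]:
        raise ValueError(
            f"output has {y_trim.shape[0]} rows, design has {A_k.shape[0]}"
        )
    if reg.gamma > 0 and reg.Gamma.shape[1] != A_k.shape[1]:
        raise ValueError(
            f"difference operator has {reg.Gamma.shape[1]} columns, "
            f"block has {A_k.shape[1]}"
        )
    _warn_if_overlapping(A_k, A_rest)
    G, b = _block_normal_eq(
        A_k, A_rest, y_trim, projector, tol.implicit_threshold, intercept=intercept
    )
    if reg.gamma > 0:
        G = G + reg.gamma * (reg.Gamma.T @ reg.Gamma)
    G_pinv, _, _ = _pinv_with_report(G, tol, n_rows=A_k.shape[0])
    return G_pinv @ b


class SignalDecomposer(BaseEstimator):
    """Decompose an output channel into additive per-input contributions.

    Fits a multiple-input FIR model by per-block oblique-subspace
    estimation with a first-difference Tikhonov penalty, then reports each
    input's partial contribution to the output.

    Parameters
    ----------
    order : int, default 50
        Number of FIR taps per input (delays ``0 .. order-1``).
    gamma : float or sequence of float, default 0.0
        Regularization constant; a sequence gives one value per input.
    center : bool, default True
        Mean-center the input channels before building the design.  The
        output's baseline is absorbed by a constant regressor kept in the
        reference subspace of every block (see ``intercept``) and reported
        as ``baseline_``.
    scale : bool, default False
        Additionally scale inputs to unit variance (impulse responses are
        mapped back to physical units on output).
    projector : {"auto", "explicit", "implicit"}, default "auto"
        Whether the complement projector is materialized or applied as
        least-squares residuals; "auto" switches to implicit for long
        records.

    Attributes
    ----------
    impulse_responses_ : ndarray of shape (order, d)
        Estimated FIR coefficients per input, in physical units.
    components_ : ndarray of shape (N - order, d)
        Partial contributions ``A_k h_k`` (centered coordinates).
    residual_ : ndarray of shape (N - order,)
        Centered trimmed output minus the summed components.
    design_ : RegressorDesign
        The block-Hankel design used in the fit.
    """

    def __init__(
        self,
        order: int = 50,
        gamma=0.0,
        center: bool = True,
        scale: bool = False,
        projector: str = "auto",
        intercept: bool = True,
        tol: ToleranceConfig = DEFAULT_TOLERANCES,
    ):
        self.order = order
        self.gamma = gamma
        self.center = center
        self.scale = scale
        self.projector = projector
        self.intercept = intercept
        self.tol = tol

    def _gammas(self, d: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            g = np.full(d, g[0])
        if g.size != d:
            raise ValueError(f"gamma must be scalar or length {d}")
        if (g < 0).any():
            raise ValueError("regularization constant gamma must be >= 0")
        return g

    def fit(self, X, y, fs: float = 1.0, names=None, time=None):
        """Fit the FIR decomposition.

        Parameters
        ----------
        X : array-like of shape (N, d)
            Input channels.
        y : array-like of shape (N,)
            Output channel.
        """
        sigset = (
            X if isinstance(X, SignalSet)
            else SignalSet(S=X, y=y, fs=fs, names=names or [], time=time)
        )
        design = build_design(sigset, self.order, center=self.center, scale=self.scale)
        d = sigset.n_inputs
        gammas = self._gammas(d)
        y_trim = design.y_trimmed
        reg_base = regularization_matrix(self.order) if self.order >= 2 else None
        h = np.empty((self.order, d))
        components = np.empty((y_trim.shape[0], d))
        for k in range(d):
            part = partition(design, k)
            reg = RegularizerSpec(
                gamma=gammas[k],
                Gamma=reg_base if reg_base is not None else np.zeros((0, self.order)),
            )
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", IllPosedProjectionWarning)
                    h_k = solve_block(
                        part, y_trim, reg, projector=self.projector,
                        intercept=self.intercept, tol=self.tol,
                    )
                for w in caught:
                    warnings.warn(
                        f"channel {sigset.input_names[k]!r}: {w.message}",
                        IllPosedProjectionWarning,
                        stacklevel=2,
                    )
            except ValueError as exc:
                raise ValueError(
                    f"channel {sigset.input_names[k]!r}: {exc}"
                ) from exc
            components[:, k] = part.A_k @ h_k
            h[:, k] = h_k / design.input_scales[k]
        self.signal_set_ = sigset
        self.design_ = design
        self.impulse_responses_ = h
        self.components_ = components
        raw_residual = y_trim - components.sum(axis=1)
        # fitted baseline: the DC left over once every input's partial
        # contribution (of the centered inputs) is accounted for
        self.baseline_ = float(raw_residual.mean()) if self.intercept else 0.0
        self.residual_ = raw_residual - self.baseline_
        self.gammas_ = gammas
        self.n_features_in_ = d
        # fraction of |h| mass in the trailing taps: decay diagnostic only
        tail = max(1, int(round(self.tol.tail_mass_fraction * self.order)))
        mass = np.abs(h).sum(axis=0)
        self.tail_mass_ = np.where(
            mass > 0, np.abs(h[-tail:, :]).sum(axis=0) / np.where(mass > 0, mass, 1.0), 0.0
        )
        return self

    def transform(self, X, y=None) -> np.ndarray:
        """Partial contributions of each input for a (possibly new) record."""
        check_is_fitted(self, "impulse_responses_")
        if isinstance(X, SignalSet):
            X = X.S
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels, fitted for {self.n_features_in_}"
            )
        from .hankel import block_hankel

        comps = np.column_stack(
            [
                block_hankel(X[:, k] - self.design_.input_means[k], self.order)
                @ self.impulse_responses_[:, k]
                for k in range(self.n_features_in_)
            ]
        )
        return comps

    def predict(self, X) -> np.ndarray:
        """Reconstructed output (component sum plus the fitted baseline)."""
        return self.transform(X).sum(axis=1) + self.baseline_

    def score(self, X, y) -> float:
        """R^2 of the reconstruction against ``y`` (first ``order`` samples trimmed)."""
        y = np.asarray(y, dtype=float).ravel()
        y_hat = self.predict(X)
        y_t = y[self.order:]
        ss_res = np.sum((y_t - y_hat) ** 2)
        ss_tot = np.sum((y_t - y_t.mean()) ** 2)
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    def result_(self) -> DecompositionResult:
        """Bundle fitted attributes into a :class:`DecompositionResult`."""
        check_is_fitted(self, "impulse_responses_")
        return DecompositionResult(
            h=self.impulse_responses_,
            components=self.components_,
            residual=self.residual_,
            p=self.order,
            gamma=float(np.mean(self.gammas_)),
            names=self.signal_set_.names,
            fs=self.signal_set_.fs,
            y_mean=self.baseline_,
            time=self.design_.time_trimmed,
            tail_mass=self.tail_mass_,
        )


def _contiguous_folds(n_rows: int, n_folds: int):
    """Contiguous, non-overlapping time blocks (serial data: never shuffled)."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n_rows:
        raise ValueError(f"cannot split {n_rows} rows into {n_folds} folds")
    return np.array_split(np.arange(n_rows), n_folds)


def default_gamma_grid(design: RegressorDesign, n_points: int = 13):
    """Log-spaced candidate gammas scaled to the design's energy.

    The raw grid 1e-6 .. 1e3 is multiplied by the mean over blocks of
    ``trace(A_k'QA_k) / p`` so the same relative grid works across signal
    amplitudes and record lengths.
    """
    traces = []
    for k in range(design.n_blocks):
        part = partition(design, k)
        A_rest = _augment_intercept(part.A_rest, part.A_k.shape[0])
        QA = apply_complement(A_rest, part.A_k)
        traces.append(np.trace(part.A_k.T @ QA) / design.p)
    scale = float(np.mean(traces))
    return np.logspace(-6, 3, n_points) * max(scale, np.finfo(float).tiny)


def cross_validate(
    sigset: SignalSet,
    p_grid,
    gamma_grid="auto",
    n_folds: int = 10,
    center: bool = True,
    scale: bool = False,
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
):
    """Select order and regularization constant by blocked cross-validation.

    Folds are contiguous time blocks.  For each candidate ``(p, gamma)``,
    each fold's impulse responses are fitted on the training rows (with the
    complement projector built from training-row regressors) and scored on
    the held-out rows with

        e = (1/Nv) ||Qv y - Qv A_k h||^2 + (gamma/p) ||G h||^2,

    summed over input blocks, where ``Qv`` is built from the validation
    rows of the other blocks.  The smoothness term mirrors the fitting
    objective (candidate gamma, normalized by the order), so at gamma = 0
    the criterion is the pure held-out fit.  Ties (within a relative
    band) break toward smaller gamma, then smaller p.

    Returns ``(p_best, gamma_best, trace)`` with ``trace`` a list of
    ``(p, gamma, cv_error)`` triples.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("p_grid must be non-empty")
    if gamma_grid != "auto":
        gamma_list = [float(g) for g in gamma_grid]
        if not gamma_list:
            raise ValueError("gamma_grid must be non-empty")
    trace = []
    for p in p_grid:
        design = build_design(sigset, p, center=center, scale=scale)
        y_trim = design.y_trimmed
        folds = _contiguous_folds(y_trim.shape[0], n_folds)
        gammas = (
            list(default_gamma_grid(design)) if gamma_grid == "auto" else gamma_list
        )
        Gam = regularization_matrix(p) if p >= 2 else np.zeros((0, p))
        GtG = Gam.T @ Gam
        errs = np.zeros(len(gammas))
        for val_idx in folds:
            mask = np.ones(y_trim.shape[0], dtype=bool)
            mask[val_idx] = False
            if mask.sum() == 0 or val_idx.size == 0:
                raise ValueError("cross-validation produced an empty fold")
            for k in range(design.n_blocks):
                part = partition(design, k)
                A_rest_aug = _augment_intercept(part.A_rest, part.A_k.shape[0])
                A_k_t, A_rest_t = part.A_k[mask], A_rest_aug[mask]
                QA = apply_complement(A_rest_t, A_k_t)
                G = A_k_t.T @ QA
                b = A_k_t.T @ apply_complement(
                    A_rest_t, y_trim[mask].reshape(-1, 1)
                ).ravel()
                A_k_v, A_rest_v = part.A_k[val_idx], A_rest_aug[val_idx]
                Qv_A = apply_complement(A_rest_v, A_k_v)
                Qv_y = apply_complement(
                    A_rest_v, y_trim[val_idx].reshape(-1, 1)
                ).ravel()
                for j, g in enumerate(gammas):
                    M = G + g * GtG if g > 0 else G
                    M_pinv, _, _ = _pinv_with_report(M, tol, n_rows=A_k_t.shape[0])
                    h = M_pinv @ b
                    e = np.sum((Qv_y - Qv_A @ h) ** 2) / val_idx.size
                    # smoothness term mirrors the fitting objective: the
                    # candidate gamma weights it, normalized by the order
                    e += g * np.sum((Gam @ h) ** 2) / p
                    errs[j] += e
        errs /= len(folds)
        trace.extend((p, g, float(e)) for g, e in zip(gammas, errs))
    best_err = min(t[2] for t in trace)
    # tie band: relative, with an absolute floor on the output's scale so
    # that numerically-zero errors compare as equal
    band = best_err + tol.cv_tie_rtol * max(best_err, float(sigset.y.var()))
    candidates = [t for t in trace if t[2] <= band]
    # prefer less bias (smaller gamma), then fewer parameters (smaller p)
    p_best, gamma_best, _ = min(candidates, key=lambda t: (t[1], t[0]))
    return p_best, gamma_best, trace


class SignalDecomposerCV(BaseEstimator):
    """:class:`SignalDecomposer` with blocked cross-validated ``(order, gamma)``.

    Parameters mirror :func:`cross_validate`; after selection the model is
    refitted on the full record.

    Attributes
    ----------
    order_ : int
        Selected FIR order.
    gamma_ : float
        Selected regularization constant.
    cv_trace_ : list of (p, gamma, cv_error)
        Full cross-validation trace.
    estimator_ : SignalDecomposer
        The refitted final model (its fitted attributes are mirrored here).
    """

    def __init__(
        self,
        p_grid=(50,),
        gamma_grid="auto",
        n_folds: int = 10,
        center: bool = True,
        scale: bool = False,
        projector: str = "auto",
        tol: ToleranceConfig = DEFAULT_TOLERANCES,
    ):
        self.p_grid = p_grid
        self.gamma_grid = gamma_grid
        self.n_folds = n_folds
        self.center = center
        self.scale = scale
        self.projector = projector
        self.tol = tol

    def fit(self, X, y, fs: float = 1.0, names=None, time=None):
        sigset = (
            X if isinstance(X, SignalSet)
            else SignalSet(S=X, y=y, fs=fs, names=names or [], time=time)
        )
        p_best, gamma_best, trace = cross_validate(
            sigset,
            self.p_grid,
            self.gamma_grid,
            n_folds=self.n_folds,
            center=self.center,
            scale=self.scale,
            tol=self.tol,
        )
        self.order_ = p_best
        self.gamma_ = gamma_best
        self.cv_trace_ = trace
        est = SignalDecomposer(
            order=p_best,
            gamma=gamma_best,
            center=self.center,
            scale=self.scale,
            projector=self.projector,
            tol=self.tol,
        )
        est.fit(sigset, None)
        self.estimator_ = est
        self.impulse_responses_ = est.impulse_responses_
        self.components_ = est.components_
        self.residual_ = est.residual_
        self.n_features_in_ = est.n_features_in_
        return self

    def transform(self, X, y=None):
        check_is_fitted(self, "estimator_")
        return self.estimator_.transform(X)

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def score(self, X, y):
        check_is_fitted(self, "estimator_")
        return self.estimator_.score(X, y)

    def result_(self) -> DecompositionResult:
        check_is_fitted(self, "estimator_")
        res = self.estimator_.result_()
        return DecompositionResult(
            h=res.h,
            components=res.components,
            residual=res.residual,
            p=res.p,
            gamma=res.gamma,
            names=res.names,
            fs=res.fs,
            cv_trace=self.cv_trace_,
            y_mean=res.y_mean,
            time=res.time,
            tail_mass=res.tail_mass,
        )


def side_obsp(
    sigset: SignalSet, p: int, gamma: float = 0.0, **kwargs
) -> DecompositionResult:
    """One-shot decomposition at a fixed order and regularization constant."""
    est = SignalDecomposer(order=p, gamma=gamma, **kwargs)
    est.fit(sigset, None)
    return est.result_()


def frequency_response(
    result: DecompositionResult, fs: float | None = None, n_freq: int = 512
) -> FrequencyResponse:
    """Amplitude spectra of the estimated impulse responses.

    Zero-padded DFT magnitude of each FIR column on a uniform grid of
    ``n_freq`` frequencies from 0 to Nyquist (inclusive).
    """
    if fs is None:
        fs = result.fs
    if n_freq < result.p:
        raise ValueError(f"n_freq must be >= p = {result.p}")
    nfft = 2 * (n_freq - 1)
    amp = np.abs(np.fft.rfft(result.h, n=nfft, axis=0))
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    return FrequencyResponse(freqs=freqs, amplitude=amp, names=result.input_names)
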