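"""Block-Hankel moving-average design matrices.

A finite-impulse-response (moving-average) model writes the output at time
``n`` as a weighted sum of the current and the ``p - 1`` previous samples of
each input channel.  Stacking those delayed copies column-wise turns the
convolution into a matrix product: each input contributes one Hankel block
of ``p`` columns (column ``j`` holds delay ``j``), and the blocks are
concatenated in channel order.  The first ``p`` output samples are dropped
(no zero padding), so every design row uses only observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projections import BlockPartition

__all__ = ["SignalSet", "RegressorDesign", "block_hankel", "build_design", "partition"]


@dataclass(frozen=True)
class SignalSet:
    """Synchronously sampled multichannel record.

    Attributes
    ----------
    S : ndarray, shape (N, d)
        Input channels, one per column.
    y : ndarray, shape (N,)
        Output channel.
    fs : float
        Sampling rate in Hz.
    names : list of str
        ``d`` input labels followed by the output label.
    time : ndarray or None
        Optional wall-clock timestamps (seconds), same length as ``y``.
    """

    S: np.ndarray
    y: np.ndarray
    fs: float = 1.0
    names: list = field(default_factory=list)
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim == 1:
            S = S.reshape(-1, 1)
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "y", y)
        if S.shape[0] != y.shape[0]:
            raise ValueError(
                f"inputs have {S.shape[0]} samples but output has {y.shape[0]}"
            )
        if S.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.isfinite(S).all():
            raise ValueError("input channels contain non-finite values")
        if not np.isfinite(y).all():
            raise ValueError("output channel contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        names = list(self.names) if self.names else (
            [f"input_{i}" for i in range(S.shape[1])] + ["output"]
        )
        if len(names) != S.shape[1] + 1:
            raise ValueError(
                f"expected {S.shape[1] + 1} channel names, got {len(names)}"
            )
        object.__setattr__(self, "names", names)
        if self.time is not None:
            t = np.asarray(self.time, dtype=float).ravel()
            if t.shape[0] != y.shape[0]:
                raise ValueError("time axis length mismatch")
            object.__setattr__(self, "time", t)

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.S.shape[1]

    @property
    def input_names(self) -> list:
        return self.names[:-1]

    @property
    def output_name(self) -> str:
        return self.names[-1]


@dataclass(frozen=True)
class RegressorDesign:
    """Block-Hankel design ``A`` with per-input block bookkeeping."""

    A: np.ndarray
    p: int
    block_slices: dict
    source: SignalSet
    input_means: np.ndarray
    input_scales: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.block_slices)

    @property
    def y_trimmed(self) -> np.ndarray:
        """Output samples aligned with the design rows."""
        return self.source.y[self.p:]

    @property
    def time_trimmed(self) -> np.ndarray | None:
        if self.source.time is None:
            return None
        return self.source.time[self.p:]


def block_hankel(s: np.ndarray, p: int) -> np.ndarray:
    """Delay-embedding of a single channel.

    Row ``r`` (output time ``n = p + r``) is ``[s[n], s[n-1], ..., s[n-p+1]]``;
    column ``j`` is the channel delayed by ``j`` samples.  ``p`` taps cover
    delays ``0 .. p-1``.
    """
    s = np.asarray(s, dtype=float).ravel()
    N = s.shape[0]
    if p < 1:
        raise ValueError("order p must be >= 1")
    if p >= N:
        raise ValueError(f"order p={p} must be smaller than the record length N={N}")
    windows = np.lib.stride_tricks.sliding_window_view(s, p)
    return np.ascontiguousarray(windows[1:, ::-1])


def build_design(
    sigset: SignalSet,
    p: int,
    center: bool = True,
    scale: bool = False,
) -> RegressorDesign:
    """Concatenate per-channel Hankel blocks into the full design.

    Input channels are mean-centered by default so that DC offsets do not
    load onto collinear constant directions (the output's baseline is
    handled downstream by the solver's constant reference regressor);
    optional unit-variance scaling is recorded so impulse responses can be
    mapped back to physical units.  Requires ``N - p > d * p`` so that the
    least-squares problem stays overdetermined.
    """
    N, d = sigset.n_samples, sigset.n_inputs
    if p < 1:
        raise ValueError("order p must be >= 1")
    if N - p <= d * p:
        n_min = p * (d + 1) + 1
        raise ValueError(
            f"design is underdetermined: N - p = {N - p} <= d*p = {d * p}; "
            f"need at least N = {n_min} samples for d = {d}, p = {p}"
        )
    means = sigset.S.mean(axis=0) if center else np.zeros(d)
    if scale:
        scales = sigset.S.std(axis=0, ddof=0)
        scales = np.where(scales > 0, scales, 1.0)
    else:
        scales = np.ones(d)
    blocks = []
    slices = {}
    col = 0
    for k in range(d):
        blk = block_hankel((sigset.S[:, k] - means[k]) / scales[k], p)
        blocks.append(blk)
        slices[k] = slice(col, col + p)
        col += p
    A = np.hstack(blocks)
    return RegressorDesign(
        A=A, p=p, block_slices=slices, source=sigset,
        input_means=means, input_scales=scales,
    )


def partition(design: RegressorDesign, k: int) -> BlockPartition:
    """Split the design into the block of input ``k`` and all others.

    ``k`` is 0-based; the remaining blocks keep their original order.
    """
    d = design.n_blocks
    if not 0 <= k < d:
        raise IndexError(f"block index k={k} out of range for d={d} inputs")
    sl = design.block_slices[k]
    A_k = design.A[:, sl]
    rest_cols = [design.A[:, design.block_slices[j]] for j in range(d) if j != k]
    A_rest = (
        np.hstack(rest_cols) if rest_cols else np.empty((design.A.shape[0], 0))
    )
    return BlockPartition(A_k=A_k, A_rest=A_rest, k=k)
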