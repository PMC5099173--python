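"""CSV input/output and run manifests.

All on-disk formats are plain comma-separated text with a header row.
Output files never embed wall-clock timestamps, so a rerun from the same
seed and configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_TOLERANCES
from .decompose import DecompositionResult, FrequencyResponse
from .hankel import SignalSet

__all__ = ["RunConfig", "read_signals", "write_signals", "write_results", "read_components"]

logger = logging.getLogger("sideobsp")

_TIME_NAMES = {"t", "time", "timestamp", "seconds"}


@dataclass
class RunConfig:
    """Configuration of a decomposition run (echoed into the manifest)."""

    input_path: str = ""
    output_dir: str = ""
    input_channels: list = field(default_factory=list)
    target_channel: str = ""
    order: object = 50            # int or "auto"
    p_grid: list = field(default_factory=lambda: [50])
    gamma: object = 0.0           # float or "auto"
    n_folds: int = 10
    seed: int | None = None
    coupling: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=lambda: DEFAULT_TOLERANCES.as_dict())
    segment_length: float | None = None

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 cross-validation folds")
        if self.order == "auto" and not self.p_grid:
            raise ValueError("order grid must be non-empty")


def _find_time_column(df: pd.DataFrame, time_column) -> str | None:
    if time_column not in (None, "auto"):
        if time_column not in df.columns:
            raise ValueError(f"time column {time_column!r} not found")
        return time_column
    for c in df.columns:
        if c.strip().lower() in _TIME_NAMES:
            return c
    return None


def read_signals(
    path,
    inputs=None,
    target=None,
    time_column="auto",
    fs: float | None = None,
    interpolate_max_gap: int = 0,
) -> SignalSet:
    """Load a delimited-text record into a validated :class:`SignalSet`.

    Parameters
    ----------
    inputs, target : channel names; defaults are every non-time column
        except the last (inputs) and the last column (target).
    time_column : name of the time column, or "auto" to detect one named
        t/time/timestamp/seconds.  Time must be strictly increasing and
        regularly sampled (within 1% of the median step).
    fs : sampling rate override (required if there is no time column and
        the rate is not 1 Hz).
    interpolate_max_gap : if > 0, runs of at most this many consecutive
        non-finite samples are linearly interpolated (and logged) instead
        of raising.
    """
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    tcol = _find_time_column(df, time_column)
    time = None
    if tcol is not None:
        time = pd.to_numeric(df[tcol], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(time).all():
            raise ValueError(f"{path}: non-numeric values in time column {tcol!r}")
        dt = np.diff(time)
        if (dt <= 0).any():
            raise ValueError(f"{path}: time column {tcol!r} is not strictly increasing")
        med = np.median(dt)
        if np.abs(dt - med).max() > 0.01 * med:
            raise ValueError(
                f"{path}: irregular sampling (max deviation "
                f"{np.abs(dt - med).max():.3g}s from median step {med:.3g}s)"
            )
        if fs is None:
            fs = 1.0 / med
    data_cols = [c for c in df.columns if c != tcol]
    if target is None:
        target = data_cols[-1]
    if inputs is None:
        inputs = [c for c in data_cols if c != target]
    for c in list(inputs) + [target]:
        if c not in df.columns:
            raise ValueError(f"{path}: channel {c!r} not found (have {data_cols})")
    channels = {}
    for c in list(inputs) + [target]:
        x = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(x)
        if bad.any():
            if interpolate_max_gap > 0:
                x = _interpolate_gaps(x, bad, interpolate_max_gap, c, path)
            else:
                row = int(np.nonzero(bad)[0][0])
                raise ValueError(
                    f"{path}: non-finite value in column {c!r} at row {row}"
                )
        channels[c] = x
    S = np.column_stack([channels[c] for c in inputs])
    return SignalSet(
        S=S,
        y=channels[target],
        fs=fs if fs is not None else 1.0,
        names=list(inputs) + [target],
        time=time,
    )


def _interpolate_gaps(x, bad, max_gap, name, path):
    idx = np.arange(x.shape[0])
    # find runs of consecutive bad samples
    edges = np.diff(bad.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1) + ([0] if bad[0] else [])
    for s in sorted(starts):
        e = s
        while e < x.shape[0] and bad[e]:
            e += 1
        if e - s > max_gap or s == 0 or e == x.shape[0]:
            raise ValueError(
                f"{path}: non-finite gap of {e - s} samples in column "
                f"{name!r} at row {s} exceeds the interpolation limit"
            )
    x = x.copy()
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    logger.info("interpolated %d non-finite samples in column %r", bad.sum(), name)
    return x


def write_signals(sigset: SignalSet, path) -> None:
    """Write a :class:`SignalSet` as CSV (time column first if present)."""
    data = {}
    if sigset.time is not None:
        data["t"] = sigset.time
    for i, name in enumerate(sigset.input_names):
        data[name] = sigset.S[:, i]
    data[sigset.output_name] = sigset.y
    pd.DataFrame(data).to_csv(path, index=False)


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("sideobsp", "numpy", "scipy", "pandas", "scikit-learn"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def write_results(
    result: DecompositionResult,
    freq: FrequencyResponse,
    outdir,
    config: RunConfig | None = None,
) -> list:
    """Write the four result files and return their paths.

    ``components.csv`` — time-aligned partial contributions named
    ``<target>_<input>``, plus the trimmed target and a residual column
    that absorbs the fitted baseline, so the component columns and the
    residual sum exactly to the target column.
    ``impulse_responses.csv`` — per-input FIR coefficients by lag.
    ``frequency_response.csv`` — amplitude spectra of the FIRs.
    ``manifest.json`` — configuration, seeds, tolerances, selected
    (order, gamma), CV trace and library versions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = result.output_name
    p = result.p
    comp = {}
    if result.time is not None:
        comp["t"] = result.time
    y_trim_raw = result.y_trimmed + result.y_mean
    comp[target] = y_trim_raw
    for i, name in enumerate(result.input_names):
        comp[f"{target}_{name}"] = result.components[:, i]
    comp["residual"] = y_trim_raw - result.components.sum(axis=1)
    comp_path = outdir / "components.csv"
    pd.DataFrame(comp).to_csv(comp_path, index=False)

    imp = {"tap": np.arange(p), "lag_seconds": np.arange(p) / result.fs}
    for i, name in enumerate(result.input_names):
        imp[f"h_{name}"] = result.h[:, i]
    imp_path = outdir / "impulse_responses.csv"
    pd.DataFrame(imp).to_csv(imp_path, index=False)

    fr = {"freq_hz": freq.freqs}
    for i, name in enumerate(freq.names):
        fr[f"amplitude_{name}"] = freq.amplitude[:, i]
    freq_path = outdir / "frequency_response.csv"
    pd.DataFrame(fr).to_csv(freq_path, index=False)

    manifest = {
        "order": result.p,
        "gamma": result.gamma,
        "channel_names": result.names,
        "sampling_rate_hz": result.fs,
        "y_mean": result.y_mean,
        "cv_trace": [list(t) for t in result.cv_trace],
        "tail_mass": list(result.tail_mass) if result.tail_mass is not None else None,
        "versions": _versions(),
        "config": config.__dict__ if config is not None else None,
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return [comp_path, imp_path, freq_path, man_path]


def read_components(outdir) -> tuple:
    """Reload ``components.csv`` + ``manifest.json`` written by :func:`write_results`."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "components.csv")
    manifest = json.loads((outdir / "manifest.json").read_text())
    return df, manifest
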