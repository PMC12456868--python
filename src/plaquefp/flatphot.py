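"""Flat-fiber photometry: demodulation of pulsed recordings into per-depth
fluorescence, depth z-scoring against a superficial baseline, median
smoothing, and photometry-vs-histology correlation.

The acquisition is time-division modulated: the light source pulses 10 ms
on / 5 ms off, ten repetitions per depth measurement, with a dark baseline
gap separating measurement blocks; channels (sample clock, detector, sync)
run at 5000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .histomap import DepthProfile
from .stats import DegenerateInputError, SpearmanResult, spearman
from .synthgen import AcquisitionProtocol, RawRecording


class DemodulationError(ValueError):
    pass


@dataclass(frozen=True)
class ZProfile:
    """Depth profile of z-scored fluorescence."""

    depth_grid_um: np.ndarray
    dF: np.ndarray
    baseline_window_um: tuple[float, float] = (0.0, 400.0)
    raw_F: np.ndarray | None = None

    def __post_init__(self):
        if len(self.depth_grid_um) != len(self.dF):
            raise ValueError("depth grid and dF must share a length")


def _on_runs(sync: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (exclusive) sample indices of light-on runs."""
    s = np.asarray(sync) > 0.5
    edges = np.diff(s.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if s[0]:
        starts = np.insert(starts, 0, 0)
    if s[-1]:
        ends = np.append(ends, len(s))
    return starts, ends


def demodulate(
    recording: RawRecording,
    protocol: AcquisitionProtocol,
    *,
    guard_samples: int = 1,
    reducer: str = "mean",
) -> np.ndarray:
    """Demodulate a flat-fiber recording into per-measurement fluorescence.

    Each pulse contributes the mean of the detector samples strictly inside
    its on window (``guard_samples`` dropped at each edge as a slew guard).
    Pulses separated by more than the off gap start a new measurement
    block; each block averages its ``protocol.reps`` pulses (or takes their
    median with ``reducer="median"``). Blocks are ordered depth-major,
    power-minor, so the result has shape ``(n_measurements, n_powers)``.
    """
    if len(recording.sync) != len(recording.detector):
        raise DemodulationError("sync and detector must share a length")
    starts, ends = _on_runs(recording.sync)
    if len(starts) == 0:
        raise DemodulationError("no complete light-on pulse found")
    per_pulse = np.array([
        recording.detector[s + guard_samples:e - guard_samples].mean()
        for s, e in zip(starts, ends)
    ])
    if np.any((ends - starts) <= 2 * guard_samples):
        raise DemodulationError("pulse too short for the transition guard")
    # group pulses separated by more than the off gap
    gap_limit = protocol.off_samples + protocol.on_samples // 2
    new_block = np.ones(len(starts), dtype=bool)
    new_block[1:] = (starts[1:] - ends[:-1]) > gap_limit
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    reduce_fn = np.median if reducer == "median" else np.mean
    values = np.array([reduce_fn(per_pulse[block_id == b]) for b in range(n_blocks)])
    n_powers = len(protocol.powers)
    if n_blocks % n_powers:
        raise DemodulationError(
            f"{n_blocks} measurement blocks do not divide into {n_powers} powers")
    return values.reshape(-1, n_powers)


def demodulate_depths(
    recording: RawRecording,
    protocol: AcquisitionProtocol,
    *,
    power: float | None = None,
    depth_grid_um=None,
    guard_samples: int = 1,
    reducer: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth fluorescence at one analysis power.

    Returns ``(depth_grid_um, F)``. The default power is the last entry of
    ``protocol.powers`` (the analysis power, 1 mW/mm^2 in the flat
    protocol); the default depth grid steps 100 um from the surface.
    """
    F = demodulate(recording, protocol, guard_samples=guard_samples, reducer=reducer)
    powers = np.asarray(protocol.powers, dtype=float)
    idx = len(powers) - 1 if power is None else int(np.argmin(np.abs(powers - power)))
    values = F[:, idx]
    if depth_grid_um is None:
        depth_grid_um = 100.0 * np.arange(len(values))
    depth_grid_um = np.asarray(depth_grid_um, dtype=float)
    if len(depth_grid_um) != len(values):
        raise DemodulationError("depth grid length does not match measurements")
    return depth_grid_um, values


def depth_zscore(
    depth_grid_um,
    F,
    baseline_range_um: tuple[float, float] = (0.0, 400.0),
) -> ZProfile:
    """Z-score fluorescence against the superficial baseline window.

    dF = (F - mean(F0)) / std(F0) with F0 = all values at depths inside
    ``baseline_range_um`` (closed interval; the default 0-400 um covers
    five depths at 100-um steps). Sample standard deviation (ddof=1).
    """
    depth_grid_um = np.asarray(depth_grid_um, dtype=float)
    F = np.asarray(F, dtype=float)
    lo, hi = baseline_range_um
    in_base = (depth_grid_um >= lo) & (depth_grid_um <= hi)
    if in_base.sum() < 2:
        raise DegenerateInputError("baseline window must contain >= 2 depths")
    f0 = F[in_base]
    sd = f0.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("baseline has zero variance; z-score undefined")
    return ZProfile(depth_grid_um=depth_grid_um, dF=(F - f0.mean()) / sd,
                    baseline_window_um=(lo, hi), raw_F=F)


def median_filter(values, window: int = 4) -> np.ndarray:
    """Moving median with edge truncation.

    The window at index i covers ``[i - (window-1)//2, i + window//2]``
    (for the even default 4: indices i-1..i+2), truncated at the array
    edges; the output length equals the input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    n = len(v)
    left = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i - left + window)
        out[i] = np.median(v[lo:hi])
    return out


def median_smooth(profile: ZProfile, window: int = 4) -> ZProfile:
    """Median-filtered copy of a z-scored depth profile (default window 4)."""
    return replace(profile, dF=median_filter(profile.dF, window))


def correlate_profiles(photometry: ZProfile, histology: DepthProfile) -> SpearmanResult:
    """Spearman correlation of a photometry profile against plaque density.

    The histology profile is resampled to the photometry grid by nearest
    depth station (grids built by the pipeline already coincide).
    """
    idx = np.abs(np.asarray(histology.depth_grid_um)[None, :]
                 - np.asarray(photometry.depth_grid_um)[:, None]).argmin(axis=1)
    return spearman(photometry.dF, np.asarray(histology.density_per_mm3)[idx])
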