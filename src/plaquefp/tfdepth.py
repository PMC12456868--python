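"""In vivo tapered-fiber depth-resolved photometry.

A galvo mirror steps the light-injection angle through 41 levels over
0-4.5 V (each level probing an axial station ~39.5 um apart along the
taper) while the laser pulses 10 ms on / 5 ms off. This module turns such
recordings into a galvo-level x time fluorescence matrix, calibrates the
per-level excitation power, removes the per-level linear autofluorescence
drift predicted from a tracer-free day-0 session, bins the tracer signal
in 5-min windows, locates the depths of extreme signal change, z-scores
their time courses, and extracts late-window depth profiles for comparison
with histology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .flatphot import median_filter
from .stats import DegenerateInputError, GroupComparison, paired_wilcoxon
from .synthgen import AcquisitionProtocol, RawRecording, level_voltages


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class PowerCalibration:
    """Relative required power per galvo level: PR = (1/F) / min(1/F)."""

    levels_v: np.ndarray
    PR: np.ndarray

    def __post_init__(self):
        if np.any(self.PR < 1.0 - 1e-12) or not np.isclose(self.PR.min(), 1.0):
            raise ValueError("PR must be >= 1 with min exactly 1")


@dataclass(frozen=True)
class GalvoScanMatrix:
    """Demodulated fluorescence per (galvo level, scan timepoint)."""

    levels_v: np.ndarray
    times_s: np.ndarray
    F: np.ndarray                 # (n_levels, n_times); NaN marks missing
    channel: str = "440nm"
    power_uw: float = 120.0

    def __post_init__(self):
        if self.F.shape != (len(self.levels_v), len(self.times_s)):
            raise ValueError("F must be (n_levels, n_times)")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class AFModel:
    """Per-level linear autofluorescence model AF = a*t + b."""

    slopes: np.ndarray
    intercepts: np.ndarray
    cv_error: np.ndarray

    def predict(self, times_s) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        return self.slopes[:, None] * t[None, :] + self.intercepts[:, None]


@dataclass(frozen=True)
class BinnedMatrix:
    """Time-binned tracer signal (default 5-min bins)."""

    levels_v: np.ndarray
    bin_mid_s: np.ndarray
    F: np.ndarray
    bin_s: float = 300.0
    partial_last: bool = False


@dataclass(frozen=True)
class LevelProfile:
    """Per-level signal mapped onto axial depth along the taper."""

    levels_v: np.ndarray
    depth_um: np.ndarray
    values: np.ndarray


def calibrate_power(F_per_level, levels_v=None) -> PowerCalibration:
    """Relative required power that equalizes fluorescence along the taper.

    Measured in a uniform dye bath: PR(level) = (1/F) / min(1/F), so the
    brightest level needs relative power exactly 1 and every other level
    proportionally more.
    """
    F = np.asarray(F_per_level, dtype=float)
    if np.any(F <= 0) or not np.all(np.isfinite(F)):
        raise ValueError("calibration fluorescence must be positive and finite")
    inv = 1.0 / F
    if levels_v is None:
        levels_v = level_voltages(len(F))
    return PowerCalibration(levels_v=np.asarray(levels_v, dtype=float),
                            PR=inv / inv.min())


def demodulate_scan(
    recording: RawRecording,
    protocol: AcquisitionProtocol,
    *,
    n_levels: int = 41,
    power_uw: float | None = None,
    guard_samples: int = 1,
) -> GalvoScanMatrix:
    """Demodulate a galvo-scan recording into a level x timepoint matrix.

    Light-on pulses are located from the sync channel; each pulse's
    fluorescence is the mean of its detector samples inside the on window
    (one guard sample dropped per edge) and its galvo level is the nearest
    point of the ``n_levels`` grid over 0-4.5 V (spacing 4.5/40 =
    0.1125 V by default). Pulses at negative galvo voltage are discarded.
    Pulse groups separated by more than two pulse periods form scan
    timepoints, stamped with the group's first light-on sample time; when
    the protocol interleaves several powers, each timepoint is split into
    equal consecutive power blocks and the requested power selected
    (default: the analysis power, the last protocol entry). Per (level,
    timepoint) the fluorescence is the mean over assigned pulses; levels a
    scan never visited are NaN and flagged with a warning.
    """
    sync = np.asarray(recording.sync) > 0.5
    edges = np.diff(sync.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    if sync[0]:
        starts = np.insert(starts, 0, 0)
    if len(starts) == 0:
        raise ScanError("no light-on pulse found")
    on_n = protocol.on_samples
    if np.any(starts + on_n > len(recording.detector)):
        starts = starts[starts + on_n <= len(recording.detector)]
    window = np.arange(guard_samples, on_n - guard_samples)
    pulse_vals = recording.detector[starts[:, None] + window[None, :]].mean(axis=1)
    pulse_v = recording.galvo[starts + on_n // 2]
    pulse_t = recording.t[starts]

    period_s = (protocol.on_ms + protocol.off_ms) / 1000.0
    new_tp = np.ones(len(starts), dtype=bool)
    new_tp[1:] = np.diff(pulse_t) > 2.0 * period_s
    tp_id = np.cumsum(new_tp) - 1
    n_tp = tp_id[-1] + 1
    tp_times = pulse_t[new_tp]

    powers = np.asarray(protocol.powers, dtype=float)
    p_idx = len(powers) - 1 if power_uw is None else int(np.argmin(np.abs(powers - power_uw)))

    levels = level_voltages(n_levels, protocol.galvo_range_v[1])
    spacing = levels[1] - levels[0]
    F = np.full((n_levels, n_tp), np.nan)
    for k in range(n_tp):
        sel = tp_id == k
        vals, volts = pulse_vals[sel], pulse_v[sel]
        if len(powers) > 1:
            if len(vals) % len(powers):
                raise ScanError(f"timepoint {k}: pulses do not divide into powers")
            m = len(vals) // len(powers)
            vals = vals[p_idx * m:(p_idx + 1) * m]
            volts = volts[p_idx * m:(p_idx + 1) * m]
        keep = volts >= -1e-12
        vals, volts = vals[keep], volts[keep]
        idx = np.clip(np.rint(volts / spacing).astype(int), 0, n_levels - 1)
        sums = np.bincount(idx, weights=vals, minlength=n_levels)
        counts = np.bincount(idx, minlength=n_levels)
        with np.errstate(invalid="ignore"):
            F[:, k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.isnan(F).any():
        warnings.warn("some galvo levels were never visited; carried as missing",
                      stacklevel=2)
    return GalvoScanMatrix(levels_v=levels, times_s=tp_times, F=F,
                           power_uw=powers[p_idx] if power_uw is None else power_uw)


def fit_autofluorescence(day0: GalvoScanMatrix) -> AFModel:
    """Per-level linear autofluorescence fit with twofold cross-validation.

    Folds interleave scan timepoints (odd/even); each fold is fitted by
    least squares, the reported coefficients are the fold average, and
    ``cv_error`` is the mean held-out squared error per level.
    """
    t = day0.times_s
    if len(t) < 4:
        raise ScanError("autofluorescence fit needs >= 4 timepoints per level")
    fold_a = np.arange(len(t)) % 2 == 0
    folds = (fold_a, ~fold_a)
    n_levels = len(day0.levels_v)
    slopes = np.empty(n_levels)
    intercepts = np.empty(n_levels)
    cv_err = np.empty(n_levels)
    for lv in range(n_levels):
        y = day0.F[lv]
        coefs, errs = [], []
        for fit_mask, test_mask in ((folds[0], folds[1]), (folds[1], folds[0])):
            ok = fit_mask & np.isfinite(y)
            if ok.sum() < 2:
                raise ScanError(f"level {lv}: < 2 points in a CV fold")
            c = np.polyfit(t[ok], y[ok], 1)
            coefs.append(c)
            ok_t = test_mask & np.isfinite(y)
            errs.append(np.mean((np.polyval(c, t[ok_t]) - y[ok_t]) ** 2))
        mean_c = np.mean(coefs, axis=0)
        slopes[lv], intercepts[lv] = mean_c[0], mean_c[1]
        cv_err[lv] = np.mean(errs)
    return AFModel(slopes=slopes, intercepts=intercepts, cv_error=cv_err)


def subtract_af(day1: GalvoScanMatrix, model: AFModel) -> GalvoScanMatrix:
    """Tracer signal Fm = F - (a*t + b), on day 1's own session clock."""
    if len(model.slopes) != len(day1.levels_v):
        raise ScanError("autofluorescence model level grid does not match")
    return replace(day1, F=day1.F - model.predict(day1.times_s))


def bin_timecourse(mat: GalvoScanMatrix, bin_s: float = 300.0) -> BinnedMatrix:
    """Mean signal per (level, time bin); the partial trailing bin is kept
    and flagged."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    idx = np.floor(mat.times_s / bin_s).astype(int)
    n_bins = idx.max() + 1
    F = np.full((len(mat.levels_v), n_bins), np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                F[:, b] = np.nanmean(mat.F[:, sel], axis=1)
    partial = mat.times_s.max() < n_bins * bin_s - 1e-9
    return BinnedMatrix(levels_v=mat.levels_v,
                        bin_mid_s=(np.arange(n_bins) + 0.5) * bin_s,
                        F=F, bin_s=bin_s, partial_last=bool(partial))


def extrema_depths(binned: BinnedMatrix,
                   window_min: tuple[float, float] = (30.0, 240.0)) -> dict:
    """Galvo levels with the maximum and minimum median signal in a window.

    Medians are taken per level over bins whose midpoints fall inside
    ``window_min`` (minutes, inclusive); ties break toward the lower level
    index. Missing bins are excluded from the medians.
    """
    mid_min = binned.bin_mid_s / 60.0
    sel = (mid_min >= window_min[0]) & (mid_min <= window_min[1])
    if not sel.any():
        raise ScanError("extrema window contains no bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(binned.F[:, sel], axis=1)
    return {"max_level": int(np.nanargmax(med)),
            "min_level": int(np.nanargmin(med)),
            "median_per_level": med}


def zscore_trace(binned: BinnedMatrix, level: int, *,
                 baseline_min: float = 25.0, smooth_window: int = 3) -> np.ndarray:
    """Z-scored, median-smoothed tracer time course at one galvo level.

    The baseline F0 is the set of bins wholly inside the first
    ``baseline_min`` minutes; dF = (Fm - mean(F0)) / std(F0) (sample std),
    followed by a moving median (default window 3).
    """
    trace = binned.F[level]
    base = binned.bin_mid_s / 60.0 < baseline_min
    f0 = trace[base & np.isfinite(trace)]
    if len(f0) < 2:
        raise DegenerateInputError("baseline needs >= 2 bins")
    sd = f0.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero baseline variance; z-score undefined")
    return median_filter((trace - f0.mean()) / sd, smooth_window)


def galvo_depth_map(levels_v, *, entry_depth_um: float = 0.0,
                    span_um: float = 1580.0, v_max: float = 4.5,
                    orientation: int = 1, shift_um: float = 0.0) -> np.ndarray:
    """Affine galvo-voltage -> axial-depth map along the taper.

    With ``orientation=+1``, 0 V probes the shallow end and ``v_max`` the
    deep end of the active span (the sweep direction is hardware-dependent,
    hence configurable); ``shift_um`` applies the histology track
    correction so photometry and histology stations coincide.
    """
    v = np.asarray(levels_v, dtype=float)
    frac = v / v_max if orientation >= 0 else 1.0 - v / v_max
    return entry_depth_um + frac * span_um + shift_um


def depth_profile_window(
    binned: BinnedMatrix,
    window_min: tuple[float, float] = (210.0, 240.0),
    **depth_map_kwargs,
) -> LevelProfile:
    """Mean tracer signal per level over a late time window, mapped to depth.

    The default 210-240 min window samples the near-plateau tracer signal
    for comparison against the histological plaque-density profile.
    """
    mid_min = binned.bin_mid_s / 60.0
    sel = (mid_min >= window_min[0]) & (mid_min <= window_min[1])
    if not sel.any():
        raise ScanError("profile window contains no bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(binned.F[:, sel], axis=1)
    return LevelProfile(levels_v=binned.levels_v,
                        depth_um=galvo_depth_map(binned.levels_v, **depth_map_kwargs),
                        values=values)


def paired_extrema_test(dF_max, dF_min) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank on per-recording (max - min) signal
    at a fixed timepoint (default usage: 90 min post-injection)."""
    return paired_wilcoxon(dF_max, dF_min)
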