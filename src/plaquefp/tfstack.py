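"""Ex vivo tapered-fiber stack analysis.

A tapered fiber (TF) lying in the plane of a brain slice is imaged while a
galvo mirror sweeps the light-injection angle: each input voltage V
illuminates a band of tissue at a voltage-dependent axial position along
the taper. Combining the per-voltage illumination fields I(x,y,V) with the
fiber's collection field C(x,y) gives the photometry stack

    P(x,y,V) = C(x,y) * I(x,y,V),

whose per-voltage integral, attributed to the illumination-band centroid,
simulates a depth-resolved photometry measurement that can be compared to
the plaque density profile of the same slice.

Image convention: rows = transverse (radial) axis, columns = axial position
along the fiber; pixel centres at ``(index + 0.5) * pixel_um``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stats import SpearmanResult, spearman


class NoPeakError(ValueError):
    """Frame indistinguishable from the terminal-angle baseline."""


@dataclass(frozen=True)
class CollectionField:
    """Collection-efficiency map C(x,y) of the fiber (non-negative)."""

    data: np.ndarray
    pixel_um: float
    axis_row: float          # transverse position of the fiber axis, pixels

    def __post_init__(self):
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError("collection field must be finite and non-negative")


@dataclass(frozen=True)
class IlluminationStack:
    """Per-voltage illumination fields I(x,y,V), globally normalized to 1."""

    data: np.ndarray         # (n_voltages, rows, cols)
    voltages: np.ndarray
    pixel_um: float

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] != len(self.voltages):
            raise ValueError("stack must be (n_voltages, rows, cols)")
        if np.any(self.data < 0):
            raise ValueError("illumination must be non-negative")


@dataclass(frozen=True)
class PhotometryStack:
    """Elementwise product P = C x I; bounded above by C since I <= 1."""

    data: np.ndarray
    voltages: np.ndarray
    pixel_um: float


@dataclass(frozen=True)
class AxialProfile:
    """Intensity or plaque count against axial position along the fiber."""

    positions_um: np.ndarray
    values: np.ndarray
    kind: str = "photometry"   # photometry | reference_count | collection_count

    def __post_init__(self):
        if len(self.positions_um) != len(self.values):
            raise ValueError("positions and values must share a length")
        if len(self.positions_um) > 1 and not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("positions must be strictly increasing")


def preprocess_stack(
    raw: np.ndarray,
    voltages,
    pixel_um: float,
    *,
    background: float | str = "frame_min",
) -> IlluminationStack:
    """Background-subtract and normalize a raw illumination stack.

    Per frame, the background (frame minimum, or a supplied constant) is
    subtracted and negatives clipped to zero; the whole stack is then
    divided by its global maximum so the stack max is exactly 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[0] == 0:
        raise ValueError("raw stack must be non-empty (n_voltages, rows, cols)")
    if background == "frame_min":
        bg = raw.min(axis=(1, 2), keepdims=True)
    else:
        bg = float(background)
    out = np.clip(raw - bg, 0.0, None)
    peak = out.max()
    if peak == 0.0:
        raise ValueError("stack is all background; cannot normalize")
    return IlluminationStack(data=out / peak, voltages=np.asarray(voltages, dtype=float),
                             pixel_um=float(pixel_um))


def terminal_baseline(stack: IlluminationStack) -> np.ndarray:
    """Baseline frame: mean of the first and last voltage frames.

    The terminal input angles deliver a negligible amount of light into the
    tissue, so their frames estimate the angle-independent background.
    """
    return 0.5 * (stack.data[0] + stack.data[-1])


def illumination_centroid(frame: np.ndarray, baseline: np.ndarray, pixel_um: float) -> float:
    """Axial centroid (um) of the illumination peak after baseline removal.

    Subtracts the terminal-angle baseline, clips at zero, projects onto the
    fiber axis (sum over the transverse rows) and returns the
    intensity-weighted mean axial coordinate.
    """
    frame = np.asarray(frame, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if frame.shape != baseline.shape:
        raise ValueError("frame and baseline must share a shape")
    resid = np.clip(frame - baseline, 0.0, None)
    axial_mass = resid.sum(axis=0)
    total = axial_mass.sum()
    if total <= 0.0:
        raise NoPeakError("no residual intensity above the terminal baseline")
    z = (np.arange(frame.shape[1]) + 0.5) * pixel_um
    return float((axial_mass @ z) / total)


def photometry_stack(C: CollectionField, I: IlluminationStack) -> PhotometryStack:
    """P(x,y,V) = C(x,y) * I(x,y,V), pixel by pixel."""
    if C.data.shape != I.data.shape[1:]:
        raise ValueError("collection field and illumination frames must share a shape")
    if C.pixel_um != I.pixel_um:
        raise ValueError("pixel sizes must match")
    P = I.data * C.data[None, :, :]
    assert np.all(P >= 0.0)
    assert np.all(P <= C.data[None, :, :] * I.data.max() + 1e-12)
    return PhotometryStack(data=P, voltages=I.voltages, pixel_um=I.pixel_um)


def photometry_profile(P: PhotometryStack, centroids_um) -> AxialProfile:
    """Simulated photometry intensities against axial position.

    ``centroids_um`` holds one axial centroid per voltage; NaN marks frames
    whose centroid extraction raised no-peak, and those frames are dropped
    with a warning. The intensity at each voltage is the integral (sum) of
    its photometry-stack frame; the output is sorted by position.
    """
    centroids = np.asarray(centroids_um, dtype=float)
    if centroids.shape != (P.data.shape[0],):
        raise ValueError("need exactly one centroid (or NaN) per voltage")
    keep = np.isfinite(centroids)
    if not keep.any():
        raise ValueError("all frames were dropped; no profile can be formed")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} frame(s) without an "
                      "illumination peak", stacklevel=2)
    values = P.data[keep].sum(axis=(1, 2))
    positions = centroids[keep]
    order = np.argsort(positions, kind="stable")
    return AxialProfile(positions_um=positions[order], values=values[order],
                        kind="photometry")


def stack_centroids(stack: IlluminationStack) -> np.ndarray:
    """Per-voltage axial centroids; NaN where no peak rises above baseline."""
    base = terminal_baseline(stack)
    out = np.empty(stack.data.shape[0])
    for i, frame in enumerate(stack.data):
        try:
            out[i] = illumination_centroid(frame, base, stack.pixel_um)
        except NoPeakError:
            out[i] = np.nan
    return out


def roi_count_profile(
    points_um: np.ndarray,
    axis_x_um: float,
    z_start_um: float,
    z_stop_um: float,
    *,
    radius_um: float = 250.0,
    step_um: float = 40.0,
    kind: str = "reference_count",
) -> AxialProfile:
    """Moving circular-ROI plaque counts along the fiber axis (slice plane).

    ``points_um`` is (n, 2) with columns (z axial, x transverse). A circle
    of ``radius_um`` centred on the axis is stepped every ``step_um`` from
    ``z_start_um`` to ``z_stop_um`` (inclusive); the profile holds the
    number of plaque centres inside the circle at each station.
    """
    if radius_um <= 0 or step_um <= 0:
        raise ValueError("radius_um and step_um must be positive")
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    n_steps = int(round((z_stop_um - z_start_um) / step_um)) + 1
    stations = z_start_um + step_um * np.arange(n_steps)
    if pts.shape[0] == 0:
        counts = np.zeros(n_steps)
    else:
        dz = pts[:, 0][None, :] - stations[:, None]
        dx = pts[:, 1] - axis_x_um
        counts = (dz**2 + dx[None, :] ** 2 <= radius_um**2).sum(axis=1).astype(float)
    return AxialProfile(positions_um=stations, values=counts, kind=kind)


def compare_profiles(photometry: AxialProfile, reference: AxialProfile) -> SpearmanResult:
    """Spearman correlation between a photometry and a reference profile.

    The reference is scaled by its maximum and resampled onto the
    photometry positions by nearest station before correlating.
    """
    ref_vals = reference.values
    peak = np.max(np.abs(ref_vals))
    if peak > 0:
        ref_vals = ref_vals / peak
    idx = np.abs(reference.positions_um[None, :]
                 - photometry.positions_um[:, None]).argmin(axis=1)
    return spearman(photometry.values, ref_vals[idx])
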