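"""Synthetic ground-truth generators for every input the pipeline consumes.

The generators emulate the study conditions end to end: genotype-dependent
3-D amyloid-plaque fields (inhomogeneous Poisson point process over depth),
disk-particle fluorescence section images, tapered-fiber illumination
stacks whose bands sweep axially with galvo voltage, radially decaying
collection fields, and modulated photometry recordings (pulsed light
source, sync and galvo channels at 5000 Hz) with a linear autofluorescence
drift plus a saturating post-injection tracer rise.

Depth convention shared by all modules: DV in um, positive downward, 0 at
the brain surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .histomap import SectionImage
from .tfstack import CollectionField, IlluminationStack


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaqueField:
    """3-D plaque centroids (AP, ML, DV in um) with equivalent diameters."""

    points: np.ndarray            # (n, 3)
    diameters_um: np.ndarray      # (n,)
    genotype_label: str = "affected"

    def __post_init__(self):
        if self.points.shape != (len(self.diameters_um), 3):
            raise ValidationError("points must be (n, 3) matching diameters")
        if len(self.diameters_um) and np.any(self.diameters_um <= 0):
            raise ValidationError("all diameters must be positive")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValidationError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.diameters_um)


@dataclass(frozen=True)
class TaperGeometry:
    """Tapered-fiber geometry: tip position, axis and optically active span."""

    tip: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    emission_length_um: float = 1800.0
    active_span_um: float = 1580.0     # 40 galvo steps x 39.5 um

    def __post_init__(self):
        if not np.isclose(np.linalg.norm(self.axis), 1.0):
            raise ValidationError("axis must be a unit vector")
        if not (0.0 < self.active_span_um <= self.emission_length_um):
            raise ValidationError("0 < active_span <= emission_length required")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Pulsed-illumination protocol shared by flat- and tapered-fiber rigs."""

    on_ms: float = 10.0
    off_ms: float = 5.0
    reps: int = 10                    # pulses (flat) or sweeps (TF) per measure
    powers: tuple[float, ...] = (1.0,)
    sample_rate_hz: float = 5000.0
    galvo_range_v: tuple[float, float] = (-1.0, 4.5)
    scan_interval_s: float = 300.0
    baseline_ms: float = 10.0         # gap separating flat measurement blocks

    def __post_init__(self):
        if self.on_ms <= 0 or self.off_ms <= 0:
            raise ValidationError("on_ms and off_ms must be positive")
        on_samples = self.sample_rate_hz * self.on_ms / 1000.0
        if abs(on_samples - round(on_samples)) > 1e-9:
            raise ValidationError("on_ms must map to an integer sample count")

    @property
    def on_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.on_ms / 1000.0))

    @property
    def off_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.off_ms / 1000.0))

    @property
    def baseline_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.baseline_ms / 1000.0))

    @property
    def duty_cycle(self) -> float:
        return self.on_ms / (self.on_ms + self.off_ms)


@dataclass(frozen=True)
class RawRecording:
    """Multiplexed photometry time-series: detector, sync and galvo channels.

    ``t`` is explicit (seconds); idle gaps between scan blocks are not
    materialized, so ``t`` may be non-uniform across blocks.
    """

    t: np.ndarray
    detector: np.ndarray
    sync: np.ndarray
    galvo: np.ndarray
    meta: dict

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.detector) == len(self.sync) == len(self.galvo) == n):
            raise ValidationError("all channels must share a length")
        if not np.isin(self.sync, (0, 1)).all():
            raise ValidationError("sync must be 0/1")
        lo, hi = self.meta.get("galvo_range_v", (-1.0, 4.5))
        on = self.sync == 1
        if on.any() and (np.any(self.galvo[on] < lo - 1e-9) or np.any(self.galvo[on] > hi + 1e-9)):
            raise ValidationError("galvo out of range during light-on periods")


# ---------------------------------------------------------------------------
# plaque fields and section images
# ---------------------------------------------------------------------------

def make_plaque_field(
    density_profile: Callable[[np.ndarray], np.ndarray] | float,
    volume_um: Sequence[Sequence[float]],
    seed: int,
    *,
    diameter_range_um: tuple[float, float] = (11.0, 20.0),
    genotype_label: str = "affected",
) -> PlaqueField:
    """Draw plaques from an inhomogeneous Poisson process over depth.

    ``density_profile`` maps DV depth (um) to intensity in plaques/mm^3
    (a scalar is taken as a constant profile); ``volume_um`` is the box
    ``((ap0, ap1), (ml0, ml1), (dv0, dv1))``. Sampling is by thinning: a
    homogeneous process at the profile maximum is thinned by the ratio
    density(dv)/max. Diameters are i.i.d. uniform on ``diameter_range_um``
    (default 11-20 um, the band the detection filter passes).
    """
    (ap0, ap1), (ml0, ml1), (dv0, dv1) = [tuple(map(float, b)) for b in volume_um]
    spans = np.array([ap1 - ap0, ml1 - ml0, dv1 - dv0])
    if np.any(spans <= 0):
        raise ValidationError("volume box must be nondegenerate")
    if callable(density_profile):
        dens = density_profile
    else:
        const = float(density_profile)
        dens = lambda d: np.full_like(np.asarray(d, dtype=float), const)
    dv_grid = np.linspace(dv0, dv1, 513)
    lam = np.asarray(dens(dv_grid), dtype=float)
    if np.any(lam < 0) or not np.all(np.isfinite(lam)):
        raise ValidationError("density profile must be finite and >= 0")
    lam_max = float(lam.max())
    rng = np.random.default_rng(seed)
    if lam_max == 0.0:
        points = np.empty((0, 3))
    else:
        vol_mm3 = float(np.prod(spans)) / 1e9
        n_hom = rng.poisson(lam_max * vol_mm3)
        pts = rng.uniform([ap0, ml0, dv0], [ap1, ml1, dv1], size=(n_hom, 3))
        keep = rng.uniform(size=n_hom) < np.asarray(dens(pts[:, 2]), dtype=float) / lam_max
        points = pts[keep]
    lo_d, hi_d = diameter_range_um
    diameters = rng.uniform(lo_d, hi_d, size=len(points))
    return PlaqueField(points=points, diameters_um=diameters,
                       genotype_label=genotype_label)


def render_section_image(
    field: PlaqueField,
    ap_um: float,
    thickness_um: float,
    pixel_um: float,
    noise_sd: float,
    seed: int,
    *,
    ml_range_um: tuple[float, float] = (0.0, 2000.0),
    dv_range_um: tuple[float, float] = (0.0, 4000.0),
    amplitude: float = 1.0,
) -> SectionImage:
    """Render the plaques of one coronal section as filled disks.

    Plaques whose centroid AP falls within ``thickness_um / 2`` of the
    section plane are drawn as disks of their equivalent diameter at full
    ``amplitude`` over a zero background, then i.i.d. Gaussian noise of sd
    ``noise_sd`` is added. An empty intersection yields a valid
    all-background image.
    """
    if pixel_um <= 0 or thickness_um <= 0:
        raise ValidationError("pixel_um and thickness_um must be positive")
    ml0, ml1 = ml_range_um
    dv0, dv1 = dv_range_um
    rows = int(round((dv1 - dv0) / pixel_um))
    cols = int(round((ml1 - ml0) / pixel_um))
    img = np.zeros((rows, cols))
    if field.n:
        in_slab = np.abs(field.points[:, 0] - ap_um) <= thickness_um / 2.0
        for (_, ml, dv), diam in zip(field.points[in_slab],
                                     field.diameters_um[in_slab]):
            r_um = diam / 2.0
            r0 = max(0, int((dv - dv0 - r_um) / pixel_um) - 1)
            r1 = min(rows, int((dv - dv0 + r_um) / pixel_um) + 2)
            c0 = max(0, int((ml - ml0 - r_um) / pixel_um) - 1)
            c1 = min(cols, int((ml - ml0 + r_um) / pixel_um) + 2)
            if r0 >= r1 or c0 >= c1:
                continue
            yy = dv0 + (np.arange(r0, r1) + 0.5) * pixel_um
            xx = ml0 + (np.arange(c0, c1) + 0.5) * pixel_um
            disk = ((yy[:, None] - dv) ** 2 + (xx[None, :] - ml) ** 2) <= r_um**2
            img[r0:r1, c0:c1][disk] = amplitude
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return SectionImage(data=img, pixel_um=pixel_um, ap_um=ap_um,
                        ml_origin_um=ml0, dv_origin_um=dv0)


# ---------------------------------------------------------------------------
# taper optical fields
# ---------------------------------------------------------------------------

def illumination_envelope(
    voltages,
    galvo_range_v: tuple[float, float] = (-1.0, 4.5),
    edge_fraction: float = 0.15,
):
    """Per-voltage emitted-energy envelope of the taper (max 1).

    A flat-top (Tukey) window over the galvo drive range: interior input
    angles couple comparable amounts of light into the tissue while the
    terminal angles deliver a negligible amount, with a cosine roll-off
    over ``edge_fraction`` of the range at each end. This is the closed
    form that frame energies of :func:`make_illumination_stack` follow.
    """
    lo, hi = galvo_range_v
    x = np.clip((np.asarray(voltages, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    edge = np.minimum(x, 1.0 - x)
    ramp = np.sin(np.pi * np.clip(edge / edge_fraction, 0.0, 1.0) / 2.0) ** 2
    return np.where(edge < edge_fraction, ramp, 1.0)


def galvo_to_axial_um(
    voltages,
    geometry: TaperGeometry,
    *,
    margin_um: float = 200.0,
    v_max: float = 4.5,
):
    """Affine galvo-voltage -> axial-position map along the taper.

    0 V maps to the shallow end of the active span (offset ``margin_um``
    from the image edge), ``v_max`` to the deep end; negative voltages
    extrapolate off-tissue.
    """
    v = np.asarray(voltages, dtype=float)
    return margin_um + (v / v_max) * geometry.active_span_um


def make_illumination_stack(
    geometry: TaperGeometry,
    voltages,
    width_um: float = 80.0,
    *,
    pixel_um: float = 10.0,
    rows: int = 61,
    margin_um: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IlluminationStack:
    """Per-voltage illumination fields: axial Gaussian bands that sweep
    monotonically along the active span as the galvo voltage increases.

    ``width_um`` is the Gaussian sd of the band along the fiber axis. The
    stack is normalized so its global maximum is 1; frame energies follow
    :func:`illumination_envelope`.
    """
    voltages = np.asarray(voltages, dtype=float)
    lo, hi = (-1.0, 4.5)
    if np.any(voltages < lo - 1e-9) or np.any(voltages > hi + 1e-9):
        raise ValidationError("voltages must lie within the galvo range")
    if width_um <= 0 or pixel_um <= 0:
        raise ValidationError("width_um and pixel_um must be positive")
    cols = int(round((geometry.active_span_um + 2 * margin_um) / pixel_um))
    z = (np.arange(cols) + 0.5) * pixel_um
    centers = galvo_to_axial_um(voltages, geometry, margin_um=margin_um)
    env = illumination_envelope(voltages)
    bands = env[:, None] * np.exp(-((z[None, :] - centers[:, None]) ** 2)
                                  / (2.0 * width_um**2))
    stack = np.repeat(bands[:, None, :], rows, axis=1)
    if noise_sd > 0:
        stack = np.clip(stack + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=stack.shape), 0.0, None)
    peak = stack.max()
    if peak == 0:
        raise ValidationError("all illumination frames are empty")
    return IlluminationStack(data=stack / peak, voltages=voltages, pixel_um=pixel_um)


def make_collection_field(
    geometry: TaperGeometry,
    radial_decay_um: float,
    *,
    pixel_um: float = 10.0,
    rows: int = 61,
    cols: int | None = None,
    margin_um: float = 200.0,
    fiber_radius_um: float = 0.0,
) -> CollectionField:
    """Collection-efficiency field: exponential decay with radial distance
    from the fiber axis, zero inside the fiber footprint.

    The axis runs along the middle pixel row. With the default zero
    footprint the field is maximal (1) on the axis and strictly decreasing
    radially with length constant ``radial_decay_um``.
    """
    if radial_decay_um <= 0:
        raise ValidationError("radial_decay_um must be positive")
    if rows % 2 == 0:
        raise ValidationError("rows must be odd so the axis lies on a pixel row")
    if cols is None:
        cols = int(round((geometry.active_span_um + 2 * margin_um) / pixel_um))
    axis_row = (rows - 1) // 2
    x = (np.arange(rows) + 0.5) * pixel_um
    r = np.abs(x - x[axis_row])
    prof = np.exp(-np.maximum(r - fiber_radius_um, 0.0) / radial_decay_um)
    prof[r < fiber_radius_um] = 0.0
    data = np.repeat(prof[:, None], cols, axis=1)
    return CollectionField(data=data, pixel_um=pixel_um, axis_row=float(axis_row))


# ---------------------------------------------------------------------------
# photometry recordings
# ---------------------------------------------------------------------------

def tracer_term(t, density, gain: float, injection_time_s: float, rise_tau_s: float):
    """Saturating tracer fluorescence: gain * density * (1 - exp(-(t-t0)/tau))."""
    t = np.asarray(t, dtype=float)
    rise = np.where(t >= injection_time_s,
                    1.0 - np.exp(-np.clip(t - injection_time_s, 0.0, None) / rise_tau_s),
                    0.0)
    return gain * np.asarray(density, dtype=float) * rise


def level_voltages(n_levels: int = 41, v_max: float = 4.5) -> np.ndarray:
    """The galvo analysis grid: ``n_levels`` levels over [0, v_max] V."""
    return np.linspace(0.0, v_max, n_levels)


def scan_truth(meta: dict, times) -> np.ndarray:
    """Noiseless per-level fluorescence the generating model assigns at the
    given scan times: shape (n_levels, n_times), at the analysis power."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    a = np.asarray(meta["af_slope_per_level"], dtype=float)[:, None]
    b = np.asarray(meta["af_intercept_per_level"], dtype=float)[:, None]
    dens = np.asarray(meta["density_per_level"], dtype=float)[:, None]
    sens = np.asarray(meta["sensitivity_per_level"], dtype=float)[:, None]
    pw = np.asarray(meta["power_per_level"], dtype=float)[:, None]
    f = a * times[None, :] + b + tracer_term(times[None, :], dens, meta["gain"],
                                             meta["injection_time_s"],
                                             meta["rise_tau_s"])
    return sens * pw * f


def simulate_recording(
    field_profile,
    protocol: AcquisitionProtocol,
    af_slope_per_level,
    af_intercept_per_level,
    injection_time_s: float,
    rise_tau_s: float,
    noise_sd: float,
    seed: int,
    *,
    duration_s: float = 15000.0,
    gain: float = 1.0,
    n_levels: int = 41,
    sensitivity_per_level=None,
    power_per_level=None,
) -> RawRecording:
    """Simulate an in vivo tapered-fiber galvo-scan session.

    Every ``protocol.scan_interval_s`` a scan block runs: for each power,
    ``protocol.reps`` sweeps of one 10-ms pulse per galvo step (about nine
    sub-zero steps followed by the ``n_levels`` analysis levels over
    0-4.5 V; the galvo is constant within a pulse and 0 between pulses).
    During each pulse the detector reads the per-level model fluorescence

        F(level, t) = a*t + b + gain * density(level) * (1 - exp(-(t-t_inj)/tau))

    evaluated at the scan start time, scaled by the per-level sensitivity
    and power calibration, plus Gaussian sample noise. Idle time between
    scan blocks is not materialized (``t`` is explicit). Control sessions
    pass a zero density profile; pre-injection sessions an
    ``injection_time_s`` beyond ``duration_s``.
    """
    density = _density_per_level(field_profile, n_levels)
    a = np.broadcast_to(np.asarray(af_slope_per_level, dtype=float), (n_levels,))
    b = np.broadcast_to(np.asarray(af_intercept_per_level, dtype=float), (n_levels,))
    if rise_tau_s <= 0:
        raise ValidationError("rise_tau_s must be positive")
    sens = np.ones(n_levels) if sensitivity_per_level is None else \
        np.broadcast_to(np.asarray(sensitivity_per_level, dtype=float), (n_levels,))
    pw = np.ones(n_levels) if power_per_level is None else \
        np.broadcast_to(np.asarray(power_per_level, dtype=float), (n_levels,))

    levels = level_voltages(n_levels, protocol.galvo_range_v[1])
    spacing = levels[1] - levels[0]
    n_pre = int(np.ceil(-protocol.galvo_range_v[0] / spacing))
    pre_v = protocol.galvo_range_v[0] + spacing * np.arange(n_pre)
    sweep_v = np.concatenate([pre_v, levels])
    n_powers = len(protocol.powers)
    ref_power = protocol.powers[-1]
    pulses_per_tp = n_powers * protocol.reps * len(sweep_v)

    scan_times = np.arange(0.0, duration_s, protocol.scan_interval_s)
    on_n, off_n = protocol.on_samples, protocol.off_samples
    pulse_n = on_n + off_n
    fs = protocol.sample_rate_hz

    # per-pulse voltage and power pattern, identical across timepoints
    v_pattern = np.tile(sweep_v, n_powers * protocol.reps)
    p_pattern = np.repeat(np.asarray(protocol.powers, dtype=float),
                          protocol.reps * len(sweep_v))
    lvl_idx = np.rint(v_pattern / spacing).astype(int)
    in_range = v_pattern >= -1e-12

    meta = {
        "kind": "tf_scan",
        "protocol": protocol,
        "galvo_range_v": protocol.galvo_range_v,
        "n_levels": n_levels,
        "level_voltages": levels,
        "density_per_level": density,
        "af_slope_per_level": a,
        "af_intercept_per_level": b,
        "sensitivity_per_level": sens,
        "power_per_level": pw,
        "gain": gain,
        "injection_time_s": injection_time_s,
        "rise_tau_s": rise_tau_s,
        "seed": seed,
        "scan_times_s": scan_times,
    }

    n_tp = len(scan_times)
    truth = scan_truth(meta, scan_times)          # (n_levels, n_tp)
    # per-pulse ON value for every timepoint
    vals = np.zeros((n_tp, pulses_per_tp))
    safe_idx = np.clip(lvl_idx, 0, n_levels - 1)
    vals[:, :] = np.where(in_range[None, :],
                          truth[safe_idx, :].T * (p_pattern / ref_power)[None, :],
                          0.0)

    block = np.zeros((n_tp, pulses_per_tp, pulse_n))
    block[:, :, :on_n] = vals[:, :, None]
    sync = np.zeros((pulses_per_tp, pulse_n))
    sync[:, :on_n] = 1.0
    galvo = np.zeros((pulses_per_tp, pulse_n))
    galvo[:, :on_n] = v_pattern[:, None]

    detector = block.reshape(n_tp, -1)
    if noise_sd > 0:
        detector = detector + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=detector.shape)
    t_block = np.arange(pulses_per_tp * pulse_n) / fs
    t = (scan_times[:, None] + t_block[None, :]).ravel()
    return RawRecording(
        t=t,
        detector=detector.ravel(),
        sync=np.tile(sync.ravel(), n_tp),
        galvo=np.tile(galvo.ravel(), n_tp),
        meta=meta,
    )


def _density_per_level(field_profile, n_levels: int) -> np.ndarray:
    """Accept a DepthProfile, an array of per-level densities, or a scalar."""
    if hasattr(field_profile, "density_per_mm3"):
        density = np.asarray(field_profile.density_per_mm3, dtype=float)
    elif np.isscalar(field_profile):
        density = np.full(n_levels, float(field_profile))
    else:
        density = np.asarray(field_profile, dtype=float)
    if density.shape != (n_levels,):
        raise ValidationError(
            f"density profile has {density.shape} entries; protocol expects {n_levels}")
    return density


def simulate_flat_recording(
    F_per_depth,
    protocol: AcquisitionProtocol,
    noise_sd: float,
    seed: int,
) -> RawRecording:
    """Simulate a flat-fiber depth-series recording.

    For each depth (in order) and each power, the light source runs
    ``protocol.reps`` pulses of ``on_ms`` on / ``off_ms`` off, preceded by a
    ``baseline_ms`` dark gap that separates measurement blocks. The
    detector reads ``F_per_depth[depth] * power`` during on periods (powers
    are relative to the analysis power 1.0), plus Gaussian sample noise.
    """
    F = np.asarray(F_per_depth, dtype=float)
    if F.ndim != 1 or F.size == 0:
        raise ValidationError("F_per_depth must be a non-empty 1-D array")
    on_n, off_n, base_n = protocol.on_samples, protocol.off_samples, protocol.baseline_samples
    pulse_n = on_n + off_n
    n_depths, n_powers = F.size, len(protocol.powers)
    block_n = base_n + protocol.reps * pulse_n

    detector = np.zeros((n_depths, n_powers, block_n))
    sync = np.zeros(block_n)
    on_mask = np.zeros(block_n, dtype=bool)
    for r in range(protocol.reps):
        s = base_n + r * pulse_n
        on_mask[s:s + on_n] = True
    sync[on_mask] = 1.0
    powers = np.asarray(protocol.powers, dtype=float)
    detector[:, :, on_mask] = (F[:, None] * powers[None, :])[:, :, None]
    detector = detector.reshape(-1)
    if noise_sd > 0:
        detector = detector + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=detector.shape)
    total = n_depths * n_powers * block_n
    meta = {
        "kind": "flat_depth_series",
        "protocol": protocol,
        "galvo_range_v": protocol.galvo_range_v,
        "n_depths": n_depths,
        "F_per_depth": F,
        "seed": seed,
    }
    return RawRecording(
        t=np.arange(total) / protocol.sample_rate_hz,
        detector=detector,
        sync=np.tile(sync, n_depths * n_powers),
        galvo=np.zeros(total),
        meta=meta,
    )


def simulate_dye_recording(
    protocol: AcquisitionProtocol,
    sensitivity_per_level,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    dye_brightness: float = 1.0,
    power_per_level=None,
    n_levels: int = 41,
) -> RawRecording:
    """Calibration session in a uniform dye bath.

    Per-level fluorescence is ``sensitivity * power * dye_brightness`` with
    no drift and no tracer kinetics; used to measure the relative required
    power PR that equalizes fluorescence along the taper.
    """
    return simulate_recording(
        np.zeros(n_levels),
        protocol,
        af_slope_per_level=0.0,
        af_intercept_per_level=dye_brightness,
        injection_time_s=np.inf,
        rise_tau_s=1.0,
        noise_sd=noise_sd,
        seed=seed,
        duration_s=protocol.scan_interval_s,   # a single scan block
        n_levels=n_levels,
        sensitivity_per_level=sensitivity_per_level,
        power_per_level=power_per_level,
    )


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def recording_to_csv(recording: RawRecording, path) -> None:
    import pandas as pd

    pd.DataFrame({"t": recording.t, "detector": recording.detector,
                  "sync": recording.sync, "galvo": recording.galvo}
                 ).to_csv(path, index=False)


def recording_from_csv(path, protocol: AcquisitionProtocol, **meta) -> RawRecording:
    import pandas as pd

    df = pd.read_csv(path)
    md = {"protocol": protocol, "galvo_range_v": protocol.galvo_range_v}
    md.update(meta)
    return RawRecording(t=df["t"].to_numpy(), detector=df["detector"].to_numpy(),
                        sync=df["sync"].to_numpy(), galvo=df["galvo"].to_numpy(),
                        meta=md)


def write_section_tiff(image: SectionImage, path) -> None:
    """Write a section as single-channel TIFF plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.data.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_um": image.pixel_um, "ap_um": image.ap_um,
        "ml_origin_um": image.ml_origin_um, "dv_origin_um": image.dv_origin_um,
    }))


def read_section_tiff(path) -> SectionImage:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SectionImage(data=tifffile.imread(path).astype(float), **meta)
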