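"""Study orchestration: configuration, synthetic cohorts, end-to-end runs.

``run_study`` chains the generators and the analysis stages the way the
experiments chain them: a flat-fiber cohort (plaque field -> histology
depth profile and pulsed recording -> z-scored photometry profile ->
correlation, group t-test and genotype classification) and an in vivo
tapered-fiber cohort (day-0/day-1 galvo-scan sessions -> autofluorescence
subtraction -> late-window depth profile, extrema dynamics and paired
statistics), and writes one machine-readable JSON report embedding the
resolved configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import flatphot, genotype_clf, histomap, synthgen, tfdepth
from .stats import two_sample_t


@dataclass(frozen=True)
class StudyConfig:
    """Resolved parameters of a synthetic study run.

    Generator defaults define the emulated study conditions: a
    depth-varying plaque density peaking in the deep (subicular) part of
    the penetration for affected animals, zero density for controls, unit
    autofluorescence with slow linear drift, and a saturating tracer rise
    reaching ~95% of plateau by 90 min post-injection.
    """

    seed: int = 0
    # cohort sizes
    n_affected_flat: int = 13
    n_control_flat: int = 11
    n_affected_tf: int = 12
    n_control_tf: int = 7
    # plaque-field generator (densities in plaques/mm^3, lengths in um)
    density_base: float = 50.0
    density_peak: float = 400.0
    bump_center_um: float = 2800.0
    bump_sigma_um: float = 500.0
    diameter_range_um: tuple[float, float] = (11.0, 20.0)
    # photometry generator
    af_intercept: float = 1.0
    af_slope_range: tuple[float, float] = (-2e-6, 2e-6)   # a.u./s
    gain: float = 0.0025            # a.u. per (plaque/mm^3)
    noise_sd: float = 0.01          # detector sample noise, a.u.
    injection_time_s: float = 1800.0
    rise_tau_s: float = 1800.0
    tf_session_s: float = 15000.0
    tf_entry_depth_um: float = 1200.0
    # analysis defaults
    ball_radius_um: float = 250.0
    flat_step_um: float = 100.0
    flat_depth_range_um: tuple[float, float] = (0.0, 4000.0)
    baseline_window_um: tuple[float, float] = (0.0, 400.0)
    median_window: int = 4
    n_levels: int = 41
    profile_window_min: tuple[float, float] = (210.0, 240.0)
    extrema_window_min: tuple[float, float] = (30.0, 240.0)
    extrema_probe_min: float = 120.0    # 90 min after the 30-min injection
    track_shift_um: float = 600.0
    pca_components: int = 3
    run_flat: bool = True
    run_tf: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = dict(d)
        for key in ("diameter_range_um", "af_slope_range", "flat_depth_range_um",
                    "baseline_window_um", "profile_window_min", "extrema_window_min"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def density_profile(cfg: StudyConfig, affected: bool):
    """Depth -> plaques/mm^3 for one genotype."""
    if not affected:
        return 0.0

    def profile(dv):
        dv = np.asarray(dv, dtype=float)
        return cfg.density_base + cfg.density_peak * np.exp(
            -((dv - cfg.bump_center_um) / cfg.bump_sigma_um) ** 2)

    return profile


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def flat_protocol() -> synthgen.AcquisitionProtocol:
    """Flat-fiber protocol: 10 pulse repetitions per depth at 5000 Hz."""
    return synthgen.AcquisitionProtocol(reps=10, powers=(1.0,))


def tf_protocol(scan_interval_s: float = 300.0) -> synthgen.AcquisitionProtocol:
    """Tapered-fiber protocol: 5 sweeps per scan, 120 uW analysis power."""
    return synthgen.AcquisitionProtocol(reps=5, powers=(120.0,),
                                        scan_interval_s=scan_interval_s)


def _vertical_track(ml_um: float = 1500.0, *, annotation_noise_um: float = 10.0,
                    seed: int = 0) -> histomap.FiberTrack:
    rng = np.random.default_rng(seed)
    dv = np.array([500.0, 1250.0, 2000.0, 2750.0, 3500.0])
    ann = np.column_stack([np.zeros_like(dv), np.full_like(dv, ml_um), dv])
    ann[:, :2] += rng.normal(0.0, annotation_noise_um, size=(len(dv), 2))
    return histomap.fit_fiber_track(ann)


def simulate_flat_animal(cfg: StudyConfig, affected: bool, seed: int) -> dict:
    """One flat-fiber animal: plaque field, histology profile, photometry.

    Returns the smoothed and unsmoothed z-profiles, the ground-truth
    density profile along the implanted track, the contralateral histology
    profile (with rank-tiebreak noise), and their Spearman correlations
    with the photometry profile.
    """
    seeds = _child_seeds(seed, 4)
    field_ = synthgen.make_plaque_field(
        density_profile(cfg, affected),
        volume_um=((-300.0, 300.0), (-2000.0, 2000.0), (-300.0, 4300.0)),
        seed=seeds[0],
        diameter_range_um=cfg.diameter_range_um,
        genotype_label=genotype_clf.AFFECTED if affected else genotype_clf.CONTROL,
    )
    track = _vertical_track(seed=seeds[1])
    truth = histomap.profile_counts(field_.points, track, cfg.ball_radius_um,
                                    cfg.flat_step_um, cfg.flat_depth_range_um)
    contra = histomap.profile_counts(
        field_.points, histomap.mirror_track(track), cfg.ball_radius_um,
        cfg.flat_step_um, cfg.flat_depth_range_um)
    histology = histomap.add_tiebreak_noise(contra, seeds[2])
    truth_tb = histomap.add_tiebreak_noise(truth, seeds[2])

    F = cfg.af_intercept + cfg.gain * truth.density_per_mm3
    rec = synthgen.simulate_flat_recording(F, flat_protocol(), cfg.noise_sd, seeds[3])
    depths, values = flatphot.demodulate_depths(
        rec, flat_protocol(), depth_grid_um=truth.depth_grid_um)
    z = flatphot.depth_zscore(depths, values, cfg.baseline_window_um)
    z_smooth = flatphot.median_smooth(z, cfg.median_window)
    return {
        "field": field_,
        "track": track,
        "truth": truth,
        "histology": histology,
        "z_profile": z,
        "z_profile_smooth": z_smooth,
        "rho_truth": flatphot.correlate_profiles(z_smooth, truth_tb),
        "rho_histology": flatphot.correlate_profiles(z_smooth, histology),
    }


def simulate_tf_animal(cfg: StudyConfig, affected: bool, seed: int) -> dict:
    """One tapered-fiber animal: day-0/day-1 sessions and the full analysis.

    The ground-truth density per galvo level is profiled from the plaque
    field at the 41 axial stations (39.5-um spacing) of the taper's active
    span; day 0 carries autofluorescence only, day 1 adds the saturating
    tracer term after the injection.
    """
    seeds = _child_seeds(seed, 6)
    rng = np.random.default_rng(seeds[0])
    field_ = synthgen.make_plaque_field(
        density_profile(cfg, affected),
        volume_um=((-300.0, 300.0), (-2000.0, 2000.0), (-300.0, 4300.0)),
        seed=seeds[1],
        diameter_range_um=cfg.diameter_range_um,
        genotype_label=genotype_clf.AFFECTED if affected else genotype_clf.CONTROL,
    )
    track = _vertical_track(seed=seeds[2])
    protocol = tf_protocol()
    levels = synthgen.level_voltages(cfg.n_levels)
    station_depths = tfdepth.galvo_depth_map(
        levels, entry_depth_um=cfg.tf_entry_depth_um)
    step = station_depths[1] - station_depths[0]
    truth = histomap.profile_counts(
        field_.points, track, cfg.ball_radius_um, step,
        (station_depths[0], station_depths[-1]))
    truth_tb = histomap.add_tiebreak_noise(truth, seeds[3])

    slopes = rng.uniform(*cfg.af_slope_range, size=cfg.n_levels)
    intercepts = cfg.af_intercept * rng.uniform(0.9, 1.1, size=cfg.n_levels)
    common = dict(protocol=protocol, rise_tau_s=cfg.rise_tau_s,
                  duration_s=cfg.tf_session_s, gain=cfg.gain,
                  n_levels=cfg.n_levels, noise_sd=cfg.noise_sd)
    day0 = synthgen.simulate_recording(
        np.zeros(cfg.n_levels), af_slope_per_level=slopes,
        af_intercept_per_level=intercepts, injection_time_s=np.inf,
        seed=seeds[4], **common)
    day1 = synthgen.simulate_recording(
        truth.density_per_mm3, af_slope_per_level=slopes,
        af_intercept_per_level=intercepts,
        injection_time_s=cfg.injection_time_s, seed=seeds[5], **common)

    m0 = tfdepth.demodulate_scan(day0, protocol, n_levels=cfg.n_levels)
    m1 = tfdepth.demodulate_scan(day1, protocol, n_levels=cfg.n_levels)
    af = tfdepth.fit_autofluorescence(m0)
    fm = tfdepth.subtract_af(m1, af)
    binned = tfdepth.bin_timecourse(fm)
    profile = tfdepth.depth_profile_window(
        binned, cfg.profile_window_min, entry_depth_um=cfg.tf_entry_depth_um)
    from .stats import spearman

    rho = spearman(profile.values, truth_tb.density_per_mm3)
    extrema = tfdepth.extrema_depths(binned, cfg.extrema_window_min)
    probe = int(np.argmin(np.abs(binned.bin_mid_s / 60.0 - cfg.extrema_probe_min)))
    dmax = tfdepth.zscore_trace(binned, extrema["max_level"])
    dmin = tfdepth.zscore_trace(binned, extrema["min_level"])
    return {
        "field": field_,
        "truth": truth,
        "binned": binned,
        "profile": profile,
        "rho_truth": rho,
        "extrema": extrema,
        "dF_max_probe": float(dmax[probe]),
        "dF_min_probe": float(dmin[probe]),
    }


def run_study(config: StudyConfig, *, out_dir: str | Path | None = None,
              figures: bool = False) -> dict:
    """Run the full synthetic study and return (optionally write) a report.

    The report embeds the resolved configuration, seed, package version and
    per-stage sample counts; re-running with the same config reproduces it
    byte for byte.
    """
    if config.run_flat and (config.n_affected_flat < 1 or config.n_control_flat < 1):
        raise ValueError("flat cohort needs at least one animal per group")
    if config.run_tf and (config.n_affected_tf < 1 or config.n_control_tf < 1):
        raise ValueError("TF cohort needs at least one animal per group")
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    seeds = _child_seeds(config.seed, 2)

    if config.run_flat:
        n_a, n_c = config.n_affected_flat, config.n_control_flat
        animal_seeds = _child_seeds(seeds[0], n_a + n_c)
        animals = [simulate_flat_animal(config, i < n_a, s)
                   for i, s in enumerate(animal_seeds)]
        labels = [genotype_clf.AFFECTED] * n_a + [genotype_clf.CONTROL] * n_c
        rho_hist = [a["rho_histology"].rho for a in animals]
        rho_truth = [a["rho_truth"].rho for a in animals]
        t_res = two_sample_t(rho_hist[:n_a], rho_hist[n_a:])
        cm = genotype_clf.classify_profiles(
            [a["z_profile"] for a in animals], labels, k=config.pca_components)
        report["flat"] = {
            "n_affected": n_a,
            "n_control": n_c,
            "rho_histology_affected": rho_hist[:n_a],
            "rho_histology_control": rho_hist[n_a:],
            "rho_truth_median_affected": float(np.median(rho_truth[:n_a])),
            "rho_truth_median_abs_control": float(np.median(np.abs(rho_truth[n_a:]))),
            "t_statistic": t_res.statistic,
            "t_df": t_res.df,
            "t_p": t_res.p,
            "confusion": dataclasses.asdict(cm),
            "metrics": genotype_clf.metrics(cm),
        }
        if figures and out_dir is not None:
            _plot_flat(animals[0], Path(out_dir) / "flat_example.png")

    if config.run_tf:
        n_a, n_c = config.n_affected_tf, config.n_control_tf
        animal_seeds = _child_seeds(seeds[1], n_a + n_c)
        animals = [simulate_tf_animal(config, i < n_a, s)
                   for i, s in enumerate(animal_seeds)]
        rho = [a["rho_truth"].rho for a in animals]
        t_res = two_sample_t(rho[:n_a], rho[n_a:])
        wx_a = tfdepth.paired_extrema_test(
            [a["dF_max_probe"] for a in animals[:n_a]],
            [a["dF_min_probe"] for a in animals[:n_a]])
        wx_c = tfdepth.paired_extrema_test(
            [a["dF_max_probe"] for a in animals[n_a:]],
            [a["dF_min_probe"] for a in animals[n_a:]])
        report["tf"] = {
            "n_affected": n_a,
            "n_control": n_c,
            "rho_affected": rho[:n_a],
            "rho_control": rho[n_a:],
            "rho_mean_affected": float(np.mean(rho[:n_a])),
            "rho_mean_control": float(np.mean(rho[n_a:])),
            "rho_gap": float(np.mean(rho[:n_a]) - np.mean(rho[n_a:])),
            "t_statistic": t_res.statistic,
            "t_df": t_res.df,
            "t_p": t_res.p,
            "wilcoxon_affected_p": wx_a.p,
            "wilcoxon_control_p": wx_c.p,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2))
    return report


def _plot_flat(animal: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(5, 4))
    z = animal["z_profile_smooth"]
    ax1.plot(z.depth_grid_um, z.dF, color="tab:blue", label="photometry dF")
    ax1.set_xlabel("depth (um)")
    ax1.set_ylabel("z-scored fluorescence", color="tab:blue")
    ax2 = ax1.twinx()
    h = animal["histology"]
    ax2.plot(h.depth_grid_um, h.density_per_mm3, color="tab:orange",
             label="plaque density")
    ax2.set_ylabel("plaques / mm^3", color="tab:orange")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
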