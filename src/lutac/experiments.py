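"""Config-driven experiment drivers.

Each experiment reproduces one of the study designs at desk scale:

``angle_sweep``
    Regularized MLTR mu-maps of a transmission scan at maximum
    acceptance angles from 57 to 17 degrees.
``duration_sweep``
    MLTR mu-maps of 5/10/20-minute transmission scans with the
    duration-matched regularization weights (40000/20000/10000).
``geometry_compare``
    A 20-minute whole-body scan on the three scanner geometries
    (single bed / two 50%-overlapping beds / eight abutting beds),
    MLTR-based attenuation correction, OSEM and MLAA-TX activity
    reconstructions, against ground-truth-mu OSEM references.
``alpha_sweep``
    MLAA-TX with transmission weights alpha of 0.1, 1 and 10.
``scatter_study``
    Transmission scans with Compton scatter categories included or
    excluded, at 250 and 290 keV lower energy thresholds, with
    water-peak rescaling of the contaminated mu-maps.

Every arm writes its metrics, volumes, logs and a config echo under a
per-arm directory; arms are independent, and a failing arm is logged
without stopping the others.  Count levels are set by a single
exposure/sensitivity calibration on the reference arm (20-minute
full-acceptance scan of the default scanner) so that count-statistics
comparisons between arms remain internally consistent.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .geometry import (SinogramSpec, build_lor_table, build_scanner,
                       concat_tables, desk_variant, max_acceptance_angle)
from .grid import Grid
from .phantom import (Phantom, build_phantom, default_body_spec,
                      default_lesion_catalog, default_voi_catalog,
                      define_vois, embed_lesions)
from .projector import chord_lengths, place_endpoints
from .quantify import (MetricPair, MetricsReport, lesion_suvmax_bias, nrmse,
                       ssim, voi_stats, voxel_bias, water_peak_scale)
from .recon import ReconConfig, mlaa_tx_reconstruct, mltr_reconstruct, osem_reconstruct
from .simulate import (LuSourceModel, emission_sensitivity_for_target,
                       exposure_scale_for_target, simulate_emission,
                       simulate_transmission)

__all__ = ["ExperimentConfig", "BedProtocol", "run_experiment",
           "stitch_beds", "write_report", "read_report"]

log = logging.getLogger("lutac.experiments")

EXPERIMENTS = ("angle_sweep", "duration_sweep", "geometry_compare",
               "alpha_sweep", "scatter_study")

#: Reference reconstruction protocols per geometry.
GEOMETRY_PROTOCOLS = {
    "uexplorer": dict(n_subsets=10, osem_iterations=3, beta=10000.0),
    "one_meter": dict(n_subsets=10, osem_iterations=2, beta=20000.0),
    "conventional_24cm": dict(n_subsets=4, osem_iterations=2, beta=80000.0),
}

#: Duration-matched regularization weights (minutes -> beta).
DURATION_BETA = {5.0: 40000.0, 10.0: 20000.0, 20.0: 10000.0}


@dataclass(frozen=True)
class BedProtocol:
    """Multi-bed acquisition plan; total scan time is conserved
    across protocols (1 x 20 = 2 x 10 = 8 x 2.5 minutes)."""

    n_beds: int
    bed_axial_positions: tuple  # mm, scanner-centre offsets
    per_bed_duration_s: float
    overlap_fraction: float = 0.0

    @property
    def total_duration_s(self) -> float:
        return self.n_beds * self.per_bed_duration_s

    def coverage_mm(self, afov_mm: float) -> float:
        lo = min(self.bed_axial_positions) - afov_mm / 2.0
        hi = max(self.bed_axial_positions) + afov_mm / 2.0
        return hi - lo


def default_bed_protocol(preset: str, total_duration_s: float = 1200.0) -> BedProtocol:
    """Single bed for the 8-unit scanner, two 50%-overlapping beds for
    the one-meter scanner, eight abutting beds for the 24-cm one."""
    if preset == "uexplorer":
        return BedProtocol(1, (0.0,), total_duration_s)
    if preset == "one_meter":
        afov = 4 * 242.5
        return BedProtocol(2, (-afov / 4.0, afov / 4.0), total_duration_s / 2.0,
                           overlap_fraction=0.5)
    if preset == "conventional_24cm":
        afov = 242.5
        pos = tuple((i - 3.5) * afov for i in range(8))
        return BedProtocol(8, pos, total_duration_s / 8.0)
    raise ValueError(f"no default bed protocol for {preset!r}")


@dataclass
class ExperimentConfig:
    experiment: str = "angle_sweep"
    geometry_presets: tuple = ("uexplorer",)
    desk_crystals_per_ring: int = 80
    desk_rings_per_unit: int = 24
    angle_mash: int = 2
    axial_mash: int = 3
    durations_min: tuple = (5.0, 10.0, 20.0)
    acceptance_angles: tuple = (57.0, 51.0, 43.0, 32.0, 17.0)
    energy_thresholds_kev: tuple = (250.0, 290.0)
    scatter_mode: str = "none"
    alphas: tuple = (0.1, 1.0, 10.0)
    run_mlaa_tx: bool = True
    seeds: tuple = (1,)
    total_activity_mbq: float = 21.0
    target_transmission_counts: float = 5e6
    target_emission_counts: float = 3e6
    exposure_scale: Optional[float] = None
    sensitivity: Optional[float] = None
    outdir: str = "lutac_out"
    save_volumes: bool = False
    mltr_iterations: int = 50

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("geometry_presets", "durations_min", "acceptance_angles",
                  "energy_thresholds_kev", "alphas", "seeds"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Shared setup
# ---------------------------------------------------------------------------

@dataclass
class _Setup:
    phantom: Phantom
    vois: tuple
    lu: LuSourceModel
    exposure_scale: float
    sensitivity: float
    config: ExperimentConfig

    def desk_geometry(self, preset: str):
        return desk_variant(build_scanner(preset),
                            crystals_per_ring=self.config.desk_crystals_per_ring,
                            rings_per_unit=self.config.desk_rings_per_unit)

    def table(self, geometry, tof: bool, max_angle=None, z_shift: float = 0.0):
        spec = SinogramSpec.for_geometry(
            geometry, tof=tof, axial_mash=self.config.axial_mash,
            angle_mash=self.config.angle_mash, max_acceptance_angle=max_angle)
        tab = place_endpoints(build_lor_table(geometry, spec))
        if z_shift:
            tab = tab.shifted(z_shift)
        mask = chord_lengths(tab.front_a, tab.front_b, self.phantom.grid) > 0
        return tab.restrict(mask)


def prepare_setup(config: ExperimentConfig) -> _Setup:
    """Build the phantom and calibrate count levels on the reference
    arm (20-min full-acceptance scan of the default scanner)."""
    body = default_body_spec(total_activity_mbq=config.total_activity_mbq)
    phantom = embed_lesions(build_phantom(body), default_lesion_catalog())
    vois = define_vois(phantom, default_voi_catalog())
    phantom.vois = vois
    lu = LuSourceModel()
    setup = _Setup(phantom=phantom, vois=vois, lu=lu, exposure_scale=1.0,
                   sensitivity=1.0, config=config)
    ref = setup.table(setup.desk_geometry(config.geometry_presets[0]), tof=False)
    es = config.exposure_scale or exposure_scale_for_target(
        ref, phantom, lu, 1200.0, config.target_transmission_counts)
    reft = setup.table(setup.desk_geometry(config.geometry_presets[0]), tof=True)
    sens = config.sensitivity or emission_sensitivity_for_target(
        reft, phantom, 1200.0, config.target_emission_counts)
    setup.exposure_scale = es
    setup.sensitivity = sens
    return setup


def stitch_beds(per_bed, protocol: BedProtocol):
    """Combine per-bed (table, sinogram) pairs into one joint dataset.

    The joint reconstruction sees the concatenated LOR set, so the
    sensitivity map is automatically bed-summed.  Returns the merged
    SinogramSet (a single bed passes through unchanged).
    """
    from .simulate import SinogramSet

    per_bed = [s for s in per_bed if len(s.table)]
    if not per_bed:
        raise ValueError("no bed overlaps the phantom")
    if len(per_bed) == 1:
        return per_bed[0]
    table = concat_tables([s.table for s in per_bed])

    def cat(name):
        vals = [getattr(s, name) for s in per_bed]
        return None if any(v is None for v in vals) else np.concatenate(vals)

    first = per_bed[0]
    return SinogramSet(
        table=table, duration_s=first.duration_s,
        blank=cat("blank"), blank_duration_s=first.blank_duration_s,
        blank_expect=cat("blank_expect"),
        tran_true=cat("tran_true"), tran_scat307=cat("tran_scat307"),
        tran_contam511=cat("tran_contam511"), tran_additive=cat("tran_additive"),
        emis_true=cat("emis_true"), emis_scat=cat("emis_scat"),
        emis_additive=cat("emis_additive"),
        emission_scale=first.emission_scale,
        exposure_scale=first.exposure_scale, seed=first.seed,
        windows=first.windows)


# ---------------------------------------------------------------------------
# Metrics helpers
# ---------------------------------------------------------------------------

def _mu_report(mu, setup: _Setup, scaling: float = 1.0) -> MetricsReport:
    ph = setup.phantom
    pair = MetricPair(x=mu, x_check=ph.mu511)
    rep = MetricsReport(nrmse_percent=nrmse(pair), ssim=ssim(pair),
                        scaling_factor=scaling)
    rep.voi_records = voi_stats(voxel_bias(pair), ph, setup.vois)
    return rep


def _activity_report(act, setup: _Setup, references=None) -> MetricsReport:
    ph = setup.phantom
    pair = MetricPair(x=act, x_check=ph.activity)
    rep = MetricsReport(nrmse_percent=nrmse(pair), ssim=ssim(pair))
    rep.voi_records = voi_stats(voxel_bias(pair), ph, setup.vois)
    refs = {"ground_truth": ph.activity}
    if references:
        refs.update(references)
    rep.lesion_records = lesion_suvmax_bias(act, refs, ph)
    return rep


# ---------------------------------------------------------------------------
# Experiment arms
# ---------------------------------------------------------------------------

def _arm_angle(setup, angle, seed):
    cfg = setup.config
    geom = setup.desk_geometry("uexplorer")
    tab = setup.table(geom, tof=False, max_angle=angle)
    tr = simulate_transmission(tab, setup.phantom, setup.lu, 1200.0, seed=seed,
                               scatter_mode=cfg.scatter_mode,
                               exposure_scale=setup.exposure_scale)
    rc = ReconConfig(algorithm="mltr", n_iterations=cfg.mltr_iterations,
                     n_subsets=10, beta=10000.0)
    res = mltr_reconstruct(tr, setup.phantom.grid, rc)
    return {"mu": res.mu, "report_mu": _mu_report(res.mu, setup)}


def _arm_duration(setup, duration_min, seed):
    cfg = setup.config
    geom = setup.desk_geometry("uexplorer")
    tab = setup.table(geom, tof=False)
    beta = DURATION_BETA.get(float(duration_min), 10000.0)
    tr = simulate_transmission(tab, setup.phantom, setup.lu,
                               duration_min * 60.0, seed=seed,
                               scatter_mode=cfg.scatter_mode,
                               exposure_scale=setup.exposure_scale)
    rc = ReconConfig(algorithm="mltr", n_iterations=cfg.mltr_iterations,
                     n_subsets=10, beta=beta)
    res = mltr_reconstruct(tr, setup.phantom.grid, rc)
    return {"mu": res.mu, "report_mu": _mu_report(res.mu, setup)}


def _arm_geometry(setup, preset, seed):
    cfg = setup.config
    proto = GEOMETRY_PROTOCOLS[preset]
    geom = setup.desk_geometry(preset)
    beds = default_bed_protocol(preset)
    tr_beds, em_beds = [], []
    t_elapsed = 0.0
    for pos in beds.bed_axial_positions:
        tab_t = setup.table(geom, tof=False, z_shift=pos)
        tab_e = setup.table(geom, tof=True, z_shift=pos)
        if len(tab_t):
            tr_beds.append(simulate_transmission(
                tab_t, setup.phantom, setup.lu, beds.per_bed_duration_s,
                seed=seed + len(tr_beds), scatter_mode=cfg.scatter_mode,
                exposure_scale=setup.exposure_scale))
        if len(tab_e):
            em_beds.append(simulate_emission(
                tab_e, setup.phantom, beds.per_bed_duration_s,
                seed=seed + 1000 + len(em_beds), sensitivity=setup.sensitivity,
                start_time_s=t_elapsed))
        t_elapsed += beds.per_bed_duration_s
    tr = stitch_beds(tr_beds, beds)
    em = stitch_beds(em_beds, beds)

    mltr_cfg = ReconConfig(algorithm="mltr", n_iterations=cfg.mltr_iterations,
                           n_subsets=proto["n_subsets"], beta=proto["beta"])
    mres = mltr_reconstruct(tr, setup.phantom.grid, mltr_cfg)
    osem_cfg = ReconConfig(algorithm="osem", n_iterations=proto["osem_iterations"],
                           n_subsets=proto["n_subsets"])
    o_gt = osem_reconstruct(em, setup.phantom.mu511, setup.phantom.grid,
                            config=osem_cfg)
    o_mltr = osem_reconstruct(em, mres.mu, setup.phantom.grid, config=osem_cfg)
    out = {
        "mu": mres.mu,
        "report_mu": _mu_report(mres.mu, setup),
        "report_osem_gt_mu": _activity_report(o_gt.activity, setup),
        "report_osem_mltr_mu": _activity_report(
            o_mltr.activity, setup, {"gt_mu_osem": o_gt.activity}),
        "activity_gt_mu": o_gt.activity,
        "activity_mltr_mu": o_mltr.activity,
    }
    if cfg.run_mlaa_tx:
        mlaa_cfg = ReconConfig(algorithm="mlaa_tx",
                               n_iterations=proto["osem_iterations"],
                               n_subsets=proto["n_subsets"], beta=proto["beta"],
                               alpha=1.0)
        jres = mlaa_tx_reconstruct(em, tr, mres.mu, setup.phantom.grid,
                                   config=mlaa_cfg)
        out["report_mlaa_mu"] = _mu_report(jres.mu, setup)
        out["report_mlaa_activity"] = _activity_report(
            jres.activity, setup, {"gt_mu_osem": o_gt.activity})
        out["mu_mlaa"] = jres.mu
        out["activity_mlaa"] = jres.activity
    return out


def _arm_alpha(setup, alpha, seed):
    cfg = setup.config
    proto = GEOMETRY_PROTOCOLS["uexplorer"]
    geom = setup.desk_geometry("uexplorer")
    tab_t = setup.table(geom, tof=False)
    tab_e = setup.table(geom, tof=True)
    tr = simulate_transmission(tab_t, setup.phantom, setup.lu, 1200.0, seed=seed,
                               exposure_scale=setup.exposure_scale)
    em = simulate_emission(tab_e, setup.phantom, 1200.0, seed=seed + 1000,
                           sensitivity=setup.sensitivity)
    mres = mltr_reconstruct(tr, setup.phantom.grid,
                            ReconConfig(algorithm="mltr",
                                        n_iterations=cfg.mltr_iterations,
                                        n_subsets=proto["n_subsets"],
                                        beta=proto["beta"]))
    jres = mlaa_tx_reconstruct(
        em, tr, mres.mu, setup.phantom.grid,
        config=ReconConfig(algorithm="mlaa_tx", n_iterations=3,
                           n_subsets=proto["n_subsets"], beta=proto["beta"],
                           alpha=alpha))
    return {"mu": jres.mu, "report_mu": _mu_report(jres.mu, setup),
            "report_activity": _activity_report(jres.activity, setup)}


def _arm_scatter(setup, threshold_kev, scatter_label, seed):
    from .geometry import (BETA_WINDOW_250, BETA_WINDOW_290,
                           GAMMA_WINDOW_250, GAMMA_WINDOW_290)

    cfg = setup.config
    proto = GEOMETRY_PROTOCOLS["uexplorer"]
    geom = setup.desk_geometry("uexplorer")
    gam = GAMMA_WINDOW_250 if threshold_kev == 250 else GAMMA_WINDOW_290
    bet = BETA_WINDOW_250 if threshold_kev == 250 else BETA_WINDOW_290
    tab_t = setup.table(geom, tof=False)
    tab_e = setup.table(geom, tof=True)
    em = simulate_emission(tab_e, setup.phantom, 1200.0, seed=seed + 1000,
                           sensitivity=setup.sensitivity)
    include = scatter_label != "no_scatter"
    tr = simulate_transmission(
        tab_t, setup.phantom, setup.lu, 1200.0, seed=seed,
        scatter_mode="single_scatter" if include else "none",
        gamma_window=gam, beta_window=bet,
        exposure_scale=setup.exposure_scale,
        emission=em if scatter_label == "all_scatter" else None)
    mres = mltr_reconstruct(
        tr, setup.phantom.grid,
        ReconConfig(algorithm="mltr", n_iterations=cfg.mltr_iterations,
                    n_subsets=proto["n_subsets"], beta=proto["beta"]),
        include_scatter=include,
        include_contamination=(scatter_label == "all_scatter"))
    mu, factor = (water_peak_scale(mres.mu) if include else (mres.mu, 1.0))
    o = osem_reconstruct(em, mu, setup.phantom.grid,
                         config=ReconConfig(algorithm="osem",
                                            n_iterations=proto["osem_iterations"],
                                            n_subsets=proto["n_subsets"]))
    return {"mu": mu, "report_mu": _mu_report(mu, setup, scaling=factor),
            "report_activity": _activity_report(o.activity, setup),
            "scatter_counts": {
                "true_307": int(tr.tran_true.sum()),
                "scattered_307": int(tr.tran_scat307.sum()),
                "contamination_511": int(tr.tran_contam511.sum())}}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> dict:
    """Run all arms of an experiment; returns {arm_name: results}.

    A failing arm is recorded with its traceback and the remaining
    arms continue.
    """
    setup = prepare_setup(config)
    arms = []
    if config.experiment == "angle_sweep":
        for a in config.acceptance_angles:
            for s in config.seeds:
                arms.append((f"angle{int(round(a))}_seed{s}",
                             lambda a=a, s=s: _arm_angle(setup, a, s)))
    elif config.experiment == "duration_sweep":
        for d in config.durations_min:
            for s in config.seeds:
                arms.append((f"dur{d:g}min_seed{s}",
                             lambda d=d, s=s: _arm_duration(setup, d, s)))
    elif config.experiment == "geometry_compare":
        for g in config.geometry_presets:
            for s in config.seeds:
                arms.append((f"{g}_seed{s}",
                             lambda g=g, s=s: _arm_geometry(setup, g, s)))
    elif config.experiment == "alpha_sweep":
        for a in config.alphas:
            for s in config.seeds:
                arms.append((f"alpha{a:g}_seed{s}",
                             lambda a=a, s=s: _arm_alpha(setup, a, s)))
    elif config.experiment == "scatter_study":
        for thr in config.energy_thresholds_kev:
            for lab in ("no_scatter", "scatter_307", "all_scatter"):
                for s in config.seeds:
                    arms.append((f"thr{int(thr)}_{lab}_seed{s}",
                                 lambda t=thr, l=lab, s=s: _arm_scatter(setup, t, l, s)))

    results = {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    for name, fn in arms:
        try:
            log.info("running arm %s", name)
            res = fn()
            results[name] = res
            write_report(res, outdir / name, save_volumes=config.save_volumes,
                         grid=setup.phantom.grid)
        except Exception as exc:  # keep other arms alive
            log.error("arm %s failed: %s", name, exc)
            results[name] = {"error": str(exc),
                             "traceback": traceback.format_exc()}
            (outdir / name).mkdir(parents=True, exist_ok=True)
            with open(outdir / name / "error.log", "w") as fh:
                fh.write(results[name]["traceback"])
    return results


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _report_dict(rep: MetricsReport) -> dict:
    return {"nrmse_percent": rep.nrmse_percent, "ssim": rep.ssim,
            "scaling_factor": rep.scaling_factor,
            "max_abs_mean_voi_bias_percent": rep.max_abs_mean_voi_bias,
            "within_10_percent": rep.within_10_percent}


def write_report(arm_results: dict, armdir, save_volumes: bool = False,
                 grid: Optional[Grid] = None) -> None:
    """Write machine-readable metrics and summary tables for one arm."""
    armdir = Path(armdir)
    armdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, val in arm_results.items():
        if isinstance(val, MetricsReport):
            summary[key] = _report_dict(val)
            if val.voi_records:
                pd.DataFrame(val.voi_records).to_csv(
                    armdir / f"{key}_voi.csv", index=False)
            if val.lesion_records:
                pd.DataFrame(val.lesion_records).to_csv(
                    armdir / f"{key}_lesions.csv", index=False)
        elif isinstance(val, dict):
            summary[key] = val
        elif save_volumes and isinstance(val, np.ndarray) and grid is not None:
            import nibabel as nib
            aff = np.eye(4)
            aff[:3, :3] *= grid.voxel_size
            aff[:3, 3] = grid.origin + grid.voxel_size / 2.0
            nib.save(nib.Nifti1Image(val.astype(np.float32), aff),
                     armdir / f"{key}.nii.gz")
    with open(armdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


def read_report(armdir) -> dict:
    """Round-trip reader for :func:`write_report` output."""
    armdir = Path(armdir)
    with open(armdir / "summary.json") as fh:
        out = {"summary": json.load(fh)}
    for csv in armdir.glob("*.csv"):
        out[csv.stem] = pd.read_csv(csv)
    return out
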