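"""End-to-end orchestration: simulate → detect → track → mask → fit → report.

A single YAML/JSON config drives every stage; all defaults encode the study
acquisition (20 frames/s, 1000 frames, ~0.5 active molecules/µm², ligand
~100/µm²).  Each stage reads and writes only the documented CSV/TIFF/JSON
interfaces, so stages are independently re-enterable: a measurement run can
start from a movie, a localization table or a trajectory table.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as spio
from .detection import detect_movie
from .kinetics import estimate_kon, fit_dwell_sample
from .regions import (
    assign_region,
    classify_corral_mobility,
    mask_from_layout,
    segment_corrals,
)
from .synthetic import (
    PatternLayout,
    SimulationConfig,
    assign_puncta,
    make_pattern_layout,
    render_ligand_channel,
    render_movie,
    simulate_binding_events,
)
from .tracking import compute_dwell_times, link_trajectories

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "layout": {
        "n_rows": 4, "n_cols": 4, "radius_um": 2.0, "spacing_um": 5.0,
        "pixel_size_um": 0.1, "alternating": True,
    },
    "acquisition": {"frame_interval_s": 0.05, "n_frames": 1000},
    "render": False,
    "simulation": {
        "k_on": {"mobile": 2.0, "immobile": 2.0},       # events/µm²/s
        "dwell": {
            "mobile": {"f1": 0.55, "tau1_s": 0.08, "tau2_s": 0.508},
            "immobile": {"f1": 0.55, "tau1_s": 0.08, "tau2_s": 0.451},
        },
        "bleach_rate_per_s": 0.2,
        "diffusion_um2_s": {"mobile": 0.01, "immobile": 0.0},
        "confinement_radius_um": 0.15,
        "psf_sigma_px": 1.0,
        "photons_per_frame": 500,
        "background": 20.0,
        "read_noise": 3.0,
        "ligand_density_um2": {"mobile": 100.0, "immobile": 100.0},
        "clustered_fraction": 0.9,
        "localization_noise_um": 0.012,
    },
    "detection": {"snr_threshold": 5.0},
    "tracking": {"max_disp_px": None, "gap_max": 0},
    "kinetics": {"truncation": 0.005, "normalize_kon_by_ligand": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_layout(config: dict) -> PatternLayout:
    lc = config["layout"]
    return make_pattern_layout(
        lc["n_rows"], lc["n_cols"], lc["radius_um"], lc["spacing_um"],
        pixel_size=lc["pixel_size_um"], alternating=lc["alternating"],
    )


def build_sim_config(config: dict) -> SimulationConfig:
    acq = config["acquisition"]
    sim = config["simulation"]
    dwell = sim["dwell"]
    return SimulationConfig(
        dt=acq["frame_interval_s"],
        n_frames=acq["n_frames"],
        k_on=sim["k_on"],
        dwell_f1={r: dwell[r]["f1"] for r in dwell},
        dwell_tau1={r: dwell[r]["tau1_s"] for r in dwell},
        dwell_tau2={r: dwell[r]["tau2_s"] for r in dwell},
        k_bleach=sim["bleach_rate_per_s"],
        diffusion=sim["diffusion_um2_s"],
        confinement_radius=sim["confinement_radius_um"],
        psf_sigma=sim["psf_sigma_px"],
        photons_per_frame=sim["photons_per_frame"],
        background=sim["background"],
        read_noise=sim["read_noise"],
        ligand_density=sim["ligand_density_um2"],
        rng_seed=config["seed"],
    )


def _default_max_disp(config: dict) -> float:
    md = config["tracking"]["max_disp_px"]
    if md is not None:
        return float(md)
    return 2.0 * float(config["simulation"]["psf_sigma_px"])


def _region_kinetics(tracks, mask, config, cell_id=0):
    """Per-region dwell fit and on-rate from assigned trajectories."""
    dt = config["acquisition"]["frame_interval_s"]
    duration = dt * config["acquisition"]["n_frames"]
    trunc = config["kinetics"]["truncation"]
    kon = estimate_kon(
        tracks, mask, duration,
        normalize_by_ligand=config["kinetics"]["normalize_kon_by_ligand"],
    )
    out = {}
    for region in ("mobile", "immobile"):
        rtracks = [t for t in tracks if t.region_class == region]
        entry = {
            "n_tracks": len(rtracks),
            "k_on_per_um2_s": kon.get(region),
            "tau2_s": None, "tau1_s": None, "fit": None,
        }
        if rtracks:
            sample = compute_dwell_times(
                rtracks, dt, cell_id=cell_id, region_class=region
            )
            entry["n_uncensored"] = int(len(sample.uncensored()))
            if entry["n_uncensored"] >= 50:
                fit = fit_dwell_sample(sample, truncation=trunc)
                if fit.success:
                    entry["tau2_s"] = fit.tau2
                    entry["tau1_s"] = fit.tau1
                    entry["fit"] = fit.to_dict()
        out[region] = entry
    return out


def run_simulated_experiment(config, out_dir=None) -> dict:
    """Execute the full chain on generated data and report truth vs estimates.

    ``config`` is a path to a YAML/JSON file or a (possibly partial) dict;
    missing keys take the study defaults.  With ``render`` the movie is
    rendered and detected; otherwise ground-truth localizations (plus
    localization noise) feed tracking directly, which exercises the same
    kinetics chain without the imaging forward model.
    """
    if not isinstance(config, dict):
        config = spio.load_config(config)
    config = _merge(DEFAULT_CONFIG, config)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    layout = build_layout(config)
    layout = assign_puncta(layout, rng)
    sim_cfg = build_sim_config(config)
    events = simulate_binding_events(layout, sim_cfg, rng)
    ligand = render_ligand_channel(
        layout, config["simulation"]["ligand_density_um2"],
        config["simulation"]["clustered_fraction"], rng,
    )
    px = layout.pixel_size
    if config["render"]:
        movie = render_movie(events, layout, sim_cfg, rng)
        locs = detect_movie(
            movie, sim_cfg.psf_sigma, config["detection"]["snr_threshold"]
        )
        mask = segment_corrals(ligand, config["layout"]["radius_um"], px)
        classify_corral_mobility(ligand, mask)
    else:
        sd = config["simulation"]["localization_noise_um"] / px
        rows = []
        for ev in events:
            for k in range(ev.n_visible_frames):
                rows.append((ev.first_frame + k,
                             ev.positions[k, 0] / px, ev.positions[k, 1] / px))
        locs = pd.DataFrame(rows, columns=["frame", "x", "y"])
        if sd > 0 and len(locs):
            locs[["x", "y"]] += rng.normal(0, sd, (len(locs), 2))
        mask = mask_from_layout(layout, ligand)
    tracks = link_trajectories(
        locs, _default_max_disp(config), config["tracking"]["gap_max"],
        n_frames=sim_cfg.n_frames,
    )
    assign_region(tracks, mask)
    estimates = _region_kinetics(tracks, mask, config)
    truth = {
        r: {
            "tau2_s": sim_cfg.dwell_tau2[r],
            "tau1_s": sim_cfg.dwell_tau1[r],
            "f1": sim_cfg.dwell_f1[r],
            "k_on_per_um2_s": sim_cfg.k_on[r],
        }
        for r in ("mobile", "immobile")
    }
    report = {
        "software": {"name": "sptcorral", "version": __version__},
        "seed": seed,
        "config": config,
        "config_hash": spio.config_hash(config),
        "n_events": len(events),
        "n_localizations": int(len(locs)),
        "n_tracks": len(tracks),
        "ground_truth": truth,
        "estimates": estimates,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spio.write_table(out / "localizations.csv", locs)
        spio.write_tracks(out / "tracks.csv", tracks)
        spio.write_image(out / "ligand.tif", ligand)
        spio.write_label_mask(out / "mask.tif", mask.labels)
        spio.write_report(out / "report.json", report)
        if config["render"]:
            spio.write_movie(out / "movie.tif", movie, seed=seed)
    return report


def run_measurement(
    config,
    movie_path=None,
    ligand_path=None,
    localizations_csv=None,
    trajectories_csv=None,
    mask_path=None,
    region_class_map=None,
    out_dir=None,
) -> dict:
    """Run the measurement chain on externally supplied data.

    Entry points, in order of precedence: a trajectory CSV (kinetics-only
    run), a localization CSV (tracking onward) or a movie TIFF (full run).
    A region mask comes either from ``mask_path`` (16-bit label TIFF, with
    ``region_class_map`` {corral_id: class}) or is segmented from the
    ligand image.  The frame interval and pixel size must be present in the
    config; runs are rejected before any computation otherwise.
    """
    if not isinstance(config, dict):
        config = spio.load_config(config)
    config = _merge(DEFAULT_CONFIG, config)
    acq = config.get("acquisition", {})
    if not acq.get("frame_interval_s") or not acq.get("pixel_size_um") and not \
            config["layout"].get("pixel_size_um"):
        raise ValueError("config must state frame_interval_s and pixel_size_um")
    dt = float(acq["frame_interval_s"])
    px = float(acq.get("pixel_size_um") or config["layout"]["pixel_size_um"])
    n_frames = int(acq["n_frames"])

    from .regions import RegionMask
    from .tracking import frame_to_tracks

    ligand = spio.read_image(ligand_path) if ligand_path else None
    if mask_path is not None:
        labels = spio.read_image(mask_path).astype(np.int32)
        mask = RegionMask(labels=labels, pixel_size=px)
        for cid in mask.corral_ids:
            sel = labels == cid
            mask.area_um2[cid] = float(sel.sum()) * px**2
            if ligand is not None:
                mask.mean_ligand[cid] = float(ligand[sel].mean())
        if region_class_map:
            mask.region_class = {int(k): v for k, v in region_class_map.items()}
        elif ligand is not None:
            classify_corral_mobility(ligand, mask)
        else:
            raise ValueError("label mask needs region_class_map or ligand image")
    elif ligand is not None:
        mask = segment_corrals(ligand, config["layout"]["radius_um"], px)
        classify_corral_mobility(ligand, mask)
    else:
        raise ValueError("a mask TIFF or a ligand image is required")

    if trajectories_csv is not None:
        tracks = frame_to_tracks(pd.read_csv(trajectories_csv), n_frames=n_frames)
    else:
        if localizations_csv is not None:
            locs = spio.read_localizations(localizations_csv)
        elif movie_path is not None:
            movie = spio.read_movie(movie_path, dt=dt, pixel_size=px)
            locs = detect_movie(
                movie, config["simulation"]["psf_sigma_px"],
                config["detection"]["snr_threshold"],
            )
        else:
            raise ValueError("need a movie, localization CSV or trajectory CSV")
        tracks = link_trajectories(
            locs, _default_max_disp(config), config["tracking"]["gap_max"],
            n_frames=n_frames,
        )
    assign_region(tracks, mask)
    estimates = _region_kinetics(tracks, mask, config)
    report = {
        "software": {"name": "sptcorral", "version": __version__},
        "seed": int(config["seed"]),
        "config": config,
        "config_hash": spio.config_hash(config),
        "inputs": {
            "movie": str(movie_path) if movie_path else None,
            "ligand": str(ligand_path) if ligand_path else None,
            "localizations": str(localizations_csv) if localizations_csv else None,
            "trajectories": str(trajectories_csv) if trajectories_csv else None,
            "mask": str(mask_path) if mask_path else None,
        },
        "n_tracks": len(tracks),
        "estimates": estimates,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spio.write_tracks(out / "tracks.csv", tracks)
        spio.write_report(out / "report.json", report)
    return report
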