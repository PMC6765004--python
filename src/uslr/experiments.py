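"""Named end-to-end experiments with config validation and provenance.

Each experiment reproduces one of the toolkit's headline analyses:

``transmit-profiles``
    Lateral transmit profiles at the focal depth for the rectangular
    single focus, the Hamming-apodized focus and the interlaced
    side-lobe-reduced scheme, plus a lobe report for each.
``optimize``
    The (c, delta_x) grid search at the configured depth: objective
    surface and best parameters.
``grating-lobes``
    Odd-element transmit vs full-aperture one-way profiles over a wide
    angular span and the two-way grating-lobe suppression report.
``wire-image``
    B-mode sector images of a single wire under the single-focus and
    interlaced transmissions, with lateral PSF metrics at the focal depth.
``resolution-image``
    B-mode image of the 11-wire resolution target (single focus and
    interlaced).
``cyst-image``
    Anechoic cyst in speckle: B-mode images and contrast/CNR for both
    transmissions.

All outputs are written to the configured directory together with a
provenance record (config hash, seed, package version).  Deterministic
stages are bit-reproducible for a fixed config.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from ._version import __version__
from .array_model import Medium, emitted_pulse, make_array
from .field_sim import lateral_profile_of_scheme
from .imaging import (
    SectorGeometry,
    das_beamform,
    grating_lobe_analysis,
    image_lateral_profile,
    save_image,
    sweep_sector,
)
from .metrics import Circle, cnr, contrast, envelope_snr, find_sidelobes, lobe_width
from .optimize import optimize_uslr
from .phantoms import cyst_phantom, resolution_phantom, single_wire
from .waveform_design import (
    USLRParams,
    focus_delays,
    hamming_scheme,
    uslr_scheme,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_experiment", "EXPERIMENTS"]

DEFAULT_CONFIG: dict[str, Any] = {
    "experiment": "transmit-profiles",
    "seed": 0,
    "output_dir": "uslr-output",
    "array": {
        "n_elements": 128,
        "pitch_mm": 0.22,
        "center_frequency_mhz": 3.0,
        "element_width_mm": None,       # default 0.9 * pitch
    },
    "medium": {
        "sound_speed_m_s": 1540.0,
        "attenuation_db_cm_mhz": 0.0,
    },
    "pulse": {
        "excitation_cycles": 1.0,
        "impulse_response_cycles": 4.0,
        "sampling_rate_mhz": 400.0,
    },
    "depth_mm": 60.0,
    "uslr": {"c": 0.37, "delta_x_mm": 3.0},
    "profile": {"half_span_mm": 5.0, "step_mm": 0.025},
    "optimize": {
        "c_min": 0.0, "c_max": 0.6, "c_step": 0.01,
        "dx_min_mm": 2.0, "dx_max_mm": 4.0, "dx_step_mm": 0.05,
    },
    "imaging": {
        "n_angles": 128,
        "field_of_view_deg": 18.0,
        "depth_range_mm": [50.0, 70.0],
        "dynamic_range_db": 50.0,
    },
    "cyst": {
        "depth_mm": 70.0,
        "radius_mm": 4.0,
        "density_per_mm2": 15.0,
        "c": 0.37,
        "delta_x_mm": 3.05,
        "n_angles": 64,
        "roi_radius_fraction": 0.7,
        "background_offset_mm": -6.5,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and/or an override mapping.

    Unknown keys raise a validation error naming the offending key.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _build(cfg: dict):
    a = cfg["array"]
    array = make_array(a["n_elements"], a["pitch_mm"],
                       a["center_frequency_mhz"], a["element_width_mm"])
    m = cfg["medium"]
    medium = Medium(m["sound_speed_m_s"], m["attenuation_db_cm_mhz"])
    p = cfg["pulse"]
    pulse = emitted_pulse(a["center_frequency_mhz"], p["sampling_rate_mhz"],
                          p["excitation_cycles"],
                          p["impulse_response_cycles"])
    return array, medium, pulse


def _lobe_metrics(profile) -> dict:
    rep = find_sidelobes(profile)
    out = {
        "width_3db_mm": lobe_width(profile, -3.0),
        "first_order_positions_mm": list(rep.first_order_positions),
        "first_order_levels_db": list(rep.first_order_levels),
        "mean_first_order_level_db": rep.mean_first_order_level,
    }
    return out


def _exp_transmit_profiles(cfg, outdir, array, medium, pulse) -> dict:
    depth = cfg["depth_mm"]
    prof_cfg = cfg["profile"]
    kw = dict(half_span=prof_cfg["half_span_mm"], dx=prof_cfg["step_mm"])
    params = USLRParams(cfg["uslr"]["c"], cfg["uslr"]["delta_x_mm"])
    schemes = {
        "rect": focus_delays(array, (0.0, depth), medium),
        "hamming": hamming_scheme(array, (0.0, depth), medium),
        "uslr": uslr_scheme(array, depth, params, medium),
    }
    metrics = {}
    for name, scheme in schemes.items():
        prof = lateral_profile_of_scheme(array, scheme, pulse, depth, medium,
                                         **kw)
        prof.to_csv(outdir / f"profile_{name}.csv")
        scheme.to_csv(outdir / f"scheme_{name}.csv")
        try:
            metrics[name] = _lobe_metrics(prof)
        except ValueError:
            metrics[name] = {"width_3db_mm": lobe_width(prof, -3.0)}
    return metrics


def _exp_optimize(cfg, outdir, array, medium, pulse) -> dict:
    o = cfg["optimize"]
    c_grid = np.round(np.arange(o["c_min"], o["c_max"] + 1e-9, o["c_step"]), 10)
    dx_grid = np.round(
        np.arange(o["dx_min_mm"], o["dx_max_mm"] + 1e-9, o["dx_step_mm"]), 10)
    res = optimize_uslr(array, cfg["depth_mm"], c_grid, dx_grid, medium, pulse)
    res.to_csv(outdir / "objective_surface.csv")
    return {
        "best_c": res.best_c,
        "best_delta_x_mm": res.best_dx,
        "best_level_db": res.best_level,
        "reference_positions_mm": list(res.reference_positions),
    }


def _exp_grating(cfg, outdir, array, medium, pulse) -> dict:
    rep = grating_lobe_analysis(array, cfg["depth_mm"], medium, pulse)
    return {
        "tx_grating_level_db": rep.tx_level,
        "tx_grating_position_mm": rep.tx_position,
        "rx_level_at_tx_grating_db": rep.rx_level,
        "two_way_grating_level_db": rep.two_way_level,
        "tx_suppression_db": rep.tx_suppression,
        "two_way_suppression_db": rep.two_way_suppression,
    }


def _wire_like_experiment(cfg, outdir, array, medium, pulse, phantom) -> dict:
    depth = cfg["depth_mm"]
    im = cfg["imaging"]
    geom = SectorGeometry(n_angles=im["n_angles"],
                          field_of_view=im["field_of_view_deg"],
                          focal_depth=depth,
                          depth_range=tuple(im["depth_range_mm"]))
    params = USLRParams(cfg["uslr"]["c"], cfg["uslr"]["delta_x_mm"])
    out = {}
    peaks = {}
    for kind, p in [("single", None), ("uslr", params)]:
        cds = sweep_sector(array, phantom, geom, medium, pulse, kind=kind,
                           params=p)
        img = das_beamform(cds, array, geom, medium, pulse,
                           dynamic_range=im["dynamic_range_db"])
        save_image(img, outdir / f"image_{kind}.h5")
        _render(img, outdir / f"image_{kind}.png")
        prof = image_lateral_profile(img, depth)
        prof.to_csv(outdir / f"image_profile_{kind}.csv")
        peaks[kind] = float(img.envelope.max())
        try:
            out[kind] = _lobe_metrics(prof)
        except ValueError:
            out[kind] = {}
        out[kind]["width_6db_mm"] = lobe_width(prof, -6.0)
    out["peak_ratio_db"] = 20.0 * float(
        np.log10(peaks["single"] / peaks["uslr"]))
    return out


def _exp_wire(cfg, outdir, array, medium, pulse) -> dict:
    return _wire_like_experiment(cfg, outdir, array, medium, pulse,
                                 single_wire(cfg["depth_mm"]))


def _exp_resolution(cfg, outdir, array, medium, pulse) -> dict:
    phantom = resolution_phantom(cfg["depth_mm"])
    phantom.to_csv(outdir / "phantom.csv")
    return _wire_like_experiment(cfg, outdir, array, medium, pulse, phantom)


def _exp_cyst(cfg, outdir, array, medium, pulse) -> dict:
    cy = cfg["cyst"]
    depth = cy["depth_mm"]
    phantom = cyst_phantom(depth, cy["radius_mm"],
                           density=cy["density_per_mm2"], seed=cfg["seed"])
    phantom.to_csv(outdir / "phantom.csv")
    geom = SectorGeometry(n_angles=cy["n_angles"],
                          field_of_view=cfg["imaging"]["field_of_view_deg"],
                          focal_depth=depth,
                          depth_range=(depth - 8.0, depth + 8.0))
    params = USLRParams(cy["c"], cy["delta_x_mm"])
    roi_in = Circle(0.0, depth, cy["roi_radius_fraction"] * cy["radius_mm"])
    roi_out = Circle(cy["background_offset_mm"], depth, roi_in.radius)
    out = {"n_scatterers": phantom.n_scatterers}
    for kind, p in [("single", None), ("uslr", params)]:
        cds = sweep_sector(array, phantom, geom, medium, pulse, kind=kind,
                           params=p)
        img = das_beamform(cds, array, geom, medium, pulse,
                           dynamic_range=cfg["imaging"]["dynamic_range_db"])
        save_image(img, outdir / f"image_{kind}.h5")
        _render(img, outdir / f"image_{kind}.png")
        out[kind] = {
            "contrast_db": contrast(img, roi_in, roi_out),
            "cnr_db": cnr(img, roi_in, roi_out),
            "background_envelope_snr": envelope_snr(img, roi_out),
        }
    return out


def _render(img, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:       # rendering is best-effort, data lives in HDF5
        return
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(img.pixels, cmap="gray", aspect="equal",
                   extent=[img.x[0], img.x[-1], img.z[-1], img.z[0]],
                   vmin=-img.dynamic_range, vmax=0)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


EXPERIMENTS: dict[str, Callable] = {
    "transmit-profiles": _exp_transmit_profiles,
    "optimize": _exp_optimize,
    "grating-lobes": _exp_grating,
    "wire-image": _exp_wire,
    "resolution-image": _exp_resolution,
    "cyst-image": _exp_cyst,
}


def run_experiment(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Run the configured experiment; returns its metric report."""
    name = cfg.get("experiment")
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; valid: {sorted(EXPERIMENTS)}")
    outdir = Path(output_dir if output_dir is not None else cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    array, medium, pulse = _build(cfg)
    report = EXPERIMENTS[name](cfg, outdir, array, medium, pulse)
    bundle = {
        "experiment": name,
        "provenance": {
            "config_hash": _config_hash(cfg),
            "seed": cfg["seed"],
            "version": __version__,
        },
        "metrics": report,
    }
    with open(outdir / "report.json", "w") as f:
        json.dump(bundle, f, indent=2)
    with open(outdir / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f)
    return bundle
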