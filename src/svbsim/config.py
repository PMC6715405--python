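"""Run configuration: YAML schema, validation, and named presets.

A run config is a plain mapping with the sections::

    model: HB | HBP | HBPM | HBPMA        # or an inline "network:" block
    params: {k1: ..., D_H: ..., ...}      # rate and diffusion constants
    geometry: {kind: disc|cylinder, radius: R, height: Z,
               shell_fraction: 0.04}
    run: {seed: int, max_events: N and/or max_time: T,
          snapshot_every_time: ..., snapshot_every_events: ...}
    analysis: {threshold: number | null, threshold_fraction: 0.5,
               connectivity: FACE, species: H}

Presets cover the model family at desk scale. The original study's
supplementary parameter tables are not reproduced here, so preset rate
constants are this package's own defaults, calibrated to the qualitative
regime each simulation explores (documented per preset); geometry sizes
are desk-scale and freely overridable.
"""

from __future__ import annotations

import copy

import yaml

from .geometry import build_cylinder, build_disc
from .network import ConfigError, ReactionNetwork, make_model
from . import engine as _engine

__all__ = [
    "BASE_HB_PARAMS",
    "PRESETS",
    "load_config",
    "dump_config",
    "validate_config",
    "build_system",
    "preset_config",
    "list_presets",
]

# ---------------------------------------------------------------------------
# Default kinetics
# ---------------------------------------------------------------------------

#: Copy-number scale of the desk-scale presets: the dimensionless
#: Schnakenberg state (a=0.2, b=1.3) is scaled so the homogeneous
#: activator level is ~60 molecules per voxel; spot peaks then reach a
#: few hundred, comfortably above demographic noise but cheap to simulate.
COUNT_SCALE = 40.0

#: Core activator-substrate kinetics shared by every preset.
#: Schnakenberg a=0.2, b=1.3 scaled by COUNT_SCALE: with D_B/D_H large
#: these sit inside the Turing (spot-forming) regime, and the critical
#: diffusion ratio lies between 10 (no band) and 100 (band), matching
#: the regimes the diffusion sweep contrasts.
BASE_HB_PARAMS = {
    "k1": 1.0 / COUNT_SCALE**2,   # autocatalysis 2H+B -> 3H
    "k2": 1.3 * COUNT_SCALE,      # substrate production
    "k3": 0.02,                   # substrate decay
    "k4": 0.2 * COUNT_SCALE,      # background activator production
    "k5": 1.0,                    # activator decay
    "D_H": 0.05,
    "D_B": 50.0,                  # ratio 1000
}

#: Carrier (P) kinetics: immobile, produced by H, so high-H columns
#: recruit carrier and canalize longitudinal movement.
BASE_P_PARAMS = {"k6": 0.02, "k7": 0.1, "alpha": 0.1, "D_P": 0.0}

#: Peripheral inhibitor (M) kinetics: produced in the outer shell,
#: diffusing inward with decay length sqrt(D_M/k10) = 5 voxels and
#: annihilating the activator potently (k11 >> k5), so it carves an
#: SVB-free zone B inside the periphery of a wide stem and floods a
#: stem whose radius is comparable to the decay length.
BASE_M_PARAMS = {"k9": 100.0, "k10": 0.2, "k11": 0.5, "D_M": 5.0}

#: Apical hormone (A) kinetics for the source-sink variant: produced at
#: the apex layer, carried basipetally by P, feeding back on H.
BASE_A_PARAMS = {"k13": 20.0, "k14": 0.05, "D_A": 0.05,
                 "k_AH": 0.05, "k_HA": 0.01}

#: Base stem radius (voxels) for the stem-size experiments; the
#: narrow/medium stems are 75%/50%/37% of this, per the study design.
BASE_RADIUS = 20


def _cfg(model, params, geometry, run, analysis=None, note=""):
    return {
        "model": model,
        "params": dict(params),
        "geometry": dict(geometry),
        "run": dict(run),
        "analysis": dict(analysis or {"threshold": None,
                                      "threshold_fraction": 0.5,
                                      "connectivity": "FACE",
                                      "species": "H"}),
        "note": note,
    }


def _hb(**over):
    p = dict(BASE_HB_PARAMS)
    p.update(over)
    return p


def _hbpm(**over):
    p = {**BASE_HB_PARAMS, **BASE_P_PARAMS, **BASE_M_PARAMS,
         "D_B": BASE_HB_PARAMS["D_H"] * 400}  # ratio 400: patterned regime
    p.update(over)
    return p


def _hbpma(**over):
    p = {**_hbpm(), **BASE_A_PARAMS}
    p.update(over)
    return p


def _stem(ratio, note):
    return _cfg("HBPM", _hbpm(),
                {"kind": "disc", "radius": max(int(round(BASE_RADIUS * ratio)), 2),
                 "shell_fraction": 0.04},
                {"seed": 1, "max_time": 40.0}, note=note)


def _build_presets() -> dict:
    demo_run = {"seed": 1, "max_time": 40.0}
    presets = {
        "hb-2d-demo": _cfg(
            "HB", _hb(), {"kind": "disc", "radius": 30},
            dict(demo_run),
            note="Core activator-substrate model on a 2D stem "
                 "cross-section; forms a regular array of high-H spots."),
        "hb-3d": _cfg(
            "HB", _hb(), {"kind": "cylinder", "radius": 10, "height": 16},
            dict(demo_run),
            note="Core model in a 3D stem: high-H regions are "
                 "disconnected blobs, with no longitudinal orientation."),
        "hbp-3d": _cfg(
            "HBP", {**_hb(), **BASE_P_PARAMS},
            {"kind": "cylinder", "radius": 10, "height": 16},
            dict(demo_run),
            note="Carrier-facilitated longitudinal transport of H "
                 "canalizes blobs into longitudinally oriented strands."),
        "hbpm-wide": _stem(1.00, "Wide stem: central SVB spots, "
                                 "peripheral suppression by M."),
        "hbpm-medium": _stem(0.75, "Medium stem (75% radius): fewer, "
                                   "scattered SVBs."),
        "hbpm-half": _stem(0.50, "Half-radius stem."),
        "hbpm-small": _stem(0.37, "Narrow stem (37% radius): M floods the "
                                  "interior and suppresses all SVBs."),
        "hbpm-highM-highD": _cfg(
            "HBPM", _hbpm(k9=200.0, D_M=10.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.04},
            {"seed": 1, "max_time": 60.0},
            note="High M production, fast M diffusion: wide SVB-free "
                 "zone B."),
        "hbpm-highM-lowD": _cfg(
            "HBPM", _hbpm(k9=200.0, D_M=2.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.04},
            {"seed": 1, "max_time": 60.0},
            note="High M production, slow M diffusion."),
        "hbpm-lowM-highD": _cfg(
            "HBPM", _hbpm(k9=50.0, D_M=10.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.04},
            {"seed": 1, "max_time": 60.0},
            note="Low M production, fast M diffusion: narrow zone B."),
        "hbpm-lowM-lowD": _cfg(
            "HBPM", _hbpm(k9=50.0, D_M=2.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.04},
            {"seed": 1, "max_time": 60.0},
            note="Low M production, slow M diffusion."),
        # Stele-pattern regimes (qualitative starting points; the stele
        # simulations explored parameter space rather than one canonical
        # setting, so these document the direction of each variation).
        "eustele": _cfg(
            "HBPM", _hbpm(k9=150.0, D_M=10.0, k12=0.02),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.08},
            {"seed": 1, "max_time": 60.0},
            note="Ring of discrete peripheral bundles; M+B annihilation "
                 "(X12) clears the center."),
        "eustele-svb": _cfg(
            "HBPM", _hbpm(k9=60.0, D_M=3.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.08},
            {"seed": 1, "max_time": 60.0},
            note="Eustele ring plus internal SVB spots (X12 off)."),
        "siphonostele-svb": _cfg(
            "HBPM", _hbpm(D_H=0.1, D_B=0.1 * 400, k9=60.0, D_M=3.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.08},
            {"seed": 1, "max_time": 60.0},
            note="Faster H diffusion merges the ring into a continuous "
                 "vascular cylinder with internal SVBs."),
        "atactostele": _cfg(
            "HBPM", _hbpm(k2=1.6 * COUNT_SCALE, k9=50.0, D_M=2.0),
            {"kind": "disc", "radius": BASE_RADIUS, "shell_fraction": 0.08},
            {"seed": 1, "max_time": 60.0},
            note="Scattered bundles throughout the section plus a "
                 "peripheral ring, monocot-like."),
        "haplostele": _cfg(
            "HBPM", _hbpm(k9=30.0, D_M=5.0),
            {"kind": "disc", "radius": 8, "shell_fraction": 0.08},
            {"seed": 1, "max_time": 60.0},
            note="Narrow axis with a single central strand."),
        "hbpma": _cfg(
            "HBPMA", _hbpma(),
            {"kind": "cylinder", "radius": 8, "height": 16},
            {"seed": 1, "max_time": 30.0},
            note="Source-sink variant: A produced at the apex, carried "
                 "basipetally by P; H and A in a feedback loop."),
        "hbpma-no-dh": _cfg(
            "HBPMA", _hbpma(D_H=0.0),
            {"kind": "cylinder", "radius": 8, "height": 16},
            {"seed": 1, "max_time": 30.0},
            note="Source-sink variant with no H diffusion: all H "
                 "patterning is driven through A transport."),
    }
    return presets


PRESETS = _build_presets()


def list_presets() -> list:
    return sorted(PRESETS)


def preset_config(name: str) -> dict:
    try:
        return copy.deepcopy(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(list_presets())}") from None


# ---------------------------------------------------------------------------
# Load / validate / build
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must hold a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    """Write a config with all defaults made explicit (self-contained)."""
    with open(path, "w") as f:
        yaml.safe_dump(validate_config(cfg), f, sort_keys=True)


_ANALYSIS_DEFAULTS = {"threshold": None, "threshold_fraction": 0.5,
                      "connectivity": "FACE", "species": "H"}


def validate_config(cfg: dict) -> dict:
    """Normalize a config and fail early with a field-level message."""
    cfg = copy.deepcopy(cfg)
    if "network" not in cfg and "model" not in cfg:
        raise ConfigError("config needs a 'model' name or inline 'network'")
    geom = cfg.get("geometry") or {}
    kind = geom.get("kind")
    if kind not in ("disc", "cylinder"):
        raise ConfigError("geometry.kind must be 'disc' or 'cylinder'")
    if int(geom.get("radius", 0)) < 1:
        raise ConfigError("geometry.radius must be a positive integer")
    if kind == "cylinder" and int(geom.get("height", 0)) < 1:
        raise ConfigError("geometry.height must be a positive integer")
    geom.setdefault("shell_fraction", 0.04)
    if not 0 < float(geom["shell_fraction"]) < 1:
        raise ConfigError("geometry.shell_fraction must be in (0, 1)")
    run = cfg.get("run") or {}
    if "seed" not in run:
        raise ConfigError("run.seed is required")
    if run.get("max_events") is None and run.get("max_time") is None:
        raise ConfigError("run.max_events and/or run.max_time is required")
    analysis = dict(_ANALYSIS_DEFAULTS)
    analysis.update(cfg.get("analysis") or {})
    cfg["geometry"] = geom
    cfg["run"] = run
    cfg["analysis"] = analysis
    # building the network surfaces missing rate constants by name
    _network_from_config(cfg)
    return cfg


def _network_from_config(cfg: dict) -> ReactionNetwork:
    if "network" in cfg:
        return _engine.network_from_dict(cfg["network"])
    return make_model(cfg["model"], cfg.get("params") or {})


def build_system(cfg: dict):
    """(network, geometry, run_options) from a validated config."""
    cfg = validate_config(cfg)
    net = _network_from_config(cfg)
    g = cfg["geometry"]
    if g["kind"] == "disc":
        geom = build_disc(int(g["radius"]), float(g["shell_fraction"]))
    else:
        geom = build_cylinder(int(g["radius"]), int(g["height"]),
                              float(g["shell_fraction"]))
    return net, geom, dict(cfg["run"])
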