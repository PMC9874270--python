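"""Run configuration: nested YAML config with defaults mirroring the
calibrated parameter set, lossless round-tripping and a provenance hash."""

from __future__ import annotations

import hashlib

import yaml

__all__ = ["default_config", "load_config", "save_config", "config_hash",
           "merge_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "out",
        "log_level": "INFO",
        "fibril": {
            "diameter_nm": 20.0,
            "length_periods": 5,
            "D_nm": 67.0,
            "bead_spacing_A": 14.0,
            "beads_per_molecule": 219,
            "lateral_spacing_A": 15.3,
            "stagger_rule": "i+2j",
            "periodic_z": True,
        },
        "mineral": {
            "l_mineral_over_D": 0.44,
            "r_mineral_nm": 10.0,
            "target_w_percent": 35.0,
            "lattice_constant_A": None,  # default: sqrt(2)*2^(1/6)*sigma_HAp
            "m_collagen_bead_amu": 285000.0 / 219.0,
            "m_mineral_bead_amu": 285000.0 / 219.0,
        },
        "forcefield": {
            "bond": {"k0": 17.13, "k1": 97.66, "r0": 14.0, "r1": 18.2, "r2": 21.0},
            "angle": {"k_theta": 14.98, "theta0_min_deg": 164.0,
                      "theta0_max_deg": 180.0},
            "pair_cc": {"epsilon": 6.87, "sigma": 14.72, "r_cutoff": 21.0},
            "pair_mm": {"epsilon": 193.7, "sigma": 10.28, "r_cutoff": 13.85},
            "pair_cm": {"epsilon": 137.1, "sigma": 9.88, "r_cutoff": 20.0},
        },
        "md": {
            "dt_fs": 10.0,
            "temperature_K": 300.0,
            "thermostat": "nhc",
            "tau_fs": 1000.0,
            "equilibration_steps": 2000,
            "minimize_steps": 200,
            "sample_every": 50,
        },
        "tension": {
            "strain_rate_s": 2.5e6,
            "grip_fraction": 0.025,
            "target_strain": 0.5,
        },
    }


def merge_config(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(default_config(), user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
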