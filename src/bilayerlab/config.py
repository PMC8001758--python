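"""Run configuration: defaults, YAML loading, selection resolution.

A run configuration is a plain nested mapping.  All tunable defaults live
in :data:`DEFAULTS` so that ``bilayerlab config show-defaults`` prints the
single source of truth.  Selections map group names either to explicit
particle index lists or to particle labels; they are resolved and validated
against the trajectory before any computation starts.
"""

from __future__ import annotations

import copy
import hashlib

import numpy as np
import yaml

from .trajectory_io import Trajectory

__all__ = ["DEFAULTS", "load_config", "config_hash", "resolve_selections", "read_any"]

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "bilayerlab_out",
    "log_level": "INFO",
    "selections": {},
    "bilayer": {
        "n_lipids_per_leaflet": 100,
        "n_chol_per_leaflet": 0,
        "lattice_spacing": 0.78,      # nm
        "leaflet_separation": 4.0,    # nm
        "positional_jitter_sd": 0.05, # nm
        "box_fluctuation_sd": 0.05,   # nm
        "n_frames": 200,
        "frame_dt": 1.0,              # ps
        "probe_z": 3.0,               # nm; null = no probe
    },
    "membrane": {
        "n_blocks": 5,
        "residence_slab": [2.0, 3.5],  # nm
        "residence_min_gap": 0.0,      # ps
    },
    "rdf": {
        "r_max": 2.0,      # nm
        "dr": 0.002,       # nm
        "temperature": 323.15,  # K, for the PMF conversion
        "smooth": False,
    },
    "diffusion": {
        "dims": ["x", "y"],
        "d": 2,
        "window": [0.10, 0.50],
        "n_blocks": 5,
    },
    "wtm": {
        "potential": "double-well",   # double-well | four-basin | flat
        "sigma": [0.30, 20.0],
        "w0": 1.0,                    # kJ/mol
        "stride": 1.0,                # ps
        "bias_factor": 10.0,
        "temperature": 303.15,        # K
        "run_length_ns": 10.0,
        "dt": 0.005,                  # ps
        "friction": [10.0, 0.05],     # 1/ps per CV
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over :data:`DEFAULTS` (path may be None)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return _deep_merge(DEFAULTS, user)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, for run provenance logs."""
    canon = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def resolve_selections(traj: Trajectory, selections: dict) -> Trajectory:
    """Attach named groups to a trajectory, validating before any compute.

    Each selection maps a group name to either an explicit list of particle
    indices or a particle label string (all particles with that label).  An
    unresolvable selection raises a ValueError naming the selection.
    """
    for name, sel in selections.items():
        if isinstance(sel, str):
            idx = np.array([i for i, lab in enumerate(traj.labels) if lab == sel], dtype=int)
            if idx.size == 0:
                raise ValueError(
                    f"selection {name!r}: no particle carries label {sel!r}"
                )
        else:
            idx = np.asarray(list(sel), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= traj.n_particles):
                raise ValueError(f"selection {name!r}: particle index out of range")
        traj.groups[name] = idx
    # re-validate group invariants
    Trajectory(traj.times, traj.coords, traj.box, traj.labels, traj.groups)
    return traj


def read_any(path) -> Trajectory:
    """Read a trajectory file, dispatching on its extension (.xyz/.gro)."""
    from .trajectory_io import read_gro, read_xyz

    p = str(path)
    if p.endswith(".gro"):
        return read_gro(p)
    if p.endswith(".xyz"):
        return read_xyz(p)
    raise ValueError(f"unrecognised trajectory extension on {p!r} (use .xyz or .gro)")
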