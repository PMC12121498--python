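"""Run configuration with the package's canonical defaults.

Every default either matches the established value for the workflow
(lambda = 2 bohr, E0 = 0.01 hartree, polynomial order 4, excitation caps
10/10/10/8, 4-mode potential representation, T_AS = T = 25,000 a.u.,
dt = 10 a.u., 4000 trajectories, 1% monodromy tolerance, 300 K) or a
documented package choice (basis sizes, broadening width).  A flat YAML file
with per-module sections overrides the defaults; command-line flags override
the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "default_config", "load_config"]

_DEFAULTS = {
    "fit": {
        "lambda_bohr": 2.0,
        "E0": 0.01,
        "order": 4,
        "eta": 0.0,
        "w_energy": 1.0,
        "w_force": 1.0,
    },
    "freq": {
        "grad_tol": 1e-7,
        "hessian_step": 1e-3,
    },
    "vci": {
        "n_max": 4,
        "caps": [10, 10, 10, 8],
        "n_prim": 16,
        "n_modal": 12,
        "grid_points": 20,
        "n_states": 200,
        "e_max_cm": 4000.0,
        "include_vam": True,
        "include_mass_term": True,
    },
    "scivr": {
        "T_as": 25000.0,
        "T": 25000.0,
        "dt": 10.0,
        "n_traj": 4000,
        "det_tolerance": 0.01,
    },
    "spectrum": {
        "temperature": 300.0,
        "sigma_cm": 10.0,
        "I_constant": 0.2,
    },
    "seed": 0,
}


@dataclass
class RunConfig:
    sections: dict = field(default_factory=lambda: _deep_copy(_DEFAULTS))

    def get(self, section: str, key: str):
        if section not in self.sections:
            raise KeyError(f"unknown config section {section!r}")
        return self.sections[section][key]

    def update(self, section: str, **overrides) -> None:
        for key, val in overrides.items():
            if val is not None:
                self.sections[section][key] = val

    def as_dict(self) -> dict:
        return _deep_copy(self.sections)


def _deep_copy(d):
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Defaults overlaid with a YAML file's per-section values."""
    cfg = default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for section, values in data.items():
        if section == "seed":
            cfg.sections["seed"] = int(values)
            continue
        if section not in cfg.sections:
            raise KeyError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        cfg.sections[section].update(values)
    return cfg
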