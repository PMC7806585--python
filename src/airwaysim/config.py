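"""Run configuration: defaults, YAML loading, and block -> object builders.

The default deposition-correlation constants are not universal physics; they
are literature-consistent fits of the impaction-parameter form (upper airway,
Cheng-style oral replica data) and the Stokes-number form (tracheobronchial
regions, Zhou/Cheng-style cast data), shipped as overridable configuration
with their source notes.  No constant is hard-coded in the transport code.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .aerosol import DECorrelation, ParticleSpec
from .flow_network import BreathingCycle, GasProperties, LossModel, OutletBC
from .morphometry import BifurcationSpec, RingSpec, TracheaSpec


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "geometry": {
        "trachea": {"diameter": 1.56, "posterior_cut_offset": 0.65, "length": 10.0},
        "rings": {"step_p": 5.0, "width_L": 3.5, "depth_d": 0.5, "fillet_r": 0.3, "enabled": True},
        "bifurcation": {"x_n": 3.0, "c_c": 0.1, "transition_fraction": 0.8},
        "upper_airway": {"fixture": "packaged", "scale_mode": "fit_trachea"},
    },
    "flow": {
        "gas": {"density": 1.225, "viscosity": 1.7894e-5},
        "cycle": {"period_T": 4.0, "mean_inspiratory_flow": 6.0},
        "losses": {"pedley": True, "pedley_C": 1.85, "junction_K": 0.5, "larynx_K": 1.0, "ring_roughness": False},
        "bc": {"mode": "equal_pressure", "fractions": {}},
        "dt": 0.01,
    },
    "deposition": {
        # form ip_exp: DE = 1 - exp(-a * IP), IP in g um^2 L / (cm^3 min)
        # form stokes_exp: DE = 1 - exp(-a * St^b)
        "oral": {"form": "ip_exp", "a": 1.7e-4, "source": "oral replica IP fits (Cheng-style)"},
        "pharynx": {"form": "ip_exp", "a": 1.0e-4, "source": "oral replica IP fits (Cheng-style)"},
        "larynx": {"form": "ip_exp", "a": 3.0e-4, "source": "laryngeal constriction IP fits (Cheng-style)"},
        "trachea": {"form": "stokes_exp", "a": 1.0, "b": 1.2, "source": "TB cast Stokes fits (Zhou/Cheng-style)"},
        "bif1": {"form": "stokes_exp", "a": 1.6, "b": 1.2, "source": "TB cast Stokes fits (Zhou/Cheng-style)"},
        "bif2": {"form": "stokes_exp", "a": 1.6, "b": 1.2, "source": "TB cast Stokes fits (Zhou/Cheng-style)"},
        "bif3": {"form": "stokes_exp", "a": 1.6, "b": 1.2, "source": "TB cast Stokes fits (Zhou/Cheng-style)"},
        "peripheral": {"form": "stokes_exp", "a": 1.6, "b": 1.2, "source": "TB cast Stokes fits (Zhou/Cheng-style)"},
    },
    "particles": {
        "diameter_um": 7.0,
        "density": 998.2,
        "cunningham_Cc": 1.0,
        "n_particles": 2720,
        "disk_diameter_cm": 2.16,
        "injection_step_s": 0.2,
    },
    "seed": 0,
    "log_level": "INFO",
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for key in ("geometry", "flow", "deposition", "particles"):
        if key not in cfg:
            raise ConfigError(f"missing config block {key!r}")
    try:
        trachea_spec(cfg)
        ring_spec(cfg)
        bifurcation_spec(cfg)
        gas_properties(cfg)
        breathing_cycle(cfg)
        loss_model(cfg)
        outlet_bc(cfg)
        correlations(cfg)
        particle_spec(cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---- block builders -------------------------------------------------------

def trachea_spec(cfg: dict) -> TracheaSpec:
    return TracheaSpec(**cfg["geometry"]["trachea"])


def ring_spec(cfg: dict) -> RingSpec:
    return RingSpec(**cfg["geometry"]["rings"])


def bifurcation_spec(cfg: dict) -> BifurcationSpec:
    return BifurcationSpec(**cfg["geometry"]["bifurcation"])


def gas_properties(cfg: dict) -> GasProperties:
    return GasProperties(**cfg["flow"]["gas"])


def breathing_cycle(cfg: dict) -> BreathingCycle:
    return BreathingCycle(**cfg["flow"]["cycle"])


def loss_model(cfg: dict) -> LossModel:
    return LossModel(**cfg["flow"]["losses"])


def outlet_bc(cfg: dict) -> OutletBC:
    return OutletBC(**cfg["flow"]["bc"])


def correlations(cfg: dict) -> dict[str, DECorrelation]:
    out = {}
    for region, spec in cfg["deposition"].items():
        out[region] = DECorrelation(
            region=region,
            form=spec["form"],
            a=float(spec["a"]),
            b=float(spec.get("b", 1.0)),
            source=spec.get("source", ""),
        )
    return out


def particle_spec(cfg: dict, diameter_um: float | None = None) -> ParticleSpec:
    p = cfg["particles"]
    return ParticleSpec(
        diameter_dp=float(diameter_um if diameter_um is not None else p["diameter_um"]),
        density_rho_p=float(p["density"]),
        cunningham_Cc=float(p["cunningham_Cc"]),
    )
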