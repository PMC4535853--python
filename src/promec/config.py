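"""Configuration parsing and output serialization.

Run configurations are YAML files with up to four sections — ``pro``,
``mec``, ``coupling`` and ``sweep`` — mirroring the scenario presets.
Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults); units are normalized to the internal SI conventions on load.
Outputs are plain comma-separated tables plus a key-value summary and a
run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .coupling import SystemResult, SystemScenario
from .mec import MECStop
from .pro import LMH, PROMembraneParams, PROStop, PressurePolicy
from .defaults import DEFAULT_MEMBRANE
from . import __version__ as _pkg_version

__all__ = ["RunConfig", "load_config", "dump_config", "write_outputs"]

_PRO_KEYS = {
    "feed_volume_mL", "feed_pi_bar", "feed_substrate_mg_L",
    "feed_conductivity_mS_cm", "draw_molarity_M", "draw_conductivity_mS_cm",
    "draw_volume_mL", "pressure_policy", "P_bar", "flux_stop_LMH",
    "t_max_h", "dt_s", "membrane",
}
_MEMBRANE_KEYS = {"A", "B", "S", "D", "k", "area"}
_MEC_KEYS = {
    "voltage_V", "R_ext_ohm", "kinetics", "stop", "x_e0_mg_L", "x_m0_mg_L",
    "M_OX0_fraction", "pH0",
}
_MEC_STOP_KEYS = {"removal", "energy_budget_J", "t_max_h"}
_COUPLING_KEYS = {
    "use_pro_energy_budget", "anolyte_from_feed_effluent",
    "catholyte_from_draw_effluent", "min_anolyte_mL",
}
_SWEEP_KEYS = {"variable", "grid"}
_TOP_KEYS = {"pro", "mec", "coupling", "sweep", "temperature_K", "phi"}


@dataclass
class RunConfig:
    """A validated run description: the coupled scenario plus an optional
    sweep specification."""

    scenario: SystemScenario
    sweep: dict[str, Any] | None = None
    mec_init: dict[str, float] = field(default_factory=dict)
    source: dict[str, Any] = field(default_factory=dict)


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def _require_number(section: dict, key: str, where: str) -> None:
    if key in section and not isinstance(section[key], (int, float)):
        raise ValueError(f"{where}.{key} must be a number")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ValueError(
            f"{path} is empty; expected sections {sorted(_TOP_KEYS)}"
        )
    if not isinstance(raw, dict):
        raise ValueError(f"{path} must contain a mapping at the top level")
    return parse_config(raw)


def parse_config(raw: dict[str, Any]) -> RunConfig:
    """Validate a configuration mapping and build the scenario."""
    _check_keys(raw, _TOP_KEYS, "top level")
    pro = dict(raw.get("pro") or {})
    mec = dict(raw.get("mec") or {})
    coupling = dict(raw.get("coupling") or {})
    sweep_cfg = raw.get("sweep")
    _check_keys(pro, _PRO_KEYS, "pro")
    _check_keys(mec, _MEC_KEYS, "mec")
    _check_keys(coupling, _COUPLING_KEYS, "coupling")
    for key in ("feed_volume_mL", "draw_volume_mL", "draw_molarity_M",
                "feed_pi_bar", "P_bar", "t_max_h", "dt_s"):
        _require_number(pro, key, "pro")

    mem_cfg = dict(pro.pop("membrane", {}) or {})
    _check_keys(mem_cfg, _MEMBRANE_KEYS, "pro.membrane")
    if mem_cfg:
        membrane = PROMembraneParams(
            A=mem_cfg.get("A", DEFAULT_MEMBRANE.A),
            B=mem_cfg.get("B", DEFAULT_MEMBRANE.B),
            S_struct=mem_cfg.get("S", DEFAULT_MEMBRANE.S_struct),
            D=mem_cfg.get("D", DEFAULT_MEMBRANE.D),
            k=mem_cfg.get("k", DEFAULT_MEMBRANE.k),
            area=mem_cfg.get("area", DEFAULT_MEMBRANE.area),
        )
    else:
        membrane = DEFAULT_MEMBRANE

    mode = pro.get("pressure_policy", "half_delta_pi")
    policy = PressurePolicy(mode=mode, P_const=float(pro.get("P_bar", 0.0)))
    flux_stop = float(pro.get("flux_stop_LMH", 0.5)) * LMH
    pro_stop = PROStop(
        flux_threshold=flux_stop,
        t_max=float(pro.get("t_max_h", 48.0)) * 3600.0,
    )

    mec_stop_cfg = dict(mec.get("stop") or {})
    _check_keys(mec_stop_cfg, _MEC_STOP_KEYS, "mec.stop")
    mec_stop = MECStop(
        removal_fraction=float(mec_stop_cfg.get("removal", 0.999)),
        energy_budget_J=mec_stop_cfg.get("energy_budget_J"),
        t_max=float(mec_stop_cfg.get("t_max_h", 250.0)) * 3600.0,
    )

    scenario_kwargs: dict[str, Any] = dict(
        membrane=membrane,
        pressure_policy=policy,
        pro_stop=pro_stop,
        pro_dt=float(pro.get("dt_s", 60.0)),
        voltage_V=float(mec.get("voltage_V", 0.8)),
        mec_overrides=dict(mec.get("kinetics") or {}),
        mec_stop=mec_stop,
    )
    if "R_ext_ohm" in mec:
        scenario_kwargs["mec_overrides"]["R_ext"] = float(mec["R_ext_ohm"])
    for cfg_key, field_name in (
        ("feed_volume_mL", "feed_volume_mL"),
        ("feed_pi_bar", "feed_pi_bar"),
        ("feed_substrate_mg_L", "feed_substrate_mg_L"),
        ("feed_conductivity_mS_cm", "feed_conductivity_mS_cm"),
        ("draw_molarity_M", "draw_molarity_M"),
        ("draw_volume_mL", "draw_volume_mL"),
    ):
        if cfg_key in pro:
            scenario_kwargs[field_name] = float(pro[cfg_key])
    if "draw_conductivity_mS_cm" in pro:
        if "draw_molarity_M" in pro:
            raise ValueError(
                "give either pro.draw_molarity_M or "
                "pro.draw_conductivity_mS_cm, not both"
            )
        from .chemistry import conductivity_to_molarity

        scenario_kwargs["draw_molarity_M"] = conductivity_to_molarity(
            float(pro["draw_conductivity_mS_cm"])
        )
    for key in _COUPLING_KEYS & set(coupling):
        scenario_kwargs[key] = coupling[key]

    sweep_spec = None
    if sweep_cfg is not None:
        _check_keys(dict(sweep_cfg), _SWEEP_KEYS, "sweep")
        if "variable" not in sweep_cfg or "grid" not in sweep_cfg:
            raise ValueError("sweep needs both 'variable' and 'grid'")
        sweep_spec = {
            "variable": str(sweep_cfg["variable"]),
            "grid": [float(v) for v in sweep_cfg["grid"]],
        }

    mec_init = {
        k: float(mec[k])
        for k in ("x_e0_mg_L", "x_m0_mg_L", "M_OX0_fraction", "pH0")
        if k in mec
    }
    return RunConfig(
        scenario=SystemScenario(**scenario_kwargs),
        sweep=sweep_spec,
        mec_init=mec_init,
        source=raw,
    )


def dump_config(cfg: RunConfig) -> dict[str, Any]:
    """Normalized mapping for a RunConfig (stable under reload)."""
    s = cfg.scenario
    out: dict[str, Any] = {
        "pro": {
            "feed_volume_mL": s.feed_volume_mL,
            "feed_pi_bar": s.feed_pi_bar,
            "feed_substrate_mg_L": s.feed_substrate_mg_L,
            "feed_conductivity_mS_cm": s.feed_conductivity_mS_cm,
            "draw_molarity_M": s.draw_molarity_M,
            "draw_volume_mL": s.draw_volume_mL,
            "pressure_policy": s.pressure_policy.mode,
            "P_bar": s.pressure_policy.P_const,
            "flux_stop_LMH": s.pro_stop.flux_threshold / LMH,
            "t_max_h": s.pro_stop.t_max / 3600.0,
            "dt_s": s.pro_dt,
            "membrane": {
                "A": s.membrane.A,
                "B": s.membrane.B,
                "S": s.membrane.S_struct,
                "D": s.membrane.D,
                "k": s.membrane.k,
                "area": s.membrane.area,
            },
        },
        "mec": {
            "voltage_V": s.voltage_V,
            "kinetics": dict(s.mec_overrides),
            "stop": {
                "removal": s.mec_stop.removal_fraction,
                "energy_budget_J": s.mec_stop.energy_budget_J,
                "t_max_h": s.mec_stop.t_max / 3600.0,
            },
        },
        "coupling": {
            "use_pro_energy_budget": s.use_pro_energy_budget,
            "anolyte_from_feed_effluent": s.anolyte_from_feed_effluent,
            "catholyte_from_draw_effluent": s.catholyte_from_draw_effluent,
            "min_anolyte_mL": s.min_anolyte_mL,
        },
    }
    if cfg.sweep is not None:
        out["sweep"] = dict(cfg.sweep)
    return out


def write_outputs(
    result: SystemResult | Any,
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write trajectory tables, a key-value summary and a run log.

    Deterministic scenarios produce byte-identical outputs across runs
    (the log carries a config hash, not a timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, text: str) -> None:
        p = out_dir / name
        p.write_text(text)
        written.append(p)

    if isinstance(result, SystemResult):
        _write("pro_trajectory.csv", result.pro.to_frame().to_csv(index=False))
        _write("mec_trajectory.csv", result.mec.to_frame().to_csv(index=False))
        lines = [
            f"{k},{v}" for k, v in result.summary.items()
        ]
        _write("summary.csv", "key,value\n" + "\n".join(lines) + "\n")
    elif hasattr(result, "to_frame"):
        _write("trajectory.csv", result.to_frame().to_csv(index=False))
    elif hasattr(result, "to_csv"):
        _write("sweep.csv", result.to_csv(index=False))

    log = {"package_version": _pkg_version}
    if config is not None:
        blob = json.dumps(dump_config(config), sort_keys=True, default=str)
        log["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    if seed is not None:
        log["seed"] = seed
    _write("run_log.json", json.dumps(log, indent=2, sort_keys=True) + "\n")
    return written
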