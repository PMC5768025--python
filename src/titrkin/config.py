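"""YAML run configuration: one file describes a whole in-silico campaign.

Sections (all optional, defaults reproduce the study conditions):

``equilibrium``
    mode, anchor_concentration_mM, anchor_pressure_bar, anchor_o2_fraction,
    temperature_C, water_vapor_correction (see :mod:`titrkin.equilibrium`).
``reactor``
    volume_uL, inner_radius_um, kLa_per_min, D_small_m2s, D_enzyme_m2s.
``kinetics``
    kcat_umol_min_mg, Kmo_mM, Kms_mM — the ground-truth parameter triple.
``campaigns``
    noise_cv, replicates, n_o2_levels, enzyme_conc_mg_mL,
    degradation_factor_B (activity scaling of the second campaign).
``estimation``
    n_starts, weighting.
``ramp``
    duration_min, q_start_uL_min, q_end_uL_min, S0_mM, sampling_interval_min.
``rtd``
    flow_uL_min, dispersion_number, noise_sd.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .equilibrium import GasCondition, HenryCalibration
from .estimation import FitOptions
from .kinetics import GOX_REFERENCE_PARAMS, KineticParams
from .reactor import FlowProgram, ReactorSpec
from .synthetic import reference_design

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with builders for every module's inputs."""

    raw: dict

    @property
    def seed(self) -> int | None:
        return self.raw.get("seed")

    def config_hash(self) -> str:
        """Stable sha256 of the canonicalized configuration (for run logs)."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- builders ----------------------------------------------------------
    def calibration(self) -> HenryCalibration:
        d = self.raw.get("equilibrium", {})
        mode = d.get("mode", "high_pressure_anchor")
        temperature = float(d.get("temperature_C", 25.0))
        vapor = bool(d.get("water_vapor_correction", False))
        if mode == "explicit_constant":
            return HenryCalibration.explicit(
                float(d["constant_mM_per_bar"]), temperature_C=temperature
            )
        defaults = {
            "air_anchor": (0.276, 1.01325, 0.2095),
            "high_pressure_anchor": (7.13, 6.0, 1.0),
        }
        if mode not in defaults:
            raise ValueError(f"unknown equilibrium mode {mode!r}")
        conc0, p0, x0 = defaults[mode]
        anchor = GasCondition(
            float(d.get("anchor_pressure_bar", p0)),
            float(d.get("anchor_o2_fraction", x0)),
            temperature,
        )
        factory = getattr(HenryCalibration, mode)
        return factory(
            anchor_concentration_mM=float(d.get("anchor_concentration_mM", conc0)),
            anchor_condition=anchor,
            water_vapor_correction=vapor,
        )

    def reactor_spec(self) -> ReactorSpec:
        d = self.raw.get("reactor", {})
        return ReactorSpec(
            volume_uL=float(d.get("volume_uL", 155.0)),
            inner_radius_um=float(d.get("inner_radius_um", 115.0)),
            kLa_per_min=float(d.get("kLa_per_min", 6.0)),
            D_small_m2s=float(d.get("D_small_m2s", 1e-9)),
            D_enzyme_m2s=float(d.get("D_enzyme_m2s", 1e-11)),
        )

    def truth(self) -> KineticParams:
        d = self.raw.get("kinetics", {})
        ref = GOX_REFERENCE_PARAMS["titr_combined"]
        return KineticParams(
            float(d.get("kcat_umol_min_mg", ref.kcat)),
            float(d.get("Kmo_mM", ref.K_MO)),
            float(d.get("Kms_mM", ref.K_MS)),
        )

    def campaigns(self, seed: int):
        d = self.raw.get("campaigns", {})
        atm, hp = reference_design(
            noise_cv=float(d.get("noise_cv", 0.03)),
            replicates=int(d.get("replicates", 1)),
            n_o2_levels=int(d.get("n_o2_levels", 6)),
            seed=seed,
        )
        enzyme = float(d.get("enzyme_conc_mg_mL", 0.05))
        atm = replace(atm, enzyme_conc_mg_mL=enzyme)
        hp = replace(hp, enzyme_conc_mg_mL=enzyme)
        return atm, hp

    def degradation_factor_B(self) -> float:
        return float(self.raw.get("campaigns", {}).get("degradation_factor_B", 1.0))

    def fit_options(self, seed: int) -> FitOptions:
        d = self.raw.get("estimation", {})
        return FitOptions(
            n_starts=int(d.get("n_starts", 20)),
            weighting=str(d.get("weighting", "absolute")),
            seed=seed,
        )

    def ramp_program(self) -> FlowProgram:
        d = self.raw.get("ramp", {})
        q_start = float(d.get("q_start_uL_min", 100.0))
        q_end = float(d.get("q_end_uL_min", 10.0))
        duration = float(d.get("duration_min", 180.0))
        schedule = str(d.get("schedule", "tau_linear"))
        if schedule == "linear":
            return FlowProgram.ramp_down(duration, q_start, q_end)
        if schedule != "tau_linear":
            raise ValueError(f"unknown ramp schedule {schedule!r}")
        vol = self.reactor_spec().volume_uL
        return FlowProgram.tau_ramp(vol, vol / q_start, vol / q_end, duration)

    def ramp_params(self) -> dict:
        d = self.raw.get("ramp", {})
        return {
            "S0_mM": float(d.get("S0_mM", 400.0)),
            "sampling_interval_min": float(d.get("sampling_interval_min", 0.5)),
        }

    def rtd_params(self) -> dict:
        d = self.raw.get("rtd", {})
        return {
            "flow_uL_min": float(d.get("flow_uL_min", 50.0)),
            "dispersion_number": float(d.get("dispersion_number", 0.005)),
            "noise_sd": float(d.get("noise_sd", 0.0)),
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig(raw={})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return RunConfig(raw=raw)
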