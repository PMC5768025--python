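"""Synthetic campaign generator emulating the study design.

Everything downstream (rate extraction, fitting, identifiability,
RTD analysis) is exercised on data generated here, with the structure of
the original campaigns: glucose at 25/100/200/400 mM crossed with
dissolved-O2 levels spanning 0.14-1.3 mM at atmospheric pressure
(5-100 % O2 in the feed gas) and 0.9-7.13 mM at 6 bar; multiplicative
Gaussian measurement noise on rates; and an optional between-campaign
enzyme-degradation factor applied to kcat.

Every generator is a pure function of its configuration and seed:
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import RateObservation
from .kinetics import EnzymeLoad, KineticParams, specific_rate
from .reactor import FlowProgram, ReactorSpec, flow_ramp_series, simulate_rtd

__all__ = [
    "CampaignConfig",
    "reference_design",
    "generate_rate_table",
    "generate_ramp_experiment",
    "generate_tracer",
    "design_from_campaigns",
]

#: Study glucose levels [mM].
GLUCOSE_LEVELS_MM = (25.0, 100.0, 200.0, 400.0)
#: Dissolved-O2 window at atmospheric pressure, 5-100 % O2 [mM].
O2_RANGE_1ATM_MM = (0.14, 1.3)
#: Dissolved-O2 window at 6 bar [mM].
O2_RANGE_6BAR_MM = (0.9, 7.13)
#: Between-campaign activity loss of the enzyme formulation (on kcat).
DEGRADATION_FACTOR = 0.79


@dataclass(frozen=True)
class CampaignConfig:
    """One measurement campaign: the (S, O) grid and its noise model.

    noise_cv is the relative SD of a single rate measurement (default 3 %,
    multiplicative Gaussian); degradation_factor multiplies kcat for this
    campaign, modelling activity loss of the formulation between campaigns.
    enzyme_conc is the constant enzyme feed [mg formulation / mL].
    """

    glucose_levels_mM: tuple[float, ...]
    o2_levels_mM: tuple[float, ...]
    replicates: int = 1
    noise_cv: float = 0.03
    enzyme_conc_mg_mL: float = 0.05
    degradation_factor: float = 1.0
    seed: int = 0
    label: str = "A"

    def __post_init__(self) -> None:
        if not self.glucose_levels_mM or not self.o2_levels_mM:
            raise ValueError("glucose and O2 level lists must be non-empty")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.degradation_factor > 0:
            raise ValueError("degradation_factor must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def grid(self) -> list[tuple[float, float]]:
        return [(S, O) for S in self.glucose_levels_mM for O in self.o2_levels_mM]


def reference_design(
    noise_cv: float = 0.03,
    replicates: int = 1,
    n_o2_levels: int = 6,
    seed: int = 0,
) -> tuple[CampaignConfig, CampaignConfig]:
    """The study's two-pressure design: (1 atm campaign, 6 bar campaign).

    Glucose {25, 100, 200, 400} mM; six log-spaced dissolved-O2 levels per
    pressure spanning 0.14-1.3 mM (atmospheric, 5-100 % O2) and
    0.9-7.13 mM (6 bar).  Log spacing reflects gas-blending practice of
    covering a wide concentration window evenly on a fold-change scale.
    """
    o2_atm = tuple(np.geomspace(*O2_RANGE_1ATM_MM, n_o2_levels))
    o2_hp = tuple(np.geomspace(*O2_RANGE_6BAR_MM, n_o2_levels))
    mk = lambda o2, lbl, s: CampaignConfig(
        glucose_levels_mM=GLUCOSE_LEVELS_MM,
        o2_levels_mM=o2,
        replicates=replicates,
        noise_cv=noise_cv,
        seed=s,
        label=lbl,
    )
    return mk(o2_atm, "1atm", seed), mk(o2_hp, "6bar", seed + 1)


def generate_rate_table(config: CampaignConfig, truth: KineticParams) -> list[RateObservation]:
    """Seeded noisy rate observations on the campaign grid.

    rate = r_E(S, O; kcat*degradation, K_MO, K_MS) * (1 + eps) with
    eps ~ N(0, noise_cv), truncated at zero so rates stay physical.
    """
    eff = KineticParams(truth.kcat * config.degradation_factor, truth.K_MO, truth.K_MS)
    rng = np.random.default_rng(config.seed)
    obs = []
    for S, O in config.grid():
        r_true = specific_rate(S, O, eff)
        for _ in range(config.replicates):
            eps = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
            obs.append(
                RateObservation(
                    S=S, O=O, rate=max(r_true * (1.0 + eps), 0.0), campaign=config.label
                )
            )
    return obs


def generate_ramp_experiment(
    config: CampaignConfig,
    truth: KineticParams,
    program: FlowProgram,
    spec: ReactorSpec,
    o2_sat_mM: float,
    S0_mM: float = 400.0,
    sampling_interval_min: float = 0.5,
) -> pd.DataFrame:
    """Noisy flow-ramp series: the reactor twin plus measurement noise.

    Multiplicative Gaussian noise (config.noise_cv) is applied to the
    measured product concentration; conversion is recomputed from the
    noisy product.  noise_cv = 0 reproduces ``flow_ramp_series`` exactly.
    """
    eff = KineticParams(truth.kcat * config.degradation_factor, truth.K_MO, truth.K_MS)
    load = EnzymeLoad(concentration_mg_mL=config.enzyme_conc_mg_mL, catalase=True)
    df = flow_ramp_series(
        program, S0_mM, load, eff, spec, o2_sat_mM, sampling_interval_min=sampling_interval_min
    )
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        eps = rng.normal(0.0, config.noise_cv, size=len(df))
        df["product_mM"] = np.maximum(df["product_mM"] * (1.0 + eps), 0.0)
        df["conversion"] = df["product_mM"] / S0_mM
    return df


def generate_tracer(
    spec: ReactorSpec,
    flow_uL_min: float,
    dispersion_number: float = 0.005,
    noise_sd: float = 0.0,
    seed: int | None = None,
    injection: str = "pulse",
) -> pd.DataFrame:
    """One-stop tracer fixture; delegates to the reactor RTD model."""
    return simulate_rtd(
        spec,
        flow_uL_min,
        injection=injection,
        dispersion_number=dispersion_number,
        noise_sd=noise_sd,
        seed=seed,
    )


def design_from_campaigns(configs, noise_cv: float | None = None):
    """Collapse campaign grids into a DesignSpec for identifiability analysis."""
    from .estimation import DesignSpec

    points, reps = [], []
    for c in configs:
        for pt in c.grid():
            points.append(pt)
            reps.append(c.replicates)
    cv = noise_cv if noise_cv is not None else configs[0].noise_cv
    if cv <= 0:
        cv = 0.03  # information analysis needs a noise scale; use the nominal CV
    return DesignSpec(points=tuple(points), replicates=tuple(reps), noise_cv=cv)
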