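"""Packaged simulation scenarios.

The ``paper_default`` scenario encodes the bench-scale reactor the
package models: 4.5-liter working volume, hydraulic retention time 6.25
days, 86.4 mg NH4+-N/day influent, DO setpoint ~0.2 mg/L, a biofilm-
homogenizing disturbance at t=0, and 56 daily samples.  Three
successional stages (days 1-13, 14-34, 35-56) are planted through
time-varying guild fitness plus stage-dependent within-guild taxon
weights: an early aerobic (AOB/NOB) bloom while anammox is suppressed, an
unstable middle stage with elevated day-to-day compositional noise, and a
recovered anammox-balanced late stage resembling the pre-disturbance
steady state.

Scenario *definitions* are deterministic (a fixed construction seed
shapes the rare-taxon tail); the run seed only drives noise and count
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .simulate import (
    CommunityCounts,
    GuildParams,
    ReactorConfig,
    ReactorState,
    SimOutput,
    generate_community_counts,
    run_to_steady_state,
    simulate_reactor,
)

__all__ = ["Scenario", "get_scenario", "run_scenario",
           "default_guilds", "SCENARIO_NAMES"]

#: stage boundaries (days); samples 1-13 / 14-34 / 35-56
STAGE_BREAKS = (13.5, 34.5)
_TRANSITION_WIDTH = 0.5  # days; sharpness of the planted stage shifts
_SCENARIO_BUILD_SEED = 20170710  # fixed: scenarios are identical every run


def default_guilds() -> tuple[GuildParams, ...]:
    """Calibrated guild set for the packaged reactor scenarios.

    Rates follow activated-sludge convention: fast aerobic ammonium and
    nitrite oxidizers, slow-growing anammox with oxygen inhibition, and a
    nitrogen-neutral heterotroph pool.
    """
    return (
        GuildParams("AOB", mu_max=1.0, k_substrate=0.3, k_oxygen=0.2,
                    yield_biomass=0.15, decay=0.04, attached_fraction=0.8,
                    attached_capacity=5.0),
        GuildParams("NOB", mu_max=0.7, k_substrate=0.2, k_oxygen=0.6,
                    yield_biomass=0.10, decay=0.02, attached_fraction=0.8,
                    attached_capacity=3.0),
        GuildParams("CMX", mu_max=0.35, k_substrate=0.5, k_oxygen=0.15,
                    yield_biomass=0.12, decay=0.03, attached_fraction=0.85,
                    attached_capacity=30.0),
        GuildParams("AMX", mu_max=0.15, k_substrate=0.1, k_oxygen=0.0,
                    oxygen_inhibition_k=0.4, yield_biomass=0.07, decay=0.005,
                    attached_fraction=0.95, attached_capacity=9.0,
                    attach_rate=0.15, detach_rate=0.01),
        GuildParams("HET", mu_max=0.3, k_substrate=1.0, k_oxygen=0.2,
                    yield_biomass=0.3, decay=0.03, attached_fraction=0.7,
                    attached_capacity=15.0),
    )


def _stage_weights(t: float) -> tuple[float, float, float]:
    """Smooth indicator weights (s1, s2, s3) of the three stages at day t."""
    b1, b2 = STAGE_BREAKS
    w = _TRANSITION_WIDTH
    z1 = np.clip((t - b1) / w, -500, 500)
    z3 = np.clip(-(t - b2) / w, -500, 500)
    s1 = 1.0 / (1.0 + math.exp(z1))
    s3 = 1.0 / (1.0 + math.exp(z3))
    s2 = max(0.0, 1.0 - s1 - s3)
    return s1, s2, s3


def _stage_label(t: float) -> int:
    s = _stage_weights(t)
    return int(np.argmax(s)) + 1


_FITNESS = {
    # guild: (stage1, stage2, stage3) mu_max multipliers
    "AOB": (1.8, 1.1, 0.8),
    "NOB": (1.6, 1.0, 0.9),
    "CMX": (0.9, 1.2, 1.2),
    "AMX": (0.22, 0.55, 1.0),
    "HET": (1.0, 1.4, 1.0),
}


def _fitness_fn(guild_ids: tuple[str, ...]) -> Callable[[float], np.ndarray]:
    table = np.array([_FITNESS[g] for g in guild_ids])

    def fn(t: float) -> np.ndarray:
        s = np.array(_stage_weights(t))
        return table @ s

    return fn


# top-10 genera of the modelled reactor with per-stage within-guild weights
_CORE_TAXA: dict[str, dict[str, tuple[float, float, float]]] = {
    "AMX": {
        "Candidatus_Jettenia": (0.90, 0.62, 0.45),
        "SM1A02": (0.05, 0.26, 0.38),
        "Groundwater_metagenome": (0.05, 0.12, 0.17),
    },
    "CMX": {"Nitrospira": (1.0, 1.0, 1.0)},
    "NOB": {"Nitrospira": (1.0, 1.0, 1.0)},
    "AOB": {"Nitrosomonas": (1.0, 1.0, 1.0)},
    "HET": {
        "Denitratisoma": (0.55, 0.28, 0.10),
        "Sideroxydans": (0.28, 0.12, 0.04),
        "AKYH767": (0.02, 0.22, 0.42),
        "OLB12": (0.02, 0.16, 0.30),
        "Bryobacter": (0.13, 0.22, 0.14),
    },
}

_CORE_PHYLA = {
    "Nitrospira": "Nitrospirae",
    "Candidatus_Jettenia": "Planctomycetes",
    "SM1A02": "Planctomycetes",
    "Groundwater_metagenome": "Planctomycetes",
    "Nitrosomonas": "Proteobacteria",
    "Denitratisoma": "Proteobacteria",
    "Sideroxydans": "Proteobacteria",
    "AKYH767": "Bacteroidetes",
    "OLB12": "Bacteroidetes",
    "Bryobacter": "Acidobacteria",
}

_TAIL_PHYLA = ("Proteobacteria", "Bacteroidetes", "Chloroflexi",
               "Acidobacteria", "Planctomycetes", "Armatimonadetes")


def _build_taxon_tables(n_tail: int = 90, tail_mass: float = 0.35):
    """Core + rare-tail taxon weights per guild and stage, plus taxonomy.

    The tail gives realistic richness; its weights are lognormal with a
    mild stage-specific perturbation (more tail mass late, echoing the
    late-stage richness rise of slow-recolonizing reactors).
    """
    rng = np.random.default_rng(_SCENARIO_BUILD_SEED)
    guild_tables: dict[str, dict[str, tuple[float, float, float]]] = {
        g: dict(taxa) for g, taxa in _CORE_TAXA.items()
    }
    taxonomy_rows = [(t, t, _CORE_PHYLA[t]) for t in _CORE_PHYLA]
    guild_cycle = ("HET", "HET", "HET", "AMX", "CMX", "AOB", "NOB")
    tail_stage_scale = (0.7, 1.0, 1.4)
    for i in range(n_tail):
        guild = guild_cycle[i % len(guild_cycle)]
        name = f"ASV_tail_{i:03d}"
        base = float(rng.lognormal(mean=0.0, sigma=1.0))
        # log-space random walk across stages: successional drift, so the
        # early and late stages differ most
        steps = rng.normal(0.0, 0.8, size=2)
        jitter = np.exp(np.array([0.0, steps[0], steps[0] + steps[1]]))
        core_mass = sum(w[0] for w in _CORE_TAXA[guild].values())
        unit = tail_mass * core_mass / (n_tail / len(guild_cycle))
        weights = tuple(unit * base * tail_stage_scale[s] * jitter[s]
                        for s in range(3))
        guild_tables[guild][name] = weights
        taxonomy_rows.append(
            (name, "unclassified", _TAIL_PHYLA[i % len(_TAIL_PHYLA)]))
    taxonomy = pd.DataFrame(taxonomy_rows,
                            columns=["taxon_id", "genus", "phylum"]
                            ).set_index("taxon_id")
    return guild_tables, taxonomy


@dataclass
class Scenario:
    """A fully specified simulation + count-emission recipe."""

    name: str
    config: ReactorConfig
    guilds: tuple[GuildParams, ...]
    disturbance_day: float | None
    depth: int
    dispersion_by_stage: tuple[float, float, float]
    do_noise_sd: float
    measurement_cv: float
    taxonomy: pd.DataFrame = field(repr=False)
    _guild_tables: dict = field(repr=False)

    def fitness_fn(self) -> Callable[[float], np.ndarray]:
        return _fitness_fn(tuple(g.guild_id for g in self.guilds))

    def stage_fn(self) -> Callable[[float], int]:
        return _stage_label

    def weight_fn(self) -> Callable[[float], Mapping[str, Mapping[str, float]]]:
        tables = self._guild_tables

        def fn(day: float) -> Mapping[str, Mapping[str, float]]:
            s = np.array(_stage_weights(day))
            return {
                g: {t: float(np.dot(w, s)) for t, w in taxa.items()}
                for g, taxa in tables.items()
            }

        return fn

    def dispersion_fn(self) -> Callable[[float], float]:
        disp = np.array(self.dispersion_by_stage, dtype=float)

        def fn(day: float) -> float:
            s = np.array(_stage_weights(day))
            # mix precisions so the middle stage is genuinely noisier
            return float(1.0 / np.dot(1.0 / disp, s))

        return fn

    def steady_fitness(self) -> np.ndarray:
        return self.fitness_fn()(1e6)


SCENARIO_NAMES = ("paper_default",)

_steady_cache: dict[str, tuple[ReactorState, float]] = {}


def get_scenario(name: str = "paper_default") -> Scenario:
    if name != "paper_default":
        raise ValueError(f"unknown scenario {name!r}; available: {SCENARIO_NAMES}")
    guild_tables, taxonomy = _build_taxon_tables()
    return Scenario(
        name=name,
        config=ReactorConfig(),
        guilds=default_guilds(),
        disturbance_day=0.0,
        depth=42000,
        dispersion_by_stage=(900.0, 350.0, 900.0),
        do_noise_sd=0.04,
        measurement_cv=0.02,
        taxonomy=taxonomy,
        _guild_tables=guild_tables,
    )


def presteady_state(scenario: Scenario) -> ReactorState:
    """Pre-disturbance steady state (cached per scenario name)."""
    if scenario.name not in _steady_cache:
        state, _ = run_to_steady_state(
            scenario.config, scenario.guilds,
            fitness=scenario.steady_fitness(), tol=1e-7, max_days=2000.0)
        _steady_cache[scenario.name] = (state, 0.0)
    return _steady_cache[scenario.name][0].copy()


def run_scenario(
    scenario: Scenario | str = "paper_default",
    seed: int = 0,
    *,
    noisy: bool = True,
) -> tuple[SimOutput, CommunityCounts]:
    """Spin up to steady state, disturb at t=0, run 56 days, emit counts."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    state = presteady_state(scenario)
    sim = simulate_reactor(
        scenario.config,
        scenario.guilds,
        disturbance_day=scenario.disturbance_day,
        initial_state=state,
        fitness_fn=scenario.fitness_fn(),
        do_noise_sd=scenario.do_noise_sd if noisy else 0.0,
        measurement_cv=scenario.measurement_cv if noisy else 0.0,
        stage_fn=scenario.stage_fn(),
        rng=np.random.default_rng(np.random.SeedSequence([seed, 1])),
    )
    counts = generate_community_counts(
        sim,
        taxon_map={g: {t: w[2] for t, w in taxa.items()}
                   for g, taxa in scenario._guild_tables.items()},
        depth=scenario.depth,
        seed=int(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % (2**31)),
        taxonomy=scenario.taxonomy,
        weight_fn=scenario.weight_fn(),
        dispersion_fn=scenario.dispersion_fn(),
    )
    return sim, counts
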