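"""Seeded synthetic harvest tables for the two pot experiments.

Emulates the randomized complete block designs of the trials: the
resistance experiment (3 diversity treatments x 6 constant WHC levels x 4
blocks, one final harvest at 50 DAS) and the resilience experiment (3
diversity treatments x 2 drought arms x 5 destructive harvests x 5 blocks,
with a 14-day drought event between 23 and 37 DAS).  Each pot is measured
exactly once; block ids are shared across harvests so that downstream
analyses can pair observations within block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .growth import AC, BM, SpeciesParams, default_species_params, simulate_pot
from .schedules import (
    IrrigationSchedule,
    build_resilience_schedules,
    default_resistance_schedules,
)

AC_MONO = "AC_mono"
BM_MONO = "BM_mono"
MIX = "MIX"
DIVERSITY_LEVELS: tuple[str, ...] = (AC_MONO, BM_MONO, MIX)

TOTAL = "total"

#: Ground area of the square 12 x 12 cm resistance pots, m^2.
SQUARE_POT_AREA_M2 = 0.12 * 0.12
#: Ground area of the round Ø12 cm resilience pots, m^2.
ROUND_POT_AREA_M2 = math.pi * 0.06**2

#: Tidy observation-table schema, in column order.
OBS_COLUMNS = (
    "experiment", "block", "diversity", "component", "arm",
    "harvest", "das", "biomass_g", "cum_water_l",
)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise: shared block effect + pot-level CV."""

    sd_block: float = 0.10
    cv_pot: float = 0.07

    def __post_init__(self) -> None:
        if self.sd_block < 0 or self.cv_pot < 0:
            raise ValueError("noise standard deviations must be non-negative")


NO_NOISE = NoiseModel(0.0, 0.0)


@dataclass
class ExperimentDesign:
    """Design of one pot experiment.

    ``schedules`` maps arm id to its irrigation schedule; the arm set of the
    design is its key set.  ``harvest_days`` are DAS of the destructive
    harvests, labelled H1..Hk in temporal order.
    """

    experiment: str
    schedules: Mapping[str, IrrigationSchedule]
    n_blocks: int
    harvest_days: tuple[int, ...]
    diversity_levels: tuple[str, ...] = DIVERSITY_LEVELS
    seeds_per_pot: int = 24
    pot_area: float = ROUND_POT_AREA_M2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("resistance", "resilience"):
            raise ValueError("experiment must be 'resistance' or 'resilience'")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        days = tuple(int(d) for d in self.harvest_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("harvest_days must be strictly increasing")
        if self.experiment == "resistance" and len(days) != 1:
            raise ValueError("a resistance design has exactly one harvest day")
        if self.experiment == "resilience" and len(days) < 2:
            raise ValueError("a resilience design needs >= 2 harvest days")
        if self.pot_area <= 0:
            raise ValueError("pot_area must be positive")
        if self.seeds_per_pot < 2 or self.seeds_per_pot % 2:
            raise ValueError("seeds_per_pot must be an even count >= 2")
        self.harvest_days = days
        horizon = max(days) + 1
        for arm, sched in self.schedules.items():
            if sched.n_days < horizon:
                raise ValueError(
                    f"schedule {arm!r} covers {sched.n_days} days but the last "
                    f"harvest is at {max(days)} DAS"
                )

    @property
    def n_days(self) -> int:
        return max(self.harvest_days) + 1

    @property
    def harvest_ids(self) -> tuple[str, ...]:
        return tuple(f"H{i + 1}" for i in range(len(self.harvest_days)))


def resistance_design(n_blocks: int = 4, harvest_day: int = 50,
                      seed: int | None = None, **schedule_kwargs) -> ExperimentDesign:
    """Default constant-drought design: 6 WHC levels, 4 blocks, harvest at 50 DAS."""
    return ExperimentDesign(
        experiment="resistance",
        schedules=default_resistance_schedules(n_days=harvest_day + 1, **schedule_kwargs),
        n_blocks=n_blocks,
        harvest_days=(harvest_day,),
        pot_area=SQUARE_POT_AREA_M2,
        seed=seed,
    )


def resilience_design(n_blocks: int = 5,
                      harvest_days: tuple[int, ...] = (23, 37, 44, 58, 72),
                      seed: int | None = None, **schedule_kwargs) -> ExperimentDesign:
    """Default drought-event design: 2 arms, 5 blocks, harvests 23..72 DAS."""
    n_days = max(harvest_days) + 1
    ns, stressed = build_resilience_schedules(n_days=n_days, **schedule_kwargs)
    return ExperimentDesign(
        experiment="resilience",
        schedules={ns.arm_id: ns, stressed.arm_id: stressed},
        n_blocks=n_blocks,
        harvest_days=tuple(harvest_days),
        pot_area=ROUND_POT_AREA_M2,
        seed=seed,
    )


def _plant_counts(diversity: str, seeds_per_pot: int) -> dict[str, int]:
    half = seeds_per_pot // 2
    if diversity == AC_MONO:
        return {AC: seeds_per_pot, BM: 0}
    if diversity == BM_MONO:
        return {AC: 0, BM: seeds_per_pot}
    if diversity == MIX:
        return {AC: half, BM: half}
    raise ValueError(f"unknown diversity level {diversity!r}")


def simulate_experiment(
    design: ExperimentDesign,
    params_by_species: Mapping[str, SpeciesParams] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the tidy harvest table of one simulated experiment.

    Each pot's biomass is its deterministic trajectory value at its harvest
    day, multiplied by ``exp(block effect)`` (shared by every pot of the
    block) and ``exp(pot noise)``.  In mixture pots one pot-level draw
    scales both species components, so the emitted total row equals the sum
    of the component rows exactly.

    A seed is mandatory (reproducibility contract); it may come from the
    design or the ``seed`` argument, the argument winning.
    """
    if params_by_species is None:
        params_by_species = default_species_params()
    if noise is None:
        noise = NoiseModel()
    if seed is None:
        seed = design.seed
    if seed is None:
        raise ValueError("a RNG seed is required (pass seed= or set design.seed)")

    rng = np.random.default_rng(seed)
    block_effects = rng.normal(0.0, noise.sd_block, design.n_blocks)

    horizon = design.n_days
    trajectories: dict[tuple[str, str], pd.DataFrame] = {}
    for arm, sched in design.schedules.items():
        for diversity in design.diversity_levels:
            counts = _plant_counts(diversity, design.seeds_per_pot)
            trajectories[(arm, diversity)] = simulate_pot(
                params_by_species, counts, sched, horizon
            )

    rows: list[tuple] = []
    for arm in design.schedules:
        sched = design.schedules[arm]
        for diversity in design.diversity_levels:
            traj = trajectories[(arm, diversity)]
            for h_id, das in zip(design.harvest_ids, design.harvest_days):
                cum_water = sched.cumulative_at(das)
                for block in range(1, design.n_blocks + 1):
                    pot_eps = rng.normal(0.0, noise.cv_pot)
                    scale = math.exp(block_effects[block - 1] + pot_eps)
                    per_species = traj.loc[das] * scale
                    if diversity == MIX:
                        for sid in (AC, BM):
                            rows.append((design.experiment, block, diversity, sid,
                                         arm, h_id, das, per_species[sid], cum_water))
                    rows.append((design.experiment, block, diversity, TOTAL,
                                 arm, h_id, das, float(per_species.sum()), cum_water))

    obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    return obs
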