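"""Daily two-species competition growth model for a single pot.

The model is a discrete-day Lotka–Volterra competition update with a
saturating water-limitation response and a ramped stress multiplier for a
transient drought event:

    B_s(t+1) = B_s(t) + r_s * m_s(t) * B_s(t)
               * (1 - [B_s(t) + alpha_s * B_s'(t)] / K_s) * g_s(w_t)

with water limitation g_s(w) = w / (w + h_s) driven by the day's applied
water, and stress multiplier m_s(t) equal to ``s_event`` inside the event
window, then ramping linearly to the compensatory boost ``c_comp`` over
``tau_recovery`` days after rewatering and decaying linearly back to 1 over
the same span.  The slow/fast asymmetry of the two legumes (fast shallow
recovery vs slow but fuller recovery) is expressed entirely through
``s_event``, ``tau_recovery`` and ``c_comp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .schedules import IrrigationSchedule

AC = "AC"
BM = "BM"


@dataclass(frozen=True)
class SpeciesParams:
    """Growth, competition and drought-response parameters for one species.

    Attributes
    ----------
    species_id:
        ``"AC"`` (alsike clover) or ``"BM"`` (black medic).
    r_max:
        Intrinsic relative growth rate, day^-1.
    K:
        Per-pot carrying capacity, g dry matter.
    alpha_inter:
        Interspecific competition coefficient (1 = competitively neutral,
        <1 = niche complementarity).
    h_water:
        Half-saturation of the water-limitation response, L day^-1.
    s_event:
        Growth-rate multiplier during the drought event, in (0, 1].
    tau_recovery:
        Days for the multiplier to ramp back up after rewatering.
    c_comp:
        Post-stress compensatory growth boost (>= 1) reached at the end of
        the ramp.
    b0:
        Seedling biomass at emergence, g dry matter per plant.
    """

    species_id: str
    r_max: float
    K: float
    alpha_inter: float
    h_water: float
    s_event: float
    tau_recovery: float
    c_comp: float
    b0: float

    def __post_init__(self) -> None:
        for name in ("r_max", "K", "alpha_inter", "h_water", "s_event",
                     "tau_recovery", "c_comp", "b0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{self.species_id}: parameter {name} must be finite")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0.0 < self.s_event <= 1.0):
            raise ValueError("s_event must lie in (0, 1]")
        if self.tau_recovery < 0:
            raise ValueError("tau_recovery must be non-negative")
        if self.c_comp < 1.0:
            raise ValueError("c_comp must be >= 1")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.h_water < 0:
            raise ValueError("h_water must be non-negative")
        if self.alpha_inter < 0:
            raise ValueError("alpha_inter must be non-negative")

    def with_(self, **kwargs) -> "SpeciesParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_species_params() -> dict[str, SpeciesParams]:
    """Default parameter sets for the two legumes.

    AC (alsike clover) is parameterized as the slow-growing, drought-
    sensitive species with the higher biomass ceiling and a slow but fuller
    compensatory recovery; BM (black medic) as the fast-growing, drought-
    adapted species with quick but shallow recovery.  Values are model
    constants chosen to reproduce the qualitative contrasts between the
    species (see docs/methods.md), not fits to any dataset.
    """
    return {
        AC: SpeciesParams(
            species_id=AC, r_max=0.30, K=14.0, alpha_inter=0.70,
            h_water=0.12, s_event=0.35, tau_recovery=10.0, c_comp=2.4,
            b0=0.006,
        ),
        BM: SpeciesParams(
            species_id=BM, r_max=0.14, K=10.0, alpha_inter=0.70,
            h_water=0.06, s_event=0.60, tau_recovery=4.0, c_comp=1.10,
            b0=0.030,
        ),
    }


def stress_multiplier(params: SpeciesParams, t: int,
                      event_window: tuple[int, int] | None) -> float:
    """Growth-rate multiplier m_s(t) for day ``t``.

    1 before the event; ``s_event`` inside the inclusive event window; after
    rewatering a linear ramp from ``s_event`` up to ``c_comp`` over
    ``tau_recovery`` days, then a linear decay back to 1 over the same span.
    ``s_event == 1`` means no stress was experienced, so no compensatory
    response is triggered either.
    """
    if event_window is None or params.s_event == 1.0:
        return 1.0
    start, end = event_window
    if t < start:
        return 1.0
    if t <= end:
        return params.s_event
    tau = params.tau_recovery
    if tau == 0:
        return 1.0
    dt = t - (end + 1)
    if dt < tau:
        return params.s_event + (params.c_comp - params.s_event) * (dt / tau)
    if dt < 2 * tau:
        return params.c_comp - (params.c_comp - 1.0) * ((dt - tau) / tau)
    return 1.0


def water_limitation(w: float, h: float) -> float:
    """Saturating water response g(w) = w / (w + h); g -> 1 as h -> 0."""
    if w <= 0:
        return 0.0
    return w / (w + h)


def simulate_pot(
    params_by_species: Mapping[str, SpeciesParams],
    plant_counts: Mapping[str, int],
    schedule: IrrigationSchedule,
    n_days: int,
) -> pd.DataFrame:
    """Deterministic daily biomass trajectory of one pot.

    Parameters
    ----------
    params_by_species:
        Parameter set per species id.
    plant_counts:
        Established plants per species; a species with count 0 keeps an
        identically-zero trajectory.
    schedule:
        The pot's irrigation arm; its ``event_window`` drives the stress
        multiplier.
    n_days:
        Number of simulated days (trajectory rows 0 .. n_days-1).

    Returns
    -------
    DataFrame indexed by DAS with one biomass column (g DM pot^-1) per
    species, in the iteration order of ``params_by_species``.
    """
    species = list(params_by_species)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if n_days > schedule.n_days:
        raise ValueError(
            f"n_days {n_days} exceeds the schedule horizon {schedule.n_days}"
        )
    for sid in plant_counts:
        if sid not in params_by_species:
            raise ValueError(f"plant_counts references unknown species {sid!r}")

    counts = {sid: int(plant_counts.get(sid, 0)) for sid in species}
    biomass = np.zeros((n_days, len(species)))
    biomass[0] = [counts[sid] * params_by_species[sid].b0 for sid in species]

    water = schedule.daily_water
    window = schedule.event_window
    for t in range(n_days - 1):
        w = water[t]
        current = biomass[t]
        nxt = np.empty_like(current)
        for i, sid in enumerate(species):
            p = params_by_species[sid]
            b = current[i]
            if b == 0.0:
                nxt[i] = 0.0
                continue
            others = sum(current[j] for j in range(len(species)) if j != i)
            crowding = 1.0 - (b + p.alpha_inter * others) / p.K
            m = stress_multiplier(p, t, window)
            g = water_limitation(w, p.h_water)
            nxt[i] = max(b + p.r_max * m * b * crowding * g, 0.0)
        biomass[t + 1] = nxt

    return pd.DataFrame(biomass, index=pd.RangeIndex(n_days, name="das"),
                        columns=species)
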