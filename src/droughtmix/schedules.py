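"""Irrigation schedules for the two pot experiments.

The resistance experiment waters every pot identically for the first week,
then scales the daily replacement water (evaporation, later also
transpiration) by the target fraction of soil water-holding capacity (WHC).
The resilience experiment waters both arms identically until the drought
event starts, cuts the stressed arm to a fixed fraction of the control
during the event, and rewaters both arms equally afterwards.

Only cumulative constraints of the original trials are published (0.98 L per
pot before the event; a 33% stressed/control ratio during it), so the
default daily series are smooth constructions that satisfy those
cumulatives exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: WHC fractions used in the resistance experiment (100..25% of capacity).
RESISTANCE_WHC_LEVELS: tuple[float, ...] = (1.0, 0.85, 0.70, 0.55, 0.40, 0.25)

NON_STRESSED = "non_stressed"
STRESSED = "stressed"


@dataclass(frozen=True)
class IrrigationSchedule:
    """Daily applied water for one treatment arm, indexed by days after sowing.

    Parameters
    ----------
    arm_id:
        Treatment-arm label (e.g. ``"whc_100"`` or ``"stressed"``).
    daily_water:
        Applied water per day in L pot^-1 day^-1; index 0 is the sowing day.
    event_window:
        Inclusive ``(start, end)`` DAS interval of a drought event, or
        ``None`` when the arm experienced no event.
    whc_fraction:
        Fraction of full water-holding capacity this arm targets, in (0, 1].
    """

    arm_id: str
    daily_water: np.ndarray
    event_window: tuple[int, int] | None = None
    whc_fraction: float = 1.0

    def __post_init__(self) -> None:
        water = np.asarray(self.daily_water, dtype=float)
        if water.ndim != 1 or water.size == 0:
            raise ValueError("daily_water must be a non-empty 1-D series")
        if not np.all(np.isfinite(water)):
            raise ValueError("daily_water contains non-finite entries")
        if np.any(water < 0):
            raise ValueError("daily_water must be non-negative")
        if not (0.0 < self.whc_fraction <= 1.0):
            raise ValueError("whc_fraction must lie in (0, 1]")
        if self.event_window is not None:
            start, end = self.event_window
            if not (0 <= start <= end < water.size):
                raise ValueError("event_window must fit inside the series")
        water.setflags(write=False)
        object.__setattr__(self, "daily_water", water)

    @property
    def n_days(self) -> int:
        return int(self.daily_water.size)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative applied water through each day, inclusive (L pot^-1)."""
        return np.cumsum(self.daily_water)

    def cumulative_at(self, das: int) -> float:
        """Cumulative applied water through ``das``, inclusive."""
        if not (0 <= das < self.n_days):
            raise ValueError(f"das {das} outside schedule horizon {self.n_days}")
        return float(self.daily_water[: das + 1].sum())


def _as_series(x, n_days: int, name: str) -> np.ndarray:
    s = np.asarray(x, dtype=float)
    if s.ndim == 0:
        s = np.full(n_days, float(s))
    if s.size != n_days:
        raise ValueError(f"{name} series length {s.size} != n_days {n_days}")
    if np.any(s < 0):
        raise ValueError(f"{name} series contains negative entries")
    return s


def arm_id_for_level(level: float) -> str:
    return f"whc_{round(level * 100):d}"


def whc_fraction_from_arm(arm: str) -> float | None:
    """Parse a WHC fraction back out of a resistance arm label, else None."""
    if arm.startswith("whc_"):
        try:
            return int(arm[4:]) / 100.0
        except ValueError:
            return None
    return None


def build_resistance_schedules(
    base_evaporation,
    base_transpiration,
    levels: Sequence[float] = RESISTANCE_WHC_LEVELS,
    n_days: int = 51,
    *,
    differentiation_start: int = 7,
    transpiration_onset: int = 21,
    sowing_water: float = 0.478,
) -> dict[str, IrrigationSchedule]:
    """Build the constant-deficit schedules of the resistance experiment.

    Every level receives the same water (sowing water plus evaporation
    replacement) until ``differentiation_start``; from then on level ``f``
    receives ``f * (evaporation + transpiration)`` per day.  Transpiration
    compensation only starts at ``transpiration_onset`` (three weeks after
    sowing); any earlier entries of the supplied series are zeroed.

    Returns a dict keyed by arm id (``whc_100`` ... ``whc_25``).
    """
    allowed = set(RESISTANCE_WHC_LEVELS)
    for f in levels:
        if f not in allowed:
            raise ValueError(
                f"unknown WHC level {f!r}; allowed levels are "
                + ", ".join(f"{x:.2f}" for x in RESISTANCE_WHC_LEVELS)
            )
    evap = _as_series(base_evaporation, n_days, "evaporation")
    trans = _as_series(base_transpiration, n_days, "transpiration").copy()
    trans[:transpiration_onset] = 0.0

    days = np.arange(n_days)
    schedules: dict[str, IrrigationSchedule] = {}
    for f in levels:
        daily = np.where(days < differentiation_start, evap, f * (evap + trans))
        daily = daily.copy()
        daily[0] += sowing_water
        schedules[arm_id_for_level(f)] = IrrigationSchedule(
            arm_id=arm_id_for_level(f),
            daily_water=daily,
            event_window=None,
            whc_fraction=f,
        )
    return schedules


def default_resistance_series(
    n_days: int = 51,
    *,
    evaporation_daily: float = 0.055,
    transpiration_onset: int = 21,
    transpiration_slope: float = 0.004,
    transpiration_cap: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth default evaporation/transpiration series (L pot^-1 day^-1).

    Evaporation replacement is constant; transpiration compensation ramps
    linearly from the onset day and saturates at a cap, mimicking canopy
    closure.  Values are plausible magnitudes for ~1.5 dm^2 pots; only their
    level ratios are consequential downstream.
    """
    evap = np.full(n_days, evaporation_daily)
    days = np.arange(n_days)
    trans = np.clip(transpiration_slope * (days - transpiration_onset + 1), 0.0, transpiration_cap)
    return evap, trans


def default_resistance_schedules(n_days: int = 51, **series_kwargs) -> dict[str, IrrigationSchedule]:
    evap, trans = default_resistance_series(n_days, **series_kwargs)
    return build_resistance_schedules(evap, trans, n_days=n_days)


def build_resilience_schedules(
    pre_event_total: float = 0.98,
    event_start: int = 23,
    event_days: int = 14,
    event_fraction: float = 0.33,
    n_days: int = 73,
    post_event_daily: float = 0.09,
    *,
    sowing_water: float = 0.525,
) -> tuple[IrrigationSchedule, IrrigationSchedule]:
    """Build the (non-stressed, stressed) arm schedules of the event experiment.

    Both arms receive identical water summing exactly to ``pre_event_total``
    before ``event_start`` (front-loaded by the sowing/moistening water, the
    remainder spread evenly).  During the ``event_days``-day event the
    stressed arm receives ``event_fraction`` of the control's daily water;
    afterwards both arms are rewatered identically at ``post_event_daily``.

    ``event_fraction == 1`` is the degenerate no-drought configuration: the
    two schedules are identical and the stressed arm carries no event window.
    """
    if not (0.0 < event_fraction <= 1.0):
        raise ValueError("event_fraction must lie in (0, 1]")
    if event_start + event_days > n_days:
        raise ValueError(
            f"event window [{event_start}, {event_start + event_days - 1}] "
            f"exceeds the {n_days}-day horizon"
        )
    if not (0 < event_start):
        raise ValueError("event_start must be positive")
    if not (0.0 <= sowing_water < pre_event_total):
        raise ValueError("sowing_water must be smaller than pre_event_total")

    ns = np.full(n_days, float(post_event_daily))
    ns[0] = sowing_water
    # days 1 .. event_start-1 share the pre-event remainder equally
    ns[1:event_start] = (pre_event_total - sowing_water) / (event_start - 1)

    stressed = ns.copy()
    window: tuple[int, int] | None = None
    if event_fraction < 1.0:
        window = (event_start, event_start + event_days - 1)
        stressed[event_start : event_start + event_days] *= event_fraction

    non_stressed_sched = IrrigationSchedule(NON_STRESSED, ns, event_window=None)
    stressed_sched = IrrigationSchedule(STRESSED, stressed, event_window=window)
    return non_stressed_sched, stressed_sched
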