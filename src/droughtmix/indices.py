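"""Index calculus for mixture pot experiments.

Scalar formulas:

* water use efficiency        WUE = b / w              (g DM L^-1)
* crop growth rate            CGR = (b_i - b_{i-1}) / [A (t_i - t_{i-1})]
* land equivalent ratio       LER = b_ACmix/b_ACmono + b_BMmix/b_BMmono
* absolute mixture effect     AME = y_mix - (y_AC + y_BM) / 2
* relative change under stress  100 * (y_stressed / y_non_stressed - 1)  (%)
* resilience index            r = 2|D0| / (|D0| + |Dx|) - 1, in [-1, 1]

plus tidy-table versions operating on the harvest schema of
:mod:`droughtmix.generate`.  Undefined values (zero denominators) are never
emitted as silent numbers: the table layer flags them with a reason code,
the scalar layer raises.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .generate import AC_MONO, BM_MONO, MIX, OBS_COLUMNS, TOTAL
from .growth import AC, BM

log = logging.getLogger(__name__)

FLAG_NONPOS_MONO = "nonpositive_monoculture"
FLAG_D0_ZERO = "d0_zero"
FLAG_NONPOS_BASELINE = "nonpositive_baseline"


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def wue(b: float, w: float) -> float:
    """Water use efficiency b/w in g DM per litre of cumulative water."""
    if w <= 0:
        raise ValueError(f"cumulative water must be positive, got {w} (b/w would divide by zero)")
    if b < 0:
        raise ValueError("biomass must be non-negative")
    return b / w


def cgr(b_i: float, b_prev: float, t_i: float, t_prev: float, area: float) -> float:
    """Crop growth rate between two harvests, g m^-2 day^-1.

    Negative values are permitted (net biomass loss over the interval).
    """
    if t_i <= t_prev:
        raise ValueError(f"harvest times must be increasing (t_prev={t_prev}, t_i={t_i})")
    if area <= 0:
        raise ValueError("pot ground area must be positive")
    if b_i < 0 or b_prev < 0:
        raise ValueError("biomass must be non-negative")
    return (b_i - b_prev) / (area * (t_i - t_prev))


@dataclass(frozen=True)
class LerRecord:
    """Partial LERs and their sum for one mixture/monoculture triple."""

    pler_ac: float
    pler_bm: float
    ler: float
    cell: tuple | None = None
    flag: str | None = None


def ler(b_ac_mix: float, b_ac_mono: float, b_bm_mix: float, b_bm_mono: float,
        cell: tuple | None = None) -> LerRecord:
    """Land equivalent ratio record; flagged-undefined on a non-positive monoculture."""
    if b_ac_mono <= 0 or b_bm_mono <= 0:
        warnings.warn(
            "non-positive monoculture biomass: LER undefined for this cell",
            stacklevel=2,
        )
        return LerRecord(np.nan, np.nan, np.nan, cell=cell, flag=FLAG_NONPOS_MONO)
    pler_ac = b_ac_mix / b_ac_mono
    pler_bm = b_bm_mix / b_bm_mono
    return LerRecord(pler_ac, pler_bm, pler_ac + pler_bm, cell=cell)


def ame(y_mix: float, y_ac: float, y_bm: float) -> float:
    """Absolute mixture effect: mixture value minus the monoculture average."""
    return y_mix - (y_ac + y_bm) / 2.0


def relative_change(y_stressed: float, y_non_stressed: float) -> float:
    """Percent change of a variable under stress relative to the control."""
    if y_non_stressed <= 0:
        raise ValueError("non-stressed reference must be positive")
    return 100.0 * (y_stressed / y_non_stressed - 1.0)


def resilience(d0, dx):
    """Resilience index r = 2|D0| / (|D0| + |Dx|) - 1.

    D0 is the control-minus-stressed difference at the end of the drought
    event, Dx the same difference at a later recovery harvest.  The index is
    bounded in [-1, 1] with full recovery at +1; it is undefined for D0 = 0
    (nothing to recover from) and raises in that case.  Accepts scalars or
    arrays (broadcast elementwise).
    """
    d0_arr = np.asarray(d0, dtype=float)
    dx_arr = np.asarray(dx, dtype=float)
    if np.any(d0_arr == 0):
        raise ValueError("resilience undefined for D0 = 0 (no initial drought impact)")
    r = 2.0 * np.abs(d0_arr) / (np.abs(d0_arr) + np.abs(dx_arr)) - 1.0
    if r.ndim == 0 and np.ndim(d0) == 0 and np.ndim(dx) == 0:
        return float(r)
    return r


# ---------------------------------------------------------------------------
# tidy-table operations
# ---------------------------------------------------------------------------

def check_schema(obs: pd.DataFrame) -> None:
    """Validate the tidy harvest-table schema, raising with a column diff."""
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    extra = [c for c in obs.columns if c not in OBS_COLUMNS]
    if missing or extra:
        raise ValueError(
            "observation table does not match the expected schema; "
            f"missing columns: {missing or 'none'}; unexpected columns: {extra or 'none'}"
        )
    if obs.empty:
        raise ValueError("observation table is empty")


def totals(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-pot total rows with a derived per-pot WUE column."""
    t = obs[obs["component"] == TOTAL].copy()
    t["wue"] = t["biomass_g"] / t["cum_water_l"]
    return t


def cell_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Treatment-mean biomass and water per design cell and component."""
    keys = ["arm", "harvest", "das", "diversity", "component"]
    g = obs.groupby(keys, sort=True, as_index=False).agg(
        biomass_g=("biomass_g", "mean"),
        cum_water_l=("cum_water_l", "mean"),
        n=("biomass_g", "size"),
    )
    return g


def _component_biomass(obs: pd.DataFrame, diversity: str, component: str,
                       value_name: str) -> pd.DataFrame:
    sub = obs[(obs["diversity"] == diversity) & (obs["component"] == component)]
    return sub[["arm", "harvest", "block", "biomass_g"]].rename(
        columns={"biomass_g": value_name}
    )


def ler_table(obs: pd.DataFrame, mode: str = "paired") -> pd.DataFrame:
    """Partial and total land equivalent ratios per design cell.

    ``mode="paired"`` computes one record per block (mixture components and
    monocultures paired within block), the basis for replicate-level tests;
    ``mode="mean"`` computes a single record per cell from treatment means.
    """
    check_schema(obs)
    parts = [
        _component_biomass(obs, MIX, AC, "b_ac_mix"),
        _component_biomass(obs, AC_MONO, TOTAL, "b_ac_mono"),
        _component_biomass(obs, MIX, BM, "b_bm_mix"),
        _component_biomass(obs, BM_MONO, TOTAL, "b_bm_mono"),
    ]
    keys = ["arm", "harvest", "block"]
    merged = parts[0]
    for p in parts[1:]:
        merged = merged.merge(p, on=keys, how="inner")
    if mode == "mean":
        merged = merged.groupby(["arm", "harvest"], as_index=False).mean(numeric_only=True)
        merged = merged.drop(columns=["block"])
        keys = ["arm", "harvest"]
    elif mode != "paired":
        raise ValueError("mode must be 'paired' or 'mean'")

    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, row in merged.iterrows():
            rec = ler(row["b_ac_mix"], row["b_ac_mono"], row["b_bm_mix"], row["b_bm_mono"])
            records.append((rec.pler_ac, rec.pler_bm, rec.ler, rec.flag))
    out = merged[keys].copy()
    out[["pler_ac", "pler_bm", "ler", "flag"]] = pd.DataFrame(records, index=merged.index)
    n_flagged = out["flag"].notna().sum()
    if n_flagged:
        log.warning("%d LER cells flagged undefined (non-positive monoculture)", n_flagged)
    return out


def _pot_values(obs: pd.DataFrame, variable: str) -> pd.DataFrame:
    t = totals(obs)
    if variable == "biomass":
        t = t.rename(columns={"biomass_g": "value"})
    elif variable == "wue":
        t = t.rename(columns={"wue": "value"})
    else:
        raise ValueError("variable must be 'biomass' or 'wue'")
    return t[["arm", "harvest", "block", "diversity", "value"]]


def ame_table(obs: pd.DataFrame, variable: str = "biomass",
              mode: str = "paired") -> pd.DataFrame:
    """Absolute mixture effect of a per-pot variable per design cell."""
    check_schema(obs)
    vals = _pot_values(obs, variable)
    wide = vals.pivot_table(index=["arm", "harvest", "block"],
                            columns="diversity", values="value")
    for needed in (AC_MONO, BM_MONO, MIX):
        if needed not in wide.columns:
            raise ValueError(f"diversity level {needed!r} absent from the table")
    wide = wide.reset_index()
    if mode == "mean":
        wide = wide.groupby(["arm", "harvest"], as_index=False).mean(numeric_only=True)
        wide = wide.drop(columns=["block"])
        keys = ["arm", "harvest"]
    elif mode == "paired":
        keys = ["arm", "harvest", "block"]
    else:
        raise ValueError("mode must be 'paired' or 'mean'")
    out = wide[keys].copy()
    out["variable"] = variable
    out["ame"] = wide[MIX] - (wide[AC_MONO] + wide[BM_MONO]) / 2.0
    return out


def cgr_table(obs: pd.DataFrame, area: float, mode: str = "mean") -> pd.DataFrame:
    """Crop growth rate between consecutive harvests, per arm and diversity.

    ``mode="mean"`` (default) applies the rate formula to treatment means;
    ``mode="paired"`` applies it per block, pairing each block's pots across
    the two harvests of the interval.  A single-harvest table yields an
    empty result (no interval exists) and logs why.
    """
    check_schema(obs)
    t = totals(obs)
    if t["das"].nunique() < 2:
        log.info("CGR not applicable: table has a single harvest time")
        cols = ["arm", "diversity", "harvest", "das_prev", "das", "cgr"]
        if mode == "paired":
            cols.insert(2, "block")
        return pd.DataFrame(columns=cols)

    group_keys = ["arm", "diversity"] + (["block"] if mode == "paired" else [])
    if mode == "mean":
        t = t.groupby(group_keys + ["harvest", "das"], as_index=False)["biomass_g"].mean()
    elif mode != "paired":
        raise ValueError("mode must be 'paired' or 'mean'")

    rows = []
    for keys, sub in t.groupby(group_keys):
        sub = sub.sort_values("das")
        das = sub["das"].to_numpy()
        b = sub["biomass_g"].to_numpy()
        hid = sub["harvest"].to_numpy()
        for i in range(1, len(sub)):
            rows.append((*keys, hid[i], das[i - 1], das[i],
                         cgr(b[i], b[i - 1], das[i], das[i - 1], area)))
    return pd.DataFrame(rows, columns=group_keys + ["harvest", "das_prev", "das", "cgr"])


def relative_change_table(obs: pd.DataFrame, variable: str,
                          stressed_arm: str, baseline_arm: str) -> pd.DataFrame:
    """Percent change of a cell-mean variable between two arms, per diversity/harvest."""
    check_schema(obs)
    vals = _pot_values(obs, variable)
    means = vals.groupby(["arm", "harvest", "diversity"], as_index=False)["value"].mean()
    s = means[means["arm"] == stressed_arm].rename(columns={"value": "y_stressed"})
    b = means[means["arm"] == baseline_arm].rename(columns={"value": "y_baseline"})
    merged = s.drop(columns="arm").merge(b.drop(columns="arm"),
                                         on=["harvest", "diversity"])
    out_rows = []
    for _, row in merged.iterrows():
        if row["y_baseline"] <= 0:
            out_rows.append((np.nan, FLAG_NONPOS_BASELINE))
        else:
            out_rows.append((relative_change(row["y_stressed"], row["y_baseline"]), None))
    merged["variable"] = variable
    merged[["change_pct", "flag"]] = pd.DataFrame(out_rows, index=merged.index)
    return merged[["harvest", "diversity", "variable", "y_stressed", "y_baseline",
                   "change_pct", "flag"]]


def resilience_table(obs: pd.DataFrame, mode: str = "paired",
                     d0_harvest: str = "H2",
                     recovery_harvests: Sequence[str] = ("H3", "H4", "H5"),
                     non_stressed_arm: str = "non_stressed",
                     stressed_arm: str = "stressed") -> pd.DataFrame:
    """Resilience index per diversity level at each recovery harvest.

    D0 is the non-stressed minus stressed total-biomass difference at
    ``d0_harvest`` (the end of the drought event), Dx the same difference at
    each recovery harvest; both are kept signed alongside the index.  In
    ``paired`` mode differences are taken within block; in ``mean`` mode on
    cell means.  Cells with D0 = 0 are flagged undefined, never given a
    numeric index.
    """
    check_schema(obs)
    t = totals(obs)
    have = set(t["harvest"].unique())
    if d0_harvest not in have:
        raise ValueError(
            f"harvest {d0_harvest!r} absent: D0 undefined, resilience stage aborted"
        )
    keys = ["diversity"] + (["block"] if mode == "paired" else [])
    if mode == "mean":
        t = t.groupby(["arm", "harvest", "diversity"], as_index=False)["biomass_g"].mean()
    elif mode != "paired":
        raise ValueError("mode must be 'paired' or 'mean'")

    def _diff(harvest: str) -> pd.DataFrame:
        sub = t[t["harvest"] == harvest]
        ns = sub[sub["arm"] == non_stressed_arm].set_index(keys)["biomass_g"]
        s = sub[sub["arm"] == stressed_arm].set_index(keys)["biomass_g"]
        return (ns - s).rename("diff").reset_index()

    d0 = _diff(d0_harvest).rename(columns={"diff": "d0"})
    rows = []
    for hx in recovery_harvests:
        if hx not in have:
            log.warning("recovery harvest %s absent: skipped", hx)
            continue
        dx = _diff(hx).rename(columns={"diff": "dx"})
        merged = d0.merge(dx, on=keys)
        for _, row in merged.iterrows():
            if row["d0"] == 0:
                r_val, flag = np.nan, FLAG_D0_ZERO
            else:
                r_val, flag = resilience(row["d0"], row["dx"]), None
            rows.append((*[row[k] for k in keys], hx, row["d0"], row["dx"], r_val, flag))
    return pd.DataFrame(rows, columns=keys + ["harvest", "d0", "dx", "r", "flag"])


def table_indices(obs: pd.DataFrame, pot_area: float) -> dict[str, pd.DataFrame]:
    """All index tables derivable from one harvest table, keyed by name."""
    check_schema(obs)
    out = {
        "cell_means": cell_means(obs),
        "ler": ler_table(obs, mode="mean"),
        "ame_biomass": ame_table(obs, "biomass", mode="mean"),
        "ame_wue": ame_table(obs, "wue", mode="mean"),
        "cgr": cgr_table(obs, pot_area, mode="mean"),
    }
    return out
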