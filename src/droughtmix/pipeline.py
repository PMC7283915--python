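"""End-to-end analyses of the two experiments.

``analyze_resistance`` reduces a constant-drought harvest table to
per-WHC-level treatment means with Tukey letters (biomass and WUE), block-
paired LER and AME with tests against 1 and 0, correlations of LER and AME
with drought intensity, and the percent reduction between the extreme and
the full irrigation level.

``analyze_resilience`` reduces a drought-event table to per-arm,
per-harvest means and letters (biomass, WUE, CGR), LER and AME
trajectories with their tests, percent-change trajectories between arms,
and the resilience index (block-paired D0 at the end of the event, Dx at
each recovery harvest) with tests against 0, plus the mixture effect on
resilience itself.

``run_report`` wires a config plus observation CSV to tidy CSV outputs, a
plain-text summary and optional figures.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices as idx
from .generate import (
    AC_MONO, BM_MONO, DIVERSITY_LEVELS, MIX,
    ROUND_POT_AREA_M2, SQUARE_POT_AREA_M2,
)
from .schedules import NON_STRESSED, STRESSED, whc_fraction_from_arm
from .stats import TestResult, oneway_tukey, pearson, welch_vs_ref

log = logging.getLogger(__name__)

_PCT_COLS = ("change_pct",)
_INDEX_COLS = ("ler", "pler_ac", "pler_bm", "r", "ame")


def _test_row(res: TestResult) -> dict:
    return {
        "estimate": res.estimate, "statistic": res.statistic, "df": res.df,
        "p_value": res.p_value, "reference": res.reference, "flag": res.flag,
    }


def _tukey_summary(obs: pd.DataFrame, variable: str, by: list[str]) -> pd.DataFrame:
    """Per-cell diversity means, Tukey letters and the omnibus F/p."""
    vals = idx._pot_values(obs, variable)
    rows = []
    for keys, sub in vals.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        groups = {d: s["value"].to_numpy() for d, s in sub.groupby("diversity")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova, grouping = oneway_tukey(groups)
        for div in sorted(groups):
            rows.append((*keys, variable, div, len(groups[div]),
                         grouping.level_means[div], grouping.letters[div],
                         anova.statistic, anova.p_value, anova.flag))
    return pd.DataFrame(
        rows, columns=by + ["variable", "diversity", "n", "mean", "letter",
                            "anova_F", "anova_p", "anova_flag"])


def _welch_by_cell(table: pd.DataFrame, value_col: str, by: list[str],
                   reference: float) -> pd.DataFrame:
    rows = []
    for keys, sub in table.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        res = welch_vs_ref(sub[value_col].to_numpy(), reference)
        rows.append({**dict(zip(by, keys)), **_test_row(res)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# resistance
# ---------------------------------------------------------------------------

@dataclass
class ResistanceReport:
    """Result tables of the constant-drought analysis."""

    cell_summary: pd.DataFrame
    ler: pd.DataFrame
    ler_tests: pd.DataFrame
    ame_tests: pd.DataFrame
    correlations: pd.DataFrame
    relative_change: pd.DataFrame
    aborted_stages: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "cell_summary": self.cell_summary,
            "ler": self.ler,
            "ler_tests": self.ler_tests,
            "ame_tests": self.ame_tests,
            "correlations": self.correlations,
            "relative_change": self.relative_change,
        }


def _require_experiment(obs: pd.DataFrame, label: str) -> None:
    idx.check_schema(obs)
    found = set(obs["experiment"].unique())
    if found != {label}:
        raise ValueError(
            f"expected a table from a {label!r} run, found experiment labels {sorted(found)}"
        )


def analyze_resistance(obs: pd.DataFrame) -> ResistanceReport:
    """Full analysis of a resistance (constant cumulative drought) table."""
    _require_experiment(obs, "resistance")
    if obs["harvest"].nunique() != 1:
        raise ValueError("a resistance table must contain a single harvest")

    arms = sorted(obs["arm"].unique())
    expected = 6
    if len(arms) < expected:
        log.warning("only %d WHC levels present (expected %d); proceeding", len(arms), expected)

    cell_summary = pd.concat(
        [_tukey_summary(obs, v, ["arm"]) for v in ("biomass", "wue")],
        ignore_index=True,
    )

    ler_paired = idx.ler_table(obs, mode="paired")
    ler_mean = idx.ler_table(obs, mode="mean")
    ler_tests = _welch_by_cell(ler_paired.dropna(subset=["ler"]), "ler", ["arm"], 1.0)

    ame_frames = []
    for variable in ("biomass", "wue"):
        paired = idx.ame_table(obs, variable, mode="paired")
        tests = _welch_by_cell(paired, "ame", ["arm"], 0.0)
        tests.insert(1, "variable", variable)
        ame_frames.append(tests)
    ame_tests = pd.concat(ame_frames, ignore_index=True)

    # correlations of LER / AME(biomass) with drought intensity (WHC fraction)
    fractions = {arm: whc_fraction_from_arm(arm) for arm in arms}
    corr_rows = []
    usable = [a for a in arms if fractions[a] is not None]
    for name, table, col in (
        ("ler", ler_mean, "ler"),
        ("ame_biomass", idx.ame_table(obs, "biomass", mode="mean"), "ame"),
    ):
        sub = table[table["arm"].isin(usable)]
        x = np.array([fractions[a] for a in sub["arm"]])
        y = sub[col].to_numpy()
        if len(x) < 3:
            log.warning("correlation %s skipped: fewer than 3 WHC levels", name)
            corr_rows.append({"variable": name, **_test_row(
                TestResult("pearson", np.nan, np.nan, np.nan, np.nan, flag="too_few_levels"))})
            continue
        corr_rows.append({"variable": name, **_test_row(pearson(x, y))})
    correlations = pd.DataFrame(corr_rows)

    # percent reduction at the most extreme drought level vs full irrigation
    defined = {a: f for a, f in fractions.items() if f is not None}
    if len(defined) >= 2:
        low = min(defined, key=defined.get)
        high = max(defined, key=defined.get)
        relative_change = pd.concat(
            [idx.relative_change_table(obs, v, stressed_arm=low, baseline_arm=high)
             for v in ("biomass", "wue")],
            ignore_index=True,
        )
        relative_change.insert(0, "low_arm", low)
        relative_change.insert(1, "high_arm", high)
    else:
        relative_change = pd.DataFrame()

    return ResistanceReport(cell_summary, ler_mean, ler_tests, ame_tests,
                            correlations, relative_change)


# ---------------------------------------------------------------------------
# resilience
# ---------------------------------------------------------------------------

@dataclass
class ResilienceReport:
    """Result tables of the drought-event analysis."""

    cell_summary: pd.DataFrame
    cgr: pd.DataFrame
    cgr_summary: pd.DataFrame
    ler: pd.DataFrame
    ler_tests: pd.DataFrame
    ame_tests: pd.DataFrame
    relative_change: pd.DataFrame
    resilience: pd.DataFrame
    resilience_tests: pd.DataFrame
    resilience_ame_tests: pd.DataFrame
    aborted_stages: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "cell_summary": self.cell_summary,
            "cgr": self.cgr,
            "cgr_summary": self.cgr_summary,
            "ler": self.ler,
            "ler_tests": self.ler_tests,
            "ame_tests": self.ame_tests,
            "relative_change": self.relative_change,
            "resilience": self.resilience,
            "resilience_tests": self.resilience_tests,
            "resilience_ame_tests": self.resilience_ame_tests,
        }


def _cgr_tukey(cgr_paired: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (arm, harvest), sub in cgr_paired.groupby(["arm", "harvest"]):
        groups = {d: s["cgr"].to_numpy() for d, s in sub.groupby("diversity")}
        if len(groups) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova, grouping = oneway_tukey(groups)
        for div in sorted(groups):
            rows.append((arm, harvest, "cgr", div, len(groups[div]),
                         grouping.level_means[div], grouping.letters[div],
                         anova.statistic, anova.p_value, anova.flag))
    return pd.DataFrame(rows, columns=["arm", "harvest", "variable", "diversity",
                                       "n", "mean", "letter", "anova_F",
                                       "anova_p", "anova_flag"])


def analyze_resilience(obs: pd.DataFrame,
                       pot_area: float = ROUND_POT_AREA_M2) -> ResilienceReport:
    """Full analysis of a resilience (transient drought event) table."""
    _require_experiment(obs, "resilience")
    arms = set(obs["arm"].unique())
    if not {NON_STRESSED, STRESSED} <= arms:
        raise ValueError(
            f"a resilience table needs arms {NON_STRESSED!r} and {STRESSED!r}; found {sorted(arms)}"
        )
    aborted: list = []

    cell_summary = pd.concat(
        [_tukey_summary(obs, v, ["arm", "harvest"]) for v in ("biomass", "wue")],
        ignore_index=True,
    )

    cgr_mean = idx.cgr_table(obs, pot_area, mode="mean")
    cgr_paired = idx.cgr_table(obs, pot_area, mode="paired")
    cgr_summary = _cgr_tukey(cgr_paired)

    ler_paired = idx.ler_table(obs, mode="paired")
    ler_mean = idx.ler_table(obs, mode="mean")
    ler_tests = _welch_by_cell(ler_paired.dropna(subset=["ler"]), "ler",
                               ["arm", "harvest"], 1.0)

    ame_frames = []
    for variable in ("biomass", "wue"):
        paired = idx.ame_table(obs, variable, mode="paired")
        tests = _welch_by_cell(paired, "ame", ["arm", "harvest"], 0.0)
        tests.insert(2, "variable", variable)
        ame_frames.append(tests)
    # mixture effect on block-level CGR per interval
    if not cgr_paired.empty:
        wide = cgr_paired.pivot_table(index=["arm", "harvest", "block"],
                                      columns="diversity", values="cgr").reset_index()
        if {AC_MONO, BM_MONO, MIX} <= set(wide.columns):
            wide["ame"] = wide[MIX] - (wide[AC_MONO] + wide[BM_MONO]) / 2.0
            tests = _welch_by_cell(wide, "ame", ["arm", "harvest"], 0.0)
            tests.insert(2, "variable", "cgr")
            ame_frames.append(tests)
    ame_tests = pd.concat(ame_frames, ignore_index=True)

    # percent change between arms, per diversity and harvest
    change_frames = [
        idx.relative_change_table(obs, v, stressed_arm=STRESSED, baseline_arm=NON_STRESSED)
        for v in ("biomass", "wue")
    ]
    if not cgr_mean.empty:
        s = cgr_mean[cgr_mean["arm"] == STRESSED]
        b = cgr_mean[cgr_mean["arm"] == NON_STRESSED]
        merged = s.merge(b, on=["diversity", "harvest", "das_prev", "das"],
                         suffixes=("_stressed", "_baseline"))
        vals = []
        for _, row in merged.iterrows():
            if row["cgr_baseline"] <= 0:
                vals.append((np.nan, idx.FLAG_NONPOS_BASELINE))
            else:
                vals.append((idx.relative_change(row["cgr_stressed"], row["cgr_baseline"]), None))
        merged["variable"] = "cgr"
        merged[["change_pct", "flag"]] = pd.DataFrame(vals, index=merged.index)
        change_frames.append(
            merged.rename(columns={"cgr_stressed": "y_stressed",
                                   "cgr_baseline": "y_baseline"})[
                ["harvest", "diversity", "variable", "y_stressed", "y_baseline",
                 "change_pct", "flag"]]
        )
    relative_change = pd.concat(change_frames, ignore_index=True)

    # resilience index: block-paired D0 at H2, Dx at recovery harvests
    try:
        res_paired = idx.resilience_table(obs, mode="paired")
    except ValueError as exc:
        log.error("resilience stage aborted: %s", exc)
        aborted.append(f"resilience: {exc}")
        empty = pd.DataFrame()
        return ResilienceReport(cell_summary, cgr_mean, cgr_summary, ler_mean,
                                ler_tests, ame_tests, relative_change,
                                empty, empty, empty, aborted)

    defined = res_paired.dropna(subset=["r"])
    resilience_tests = (
        _welch_by_cell(defined, "r", ["diversity", "harvest"], 0.0)
        if not defined.empty else pd.DataFrame()
    )

    res_ame_frames = []
    if not defined.empty:
        wide = defined.pivot_table(index=["harvest", "block"],
                                   columns="diversity", values="r").reset_index()
        if {AC_MONO, BM_MONO, MIX} <= set(wide.columns):
            wide["ame"] = wide[MIX] - (wide[AC_MONO] + wide[BM_MONO]) / 2.0
            res_ame_frames.append(_welch_by_cell(wide, "ame", ["harvest"], 0.0))
    resilience_ame_tests = (pd.concat(res_ame_frames, ignore_index=True)
                            if res_ame_frames else pd.DataFrame())

    return ResilienceReport(cell_summary, cgr_mean, cgr_summary, ler_mean,
                            ler_tests, ame_tests, relative_change,
                            res_paired, resilience_tests, resilience_ame_tests,
                            aborted)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if col in _PCT_COLS:
            out[col] = out[col].round(1)
        elif col in _INDEX_COLS or col == "estimate":
            out[col] = out[col].round(3)
        else:
            out[col] = out[col].round(6)
    return out


def write_report(report, out_dir: str | Path, prefix: str = "") -> list[Path]:
    """Serialize every report table to tidy CSV; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.tables().items():
        path = out / f"{prefix}{name}.csv"
        _rounded(table).to_csv(path, index=False)
        written.append(path)
    return written


def _summary_text(experiment: str, report) -> str:
    lines = [f"experiment: {experiment}"]
    for name, table in report.tables().items():
        lines.append(f"{name}: {len(table)} rows")
    if report.aborted_stages:
        lines.append("aborted stages:")
        lines.extend(f"  - {msg}" for msg in report.aborted_stages)
    return "\n".join(lines) + "\n"


def _figures(experiment: str, obs: pd.DataFrame, report, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = idx.cell_means(obs)
    tot = means[means["component"] == "total"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for (arm, div), sub in tot.groupby(["arm", "diversity"]):
        sub = sub.sort_values("das")
        x = sub["das"] if experiment == "resilience" else [whc_fraction_from_arm(arm)] * len(sub)
        ax.plot(x, sub["biomass_g"], marker="o", label=f"{div} / {arm}")
    ax.set_xlabel("DAS" if experiment == "resilience" else "WHC fraction")
    ax.set_ylabel("biomass (g DM pot$^{-1}$)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_dir / "biomass.png", dpi=120)
    plt.close(fig)

    ler_tab = report.ler
    if not ler_tab.empty:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(ler_tab["pler_bm"], ler_tab["pler_ac"])
        lim = max(1.0, ler_tab[["pler_ac", "pler_bm"]].max().max() * 1.1)
        ax.plot([0, 1], [1, 0], color="gray")  # LER = 1 line
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel("PLER$_{BM}$")
        ax.set_ylabel("PLER$_{AC}$")
        fig.tight_layout()
        fig.savefig(out_dir / "pler.png", dpi=120)
        plt.close(fig)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a tidy harvest CSV."""
    obs = pd.read_csv(path)
    idx.check_schema(obs)
    return obs


def run_report(config: str | Path | None, obs_path: str | Path,
               out_dir: str | Path, experiment: str | None = None,
               figures: bool = False) -> int:
    """Run the analysis named by the config on a harvest CSV.

    Writes tidy CSV tables and a plain-text summary into ``out_dir``;
    returns a nonzero exit status if any stage aborted.
    """
    from .config import load_config

    t0 = time.perf_counter()
    cfg = load_config(config, experiment=experiment)
    exp = cfg["experiment"]
    obs = read_observations(obs_path)
    log.info("loaded %d observation rows (%.2fs)", len(obs), time.perf_counter() - t0)

    t1 = time.perf_counter()
    if exp == "resistance":
        report = analyze_resistance(obs)
    else:
        report = analyze_resilience(obs)
    log.info("analysis stage done (%.2fs)", time.perf_counter() - t1)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report(report, out)
    (out / "summary.txt").write_text(_summary_text(exp, report), encoding="utf-8")
    if figures:
        _figures(exp, obs, report, out)
    log.info("report written to %s (total %.2fs)", out, time.perf_counter() - t0)
    return 1 if report.aborted_stages else 0
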