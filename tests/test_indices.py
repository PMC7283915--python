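"""Index formulas: worked examples, algebraic properties, table oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtmix import indices as idx
from droughtmix.generate import ROUND_POT_AREA_M2

finite = st.floats(allow_nan=False, allow_infinity=False)
positive = st.floats(min_value=1e-6, max_value=1e6)
biomass = st.floats(min_value=0.0, max_value=1e6)


class TestWue:
    def test_examples(self):
        assert idx.wue(0.0, 1.5) == 0.0
        assert idx.wue(2.5, 1.25) == pytest.approx(2.0)

    def test_zero_water_rejected(self):
        with pytest.raises(ValueError, match="divide by zero|positive"):
            idx.wue(1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(b=biomass, w=positive, k=positive)
    def test_scale_invariance(self, b, w, k):
        assert idx.wue(k * b, k * w) == pytest.approx(idx.wue(b, w), rel=1e-9)


class TestCgr:
    def test_worked_example(self):
        """2 g gained over the 37->44 DAS week in a round pot."""
        assert idx.cgr(3.0, 1.0, 44, 37, 0.011310) == pytest.approx(25.26, abs=0.01)

    def test_no_growth_and_loss(self):
        assert idx.cgr(2.0, 2.0, 44, 37, ROUND_POT_AREA_M2) == 0.0
        assert idx.cgr(1.0, 2.0, 44, 37, ROUND_POT_AREA_M2) < 0

    def test_time_translation_and_area_linearity(self):
        a = idx.cgr(3.0, 1.0, 44, 37, 0.01)
        assert idx.cgr(3.0, 1.0, 144, 137, 0.01) == pytest.approx(a)
        assert idx.cgr(3.0, 1.0, 44, 37, 0.02) == pytest.approx(a / 2)

    @pytest.mark.parametrize("kwargs", [
        dict(t_i=37, t_prev=44, area=0.01),
        dict(t_i=44, t_prev=44, area=0.01),
        dict(t_i=44, t_prev=37, area=0.0),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            idx.cgr(3.0, 1.0, **kwargs)


class TestLer:
    def test_balanced_example_gives_unit_ler(self):
        rec = idx.ler(1, 2, 2, 4)
        assert rec.pler_ac == pytest.approx(0.5)
        assert rec.pler_bm == pytest.approx(0.5)
        assert rec.ler == pytest.approx(1.0)

    def test_full_yield_of_both(self):
        assert idx.ler(2, 2, 4, 4).ler == pytest.approx(2.0)

    def test_one_species_absent(self):
        rec = idx.ler(0, 2, 2, 4)
        assert rec.pler_ac == 0.0
        assert rec.ler == pytest.approx(0.5)

    def test_zero_monoculture_flagged_not_silent(self):
        with pytest.warns(UserWarning, match="monoculture"):
            rec = idx.ler(1.0, 0.0, 2.0, 4.0)
        assert rec.flag == idx.FLAG_NONPOS_MONO
        assert np.isnan(rec.ler)

    @settings(derandomize=True, max_examples=100)
    @given(b_ac_mix=biomass, b_ac_mono=positive, b_bm_mix=biomass, b_bm_mono=positive)
    def test_additivity_exact(self, b_ac_mix, b_ac_mono, b_bm_mix, b_bm_mono):
        rec = idx.ler(b_ac_mix, b_ac_mono, b_bm_mix, b_bm_mono)
        assert rec.ler == rec.pler_ac + rec.pler_bm
        assert rec.pler_ac >= 0 and rec.pler_bm >= 0


class TestAmeAndChange:
    @pytest.mark.parametrize("args, expected", [
        ((2.0, 2.0, 2.0), 0.0),
        ((3.0, 2.0, 2.0), 1.0),
        ((1.0, 2.0, 4.0), -2.0),
    ])
    def test_ame_examples(self, args, expected):
        assert idx.ame(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("args, expected", [
        ((2.0, 2.0), 0.0),
        ((0.0, 2.0), -100.0),
        ((0.5, 2.0), -75.0),
    ])
    def test_relative_change_examples(self, args, expected):
        assert idx.relative_change(*args) == pytest.approx(expected)

    def test_relative_change_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            idx.relative_change(1.0, 0.0)


class TestResilienceIndex:
    def test_worked_examples(self):
        assert idx.resilience(1.0, 0.0) == 1.0
        assert idx.resilience(1.0, 1.0) == pytest.approx(0.0)
        assert idx.resilience(1.0, 3.0) == pytest.approx(-0.5)

    def test_d0_zero_rejected(self):
        with pytest.raises(ValueError, match="D0"):
            idx.resilience(0.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(d0=st.floats(min_value=1e-6, max_value=1e6),
           dx=st.floats(min_value=-1e6, max_value=1e6),
           c=st.floats(min_value=1e-3, max_value=1e3),
           sign=st.sampled_from([-1.0, 1.0]))
    def test_bounds_and_scale_invariance(self, d0, dx, c, sign):
        r = idx.resilience(sign * d0, dx)
        assert -1.0 <= r <= 1.0
        assert idx.resilience(sign * c * d0, c * dx) == pytest.approx(r, abs=1e-9)

    def test_monotone_decreasing_in_abs_dx(self):
        dx = np.linspace(0, 50, 200)
        r = idx.resilience(np.full_like(dx, 2.0), dx)
        assert np.all(np.diff(r) <= 0)


def _random_obs(seed=0, n_blocks=4):
    """Small random tidy table with the full component structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ("whc_100", "whc_25"):
        for block in range(1, n_blocks + 1):
            b_ac_mono = rng.uniform(1, 5)
            b_bm_mono = rng.uniform(1, 5)
            b_ac_mix = rng.uniform(0.5, 3)
            b_bm_mix = rng.uniform(0.5, 3)
            w = rng.uniform(2, 4)
            rows += [
                ("resistance", block, "AC_mono", "total", arm, "H1", 50, b_ac_mono, w),
                ("resistance", block, "BM_mono", "total", arm, "H1", 50, b_bm_mono, w),
                ("resistance", block, "MIX", "AC", arm, "H1", 50, b_ac_mix, w),
                ("resistance", block, "MIX", "BM", arm, "H1", 50, b_bm_mix, w),
                ("resistance", block, "MIX", "total", arm, "H1", 50, b_ac_mix + b_bm_mix, w),
            ]
    return pd.DataFrame(rows, columns=list(idx.OBS_COLUMNS))


class TestTableOperations:
    def test_ler_table_matches_naive_loop(self):
        """Block-paired LER equals a row-by-row brute-force recomputation."""
        obs = _random_obs()
        table = idx.ler_table(obs, mode="paired")
        for _, row in table.iterrows():
            sel = obs[(obs["arm"] == row["arm"]) & (obs["block"] == row["block"])]
            get = lambda d, c: sel[(sel["diversity"] == d) & (sel["component"] == c)][
                "biomass_g"].iloc[0]
            expected = (get("MIX", "AC") / get("AC_mono", "total")
                        + get("MIX", "BM") / get("BM_mono", "total"))
            assert row["ler"] == pytest.approx(expected, rel=1e-12)

    def test_ame_table_matches_naive_loop(self):
        obs = _random_obs(seed=1)
        table = idx.ame_table(obs, "biomass", mode="paired")
        for _, row in table.iterrows():
            sel = obs[(obs["arm"] == row["arm"]) & (obs["block"] == row["block"])
                      & (obs["component"] == "total")]
            y = sel.set_index("diversity")["biomass_g"]
            expected = y["MIX"] - (y["AC_mono"] + y["BM_mono"]) / 2
            assert row["ame"] == pytest.approx(expected, rel=1e-12)

    def test_row_order_invariance(self):
        obs = _random_obs(seed=2)
        shuffled = obs.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = idx.ler_table(obs, mode="mean").sort_values(["arm", "harvest"]).reset_index(drop=True)
        b = idx.ler_table(shuffled, mode="mean").sort_values(["arm", "harvest"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_null_table_propagates_unit_ler_zero_ame(self, null_resilience_obs):
        """The exact-null generator yields LER = 1 and AME = 0 in every cell."""
        lt = idx.ler_table(null_resilience_obs, mode="mean")
        np.testing.assert_allclose(lt["ler"], 1.0, rtol=1e-10)
        np.testing.assert_allclose(lt["pler_ac"], 0.5, rtol=1e-10)
        at = idx.ame_table(null_resilience_obs, "biomass", mode="mean")
        np.testing.assert_allclose(at["ame"], 0.0, atol=1e-10)

    def test_single_harvest_table_has_no_cgr(self, null_resistance_obs):
        out = idx.cgr_table(null_resistance_obs, 0.0144)
        assert out.empty

    def test_resilience_table_paired_matches_scalar(self, noise_free_resilience_obs):
        table = idx.resilience_table(noise_free_resilience_obs, mode="paired")
        defined = table.dropna(subset=["r"])
        assert not defined.empty
        for _, row in defined.iterrows():
            assert row["r"] == pytest.approx(idx.resilience(row["d0"], row["dx"]))

    def test_resilience_requires_d0_harvest(self, noise_free_resilience_obs):
        broken = noise_free_resilience_obs.query("harvest != 'H2'")
        with pytest.raises(ValueError, match="aborted"):
            idx.resilience_table(broken)

    def test_schema_mismatch_reports_diff(self):
        bad = _random_obs().rename(columns={"biomass_g": "biomass"})
        with pytest.raises(ValueError, match="missing columns.*biomass_g"):
            idx.check_schema(bad)
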