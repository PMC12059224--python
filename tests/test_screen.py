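"""Screen aggregation, decile splits, doubling times, ROI selection,
flat-vs-topography grouping, and translation comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dogscreen.screen import (
    aggregate,
    cluster_vs_single_table,
    compare_screen_vs_translation,
    decile_split,
    doubling_time,
    group_flat_vs_topo,
    identify_rois,
)


def _quant_rows(tile_indices, replicate, **metrics):
    rows = []
    for i, j in tile_indices:
        row = {"tile_i": i, "tile_j": j, "replicate": replicate}
        row.update(metrics)
        rows.append(row)
    return rows


class TestAggregate:
    def test_replicate_mean_is_exact(self, sw_layout):
        tiles = [(0, 0)]
        quant = pd.DataFrame(
            _quant_rows(tiles, 1, ki67_pct=40.0)
            + _quant_rows(tiles, 2, ki67_pct=50.0)
            + _quant_rows(tiles, 3, ki67_pct=60.0)
        )
        records, heatmaps = aggregate(quant, sw_layout, grid_kind="tile")
        hm = heatmaps["ki67_pct"]
        assert hm.values[0, 0] == pytest.approx(50.0)
        assert hm.n[0, 0] == 3

    def test_sw_datapoint_heatmap_is_7x5(self, sw_layout):
        # tiles at every datapoint-window center so each window is covered
        from dogscreen.gradients import make_datapoint_grid, make_tile_grid

        tile_grid = make_tile_grid(sw_layout)
        quant = pd.DataFrame(
            _quant_rows([t.index for t in tile_grid], 1, ki67_pct=10.0)
        )
        records, heatmaps = aggregate(quant, sw_layout, grid_kind="datapoint")
        assert heatmaps["ki67_pct"].shape == (7, 5)

    def test_missing_windows_stay_missing(self, sw_layout):
        quant = pd.DataFrame(_quant_rows([(0, 0)], 1, ki67_pct=42.0))
        records, heatmaps = aggregate(quant, sw_layout, grid_kind="tile")
        hm = heatmaps["ki67_pct"]
        assert np.isnan(hm.values).sum() == hm.values.size - 1

    def test_records_carry_material_properties(self, sw_layout):
        quant = pd.DataFrame(_quant_rows([(0, 0), (5, 5)], 1, ki67_pct=10.0))
        records, _ = aggregate(quant, sw_layout, grid_kind="tile")
        assert {"stiffness_mpa", "wca_deg"} <= set(records.columns)
        assert records["wavelength_um"].eq(0).all()  # S-W is flat

    def test_unknown_tile_rejected(self, sw_layout):
        quant = pd.DataFrame(_quant_rows([(99, 99)], 1, ki67_pct=1.0))
        with pytest.raises(ValueError, match="outside"):
            aggregate(quant, sw_layout, grid_kind="tile")


class TestDecileSplit:
    def test_sizes_are_floor_of_fraction(self):
        split = decile_split(np.arange(168.0))
        assert len(split.low) == 16 and len(split.high) == 16
        assert split.low.max() <= split.high.min()

    def test_identical_values_give_zero_d(self):
        split = decile_split(np.full(50, 7.0))
        assert split.ks.d_stat == 0.0

    def test_separated_deciles_fully_distinguish(self):
        # 30 values: deciles of size 3, disjoint ranges -> D = 1 and the
        # exact enumerated p for 3v3 separation (2/C(6,3) = 0.1)
        split = decile_split(np.arange(1.0, 31.0))
        assert split.ks.d_stat == 1.0
        assert split.ks.p_value == pytest.approx(0.1)
        assert split.ks.method == "exact"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            decile_split(np.arange(9.0))

    def test_nan_values_dropped(self):
        values = np.concatenate([np.arange(20.0), [np.nan] * 5])
        assert decile_split(values).values.size == 20


class TestDoublingTime:
    def test_one_doubling_over_48h(self):
        assert doubling_time(100, 200).hours == pytest.approx(48.0)

    def test_two_doublings(self):
        assert doubling_time(50, 200).hours == pytest.approx(24.0)

    def test_decline_is_negative_with_flag(self):
        dt = doubling_time(200, 100)
        assert dt.hours < 0 and dt.flag == "decline"

    def test_no_change_is_missing(self):
        dt = doubling_time(100, 100)
        assert dt.missing and dt.flag == "no-change"

    def test_nonpositive_density_undefined(self):
        assert doubling_time(0, 100).flag == "undefined"
        assert doubling_time(100, -5).flag == "undefined"

    @given(x=st.floats(1e-3, 1e6))
    def test_doubling_always_equals_interval(self, x):
        assert doubling_time(x, 2 * x).hours == pytest.approx(48.0)


def _paired_table(effects, n_obs=6, noise=1.0, seed=0):
    """Long table of per-window observations; effects maps window -> shift
    of MCF10a above MCF7 (both centered on 50)."""
    rng = np.random.default_rng(seed)
    rows = []
    for window, shift in effects.items():
        for cell, mean in (("MCF10a", 50 + shift / 2), ("MCF7", 50 - shift / 2)):
            for _ in range(n_obs):
                rows.append({
                    "window": window, "cell_type": cell,
                    "value": mean + rng.normal(0, noise),
                })
    return pd.DataFrame(rows)


class TestIdentifyROIs:
    def test_diag_distance_formula(self):
        table = _paired_table({(0, 0): 60.0}, noise=1e-6)
        rois = identify_rois(table, k=1)
        assert rois[0].diag_distance == pytest.approx(60 / np.sqrt(2), rel=1e-3)
        assert rois[0].label == "positive"

    def test_symmetric_table_yields_no_rois(self):
        # perfectly symmetric: both cell types see identical observations
        rng = np.random.default_rng(1)
        rows = []
        for w in range(5):
            obs = 50 + rng.normal(0, 3, 6)
            for cell in ("MCF10a", "MCF7"):
                rows += [{"window": w, "cell_type": cell, "value": v}
                         for v in obs]
        with pytest.warns(UserWarning, match="significant"):
            rois = identify_rois(pd.DataFrame(rows))
        assert rois == []

    def test_planted_scenario_returns_3_pos_and_3_neg(self):
        effects = {(0, j): 20.0 + j for j in range(4)}
        effects.update({(1, j): -18.0 - j for j in range(4)})
        effects.update({(2, j): 0.0 for j in range(4)})
        rois = identify_rois(_paired_table(effects))
        assert sum(r.label == "positive" for r in rois) == 3
        assert sum(r.label == "negative" for r in rois) == 3
        ids = [r.id for r in rois]
        assert ids == ["Pos1", "Pos2", "Pos3", "Neg1", "Neg2", "Neg3"]
        # ranked by |diagonal distance|: strongest effects first
        assert rois[0].window == (0, 3)

    def test_antisymmetric_under_cell_type_swap(self):
        effects = {(0, 0): 25.0, (1, 0): -20.0, (2, 0): 15.0}
        table = _paired_table(effects)
        swapped = table.assign(
            cell_type=table["cell_type"].map(
                {"MCF10a": "MCF7", "MCF7": "MCF10a"}
            )
        )
        rois = identify_rois(table, k=2)
        rois_swapped = identify_rois(swapped, k=2)
        by_window = {r.window: r for r in rois}
        for r in rois_swapped:
            partner = by_window[r.window]
            assert r.diag_distance == pytest.approx(-partner.diag_distance)
            assert {r.label, partner.label} == {"positive", "negative"}

    def test_insufficient_replicates_skipped(self):
        table = pd.DataFrame({
            "window": [0, 0, 0], "cell_type": ["MCF10a", "MCF7", "MCF7"],
            "value": [80.0, 20.0, 21.0],
        })
        with pytest.warns(UserWarning):
            assert identify_rois(table) == []


class TestGroupFlatVsTopo:
    def _records(self, flat_vals, topo_vals):
        rows = [{"layout": "S-W", "cluster_density_per_mm2": v}
                for v in flat_vals]
        rows += [{"layout": lay, "cluster_density_per_mm2": v}
                 for lay, v in zip(
                     ["T-S", "T-W", "T-S|W"] * (len(topo_vals) // 3 + 1),
                     topo_vals)]
        return pd.DataFrame(rows)

    def test_planted_difference_detected(self, rng):
        records = self._records(rng.normal(9.1, 1.0, 30),
                                rng.normal(3.6, 1.0, 30))
        cmp = group_flat_vs_topo(records, "cluster_density_per_mm2")
        assert cmp.flat_mean == pytest.approx(9.1, abs=0.8)
        assert cmp.topo_mean == pytest.approx(3.6, abs=0.8)
        assert cmp.ks.p_value < 0.05

    def test_identical_rates_not_significant(self, rng):
        vals = rng.normal(5.0, 1.0, 60)
        records = self._records(vals[:30], vals[30:])
        cmp = group_flat_vs_topo(records, "cluster_density_per_mm2")
        assert cmp.ks.p_value > 0.05

    def test_group_sizes_counted(self, rng):
        records = self._records(rng.normal(size=35), rng.normal(size=49 * 3))
        cmp = group_flat_vs_topo(records, "cluster_density_per_mm2")
        assert cmp.n_flat == 35 and cmp.n_topo == 147

    def test_empty_group_rejected(self):
        records = self._records([], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            group_flat_vs_topo(records, "cluster_density_per_mm2")


class TestScreenVsTranslation:
    SCREEN = pd.DataFrame({
        "id": ["Pos1", "Pos2", "Neg1"],
        "mcf10a_pct": [70.0, 65.0, 30.0],
        "mcf7_pct": [40.0, 45.0, 60.0],
    })

    def test_equal_translation_gives_zero_deltas_and_retention(self):
        shifts, _ = compare_screen_vs_translation(self.SCREEN,
                                                 self.SCREEN.copy())
        assert (shifts["delta_mcf10a_pct"] == 0).all()
        assert shifts["retained"].all()

    def test_uniform_shift_keeps_diagonal_side(self):
        trans = self.SCREEN.copy()
        trans[["mcf10a_pct", "mcf7_pct"]] += 10.0
        shifts, _ = compare_screen_vs_translation(self.SCREEN, trans)
        assert shifts["retained"].all()
        assert (shifts["delta_mcf7_pct"] == 10.0).all()

    def test_unmatched_ids_listed(self):
        trans = self.SCREEN.copy()
        trans.loc[0, "id"] = "Pos9"
        with pytest.raises(ValueError, match="Pos9"):
            compare_screen_vs_translation(self.SCREEN, trans)

    def test_seeding_density_effect_on_mcf7_only(self, rng):
        """High seeding boosts MCF7 Ki-67 only: the grouped MCF7 comparison
        is significant, the MCF10a one is not."""
        ids = [f"R{i}" for i in range(6)]
        rows = []
        for seeding, mcf7_mean in (("low", 40.0), ("high", 70.0)):
            for roi in ids:
                rows.append({
                    "id": roi, "seeding": seeding,
                    "mcf10a_pct": 55 + rng.normal(0, 2),
                    "mcf7_pct": mcf7_mean + rng.normal(0, 2),
                })
        trans = pd.DataFrame(rows)
        screen = pd.DataFrame({
            "id": ids, "mcf10a_pct": 55.0, "mcf7_pct": 50.0
        })
        shifts, seeding_tests = compare_screen_vs_translation(screen, trans)
        assert seeding_tests["mcf7_pct"].p_value < 0.05
        assert seeding_tests["mcf10a_pct"].p_value > 0.05


class TestClusterVsSingleTable:
    def test_mcf10a_input_empty_with_warning(self):
        records = pd.DataFrame({
            "cell_type": ["MCF10a"] * 3,
            "cluster_density_per_mm2": [np.nan] * 3,
        })
        with pytest.warns(UserWarning):
            table = cluster_vs_single_table(records)
        assert table.empty

    def test_row_count_equals_non_missing_windows(self):
        records = pd.DataFrame({
            "cell_type": ["MCF7"] * 5,
            "single_density_per_mm2": [50.0] * 5,
            "cluster_density_per_mm2": [3.0, 4.0, np.nan, 5.0, 6.0],
            "mean_cluster_area_um2": [2500.0] * 5,
        })
        assert len(cluster_vs_single_table(records)) == 4

    def test_coupled_rates_show_positive_correlation(self, rng):
        density = rng.uniform(2, 12, 60)
        area = 2000 + 250 * density + rng.normal(0, 200, 60)
        records = pd.DataFrame({
            "cell_type": "MCF7",
            "single_density_per_mm2": 50.0,
            "cluster_density_per_mm2": density,
            "mean_cluster_area_um2": area,
        })
        table = cluster_vs_single_table(records)
        corr = np.corrcoef(table["cluster_density_per_mm2"],
                           table["mean_cluster_area_um2"])[0, 1]
        assert corr > 0
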