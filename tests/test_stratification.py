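"""Quantile binning, class intersection and median-per-class mapping."""

import numpy as np
import pandas as pd
import pytest

from carbonscape import Grid, StratifiedUpscaler, StratScheme, default_scheme
from carbonscape.stratification import (
    NODATA_CLASS,
    classify,
    fit_class_medians,
    predict_stratified,
    quantile_breaks,
)


class TestQuantileBreaks:
    def test_single_bin_has_no_breakpoints(self):
        breaks, collapsed = quantile_breaks([1.0, 2.0, 3.0], 1)
        assert breaks == [] and not collapsed

    def test_uniform_0_to_99_quartiles(self):
        breaks, collapsed = quantile_breaks(np.arange(100.0), 4)
        np.testing.assert_allclose(breaks, [24.75, 49.5, 74.25])
        assert not collapsed

    def test_matches_linear_interpolation_quantile_oracle(self, rng):
        vals = rng.gamma(2.0, 10.0, size=500)
        breaks, _ = quantile_breaks(vals, 5)
        expected = [np.quantile(vals, q, method="linear") for q in (0.2, 0.4, 0.6, 0.8)]
        np.testing.assert_allclose(breaks, expected)

    def test_identical_values_collapse_with_flag(self):
        breaks, collapsed = quantile_breaks(np.full(50, 7.0), 4)
        assert breaks == [7.0] and collapsed

    def test_rejects_zero_bins(self):
        with pytest.raises(ValueError):
            quantile_breaks([1.0], 0)


class TestShippedScheme:
    def test_twenty_intervals_distributed_as_shipped(self):
        s = default_scheme()
        assert s.total_intervals == 20
        counts = {v: s.n_bins(v) for v in ("soil", "pv", "npv", "elevation", "slope", "aspect")}
        assert counts == {"soil": 2, "pv": 8, "npv": 3, "elevation": 4, "slope": 2, "aspect": 1}

    def test_breakpoint_value_falls_in_upper_interval(self):
        s = default_scheme()
        # pv = 85 is >= the first break, so it belongs to [85, 88), bin 1
        assert s.bin_index("pv", np.array([85.0]))[0] == 1
        assert s.bin_index("pv", np.array([84.999]))[0] == 0
        assert s.bin_index("elevation", np.array([443.0]))[0] == 3

    def test_aspect_is_a_single_unbounded_interval(self):
        s = default_scheme()
        assert s.bin_index("aspect", np.array([0.0, 180.0, 359.9])).tolist() == [0, 0, 0]

    def test_value_below_domain_minimum_is_an_error(self):
        with pytest.raises(ValueError, match="below the first interval"):
            default_scheme().bin_index("slope", np.array([-0.1]))

    def test_non_increasing_breaks_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StratScheme(breaks={"soil": [5.0, 5.0], "pv": [], "npv": [],
                                "elevation": [], "slope": [], "aspect": []})


class TestClassify:
    def test_single_interval_scheme_one_habitat_gives_one_class(self, small_landscape):
        scheme = StratScheme(breaks={v: [] for v in ("soil", "pv", "npv", "elevation", "slope", "aspect")})
        ls = small_landscape
        uniform_hab = ls.habitat.like(np.zeros(ls.shape, dtype=np.int64))
        import dataclasses
        flat = dataclasses.replace(ls, habitat=uniform_hab)
        cm = classify(flat, scheme)
        assert np.unique(cm.grid.values).tolist() == [0]

    def test_identifier_decoding_roundtrips(self, small_landscape):
        cm = classify(small_landscape, default_scheme())
        for cid in np.unique(cm.grid.values)[:20]:
            if cid == NODATA_CLASS:
                continue
            d = cm.decode(int(cid))
            rebuilt = cm.encode({v: np.array([d[v]]) for v in
                                 ("soil", "pv", "npv", "elevation", "slope", "aspect")},
                                np.array([d["habitat"]]))
            assert rebuilt[0] == cid

    def test_class_count_bounded_by_combinatorics(self, small_landscape):
        cm = classify(small_landscape, default_scheme())
        n_classes = len(np.unique(cm.grid.values))
        assert n_classes <= 20 * 8 * 3 * 4 * 2 * 1 * small_landscape.config.n_habitat

    def test_nodata_pixel_gets_nodata_class(self, small_landscape):
        import dataclasses
        ls = small_landscape
        elev = ls.elevation.values.copy()
        elev[0, 0] = ls.elevation.nodata
        broken = dataclasses.replace(ls, elevation=ls.elevation.like(elev))
        cm = classify(broken, default_scheme())
        assert cm.grid.values[0, 0] == NODATA_CLASS


def _toy_class_setup():
    """3-class toy: class 0 sampled, class 1 unsampled (habitat mate of 0), class 2 empty habitat."""
    # habitat codes 0,0,1; classes differ by an elevation bin
    codes = np.array([[0, 0, 0, 0], [2, 2, 2, 2], [5, 5, 5, 5]])  # packed ids: hab = id % 2
    grid = Grid(codes, nodata=NODATA_CLASS)
    scheme = default_scheme()
    from carbonscape.stratification import ClassMap
    cm = ClassMap(grid=grid, scheme=scheme, n_habitat=2)
    acd = Grid(np.array([[30.0, 40.0, 50.0, 60.0], [1.0, 1.0, 1.0, 1.0], [70.0, 70.0, 70.0, 70.0]]))
    lidar = Grid(np.array([[1, 1, 1, 1], [0, 0, 0, 0], [1, 1, 0, 0]], dtype=bool), nodata=-1)
    return cm, acd, lidar


class TestClassMedians:
    def test_odd_and_even_count_medians(self):
        cm, acd, lidar = _toy_class_setup()
        mt = fit_class_medians(cm, acd, lidar)
        row0 = mt.table.set_index("class_id").loc[0]
        assert row0["median"] == pytest.approx(45.0)  # even count: mean of middle two
        assert row0["fallback"] == "class"

    def test_unsampled_class_falls_back_to_habitat_then_global(self):
        cm, acd, lidar = _toy_class_setup()
        mt = fit_class_medians(cm, acd, lidar)
        t = mt.table.set_index("class_id")
        # class 2 (habitat 0) unsampled: habitat 0 samples are {30,40,50,60} -> 45
        assert t.loc[2, "fallback"] == "habitat"
        assert t.loc[2, "median"] == pytest.approx(45.0)
        # class 5 (habitat 1) sampled directly
        assert t.loc[5, "fallback"] == "class"
        assert t.loc[5, "median"] == pytest.approx(70.0)

    def test_global_fallback_when_habitat_unsampled(self):
        cm, acd, lidar = _toy_class_setup()
        lidar.values[2, :] = False  # habitat 1 now entirely unsampled
        mt = fit_class_medians(cm, acd, lidar)
        t = mt.table.set_index("class_id")
        assert t.loc[5, "fallback"] == "global"
        assert t.loc[5, "median"] == pytest.approx(45.0)

    def test_no_samples_at_all_is_an_error(self):
        cm, acd, lidar = _toy_class_setup()
        lidar.values[:] = False
        with pytest.raises(ValueError, match="no sampled pixels"):
            fit_class_medians(cm, acd, lidar)


class TestPredictStratified:
    def test_equals_groupby_median_oracle_on_random_landscape(self):
        from carbonscape import LandscapeConfig, make_landscape

        ls = make_landscape(LandscapeConfig(n_rows=50, n_cols=50, seed=21, n_habitat=6))
        res = StratifiedUpscaler(ls).fit()
        pred = res.predict()
        # brute-force oracle: group sampled pixels by class, median, broadcast
        cm = res.class_map.grid.values
        lidar = ls.lidar_mask.values.astype(bool)
        acd = ls.acd_true.values
        df = pd.DataFrame({"cls": cm[lidar], "acd": acd[lidar]})
        med = df.groupby("cls")["acd"].median()
        for cid, m in med.items():
            np.testing.assert_allclose(pred.values[cm == cid], m)

    def test_prediction_values_come_from_the_median_table(self, small_landscape):
        res = StratifiedUpscaler(small_landscape).fit()
        pred = res.predict()
        allowed = set(res.median_table.table["median"].round(9))
        got = set(np.round(pred.values[pred.valid_mask()], 9).ravel())
        assert got <= allowed

    def test_unresolvable_class_is_an_error(self):
        cm, acd, lidar = _toy_class_setup()
        mt = fit_class_medians(cm, acd, lidar)
        mt.table = mt.table[mt.table["class_id"] != 2]
        with pytest.raises(ValueError, match="class id"):
            predict_stratified(cm, mt)

    def test_refit_is_idempotent(self, small_landscape):
        a = StratifiedUpscaler(small_landscape).fit()
        b = StratifiedUpscaler(small_landscape).fit()
        pd.testing.assert_frame_equal(a.median_table.table, b.median_table.table)

    def test_sampled_class_residual_median_is_zero(self, small_landscape):
        res = StratifiedUpscaler(small_landscape).fit()
        pred = res.predict()
        lidar = small_landscape.lidar_mask.values.astype(bool)
        cm = res.class_map.grid.values
        resid = pred.values - small_landscape.acd_true.values
        directly = res.median_table.table.query("fallback == 'class'")["class_id"]
        for cid in directly.head(25):
            sel = (cm == cid) & lidar
            assert np.abs(np.median(resid[sel])) < 1e-9
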