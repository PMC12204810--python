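"""Temporal matching, ranking, and tolerance-threshold selection."""

import numpy as np
import pytest

from rangehood import AnnualSeries, FocalConfig, LandscapeConfig, \
    apply_focal_to_series, extract_matched_values, filter_by_year_range, \
    filter_records_by_habitat, generate_cover_series, generate_suitability, \
    rank_matched_values, sample_occurrences, select_dtt
from rangehood.matching import MatchedValue
from rangehood.occurrences import OccurrenceRecord, OccurrenceSet, Status
from rangehood.projection import points_to_crs

from conftest import make_raster


def mv(rid, value, year=2005, method="exact"):
    return MatchedValue(rid, year, method, value)


class TestYearFilter:
    def test_boundary_years_inclusive(self):
        occ = OccurrenceSet([
            OccurrenceRecord("a", 0, 0, 1999),
            OccurrenceRecord("b", 0, 1, 2000),
            OccurrenceRecord("c", 0, 2, 2019),
            OccurrenceRecord("d", 0, 3, 2020),
            OccurrenceRecord("e", 0, 4, None),
        ])
        out = filter_by_year_range(occ, 2000, 2019)
        assert out.n_active == 2
        assert out["e"].status is Status.DROPPED_NO_YEAR
        assert out["a"].status is Status.DROPPED_OUT_OF_RANGE
        assert out["d"].status is Status.DROPPED_OUT_OF_RANGE
        assert sum(out.status_counts().values()) == 5  # conservation

    def test_all_in_range_unchanged(self):
        occ = OccurrenceSet([OccurrenceRecord(f"r{i}", 0, 0.1 * i, 2005)
                             for i in range(4)])
        assert filter_by_year_range(occ, 2000, 2019).n_active == 4

    def test_bad_range_rejected(self):
        occ = OccurrenceSet([OccurrenceRecord("a", 0, 0, 2005)])
        with pytest.raises(ValueError):
            filter_by_year_range(occ, 2019, 2000)


class TestRanking:
    def test_ascending_order(self):
        ranked = rank_matched_values([mv("a", 31.0), mv("b", 21.1), mv("c", 45.0)])
        assert [m.cover_value for m in ranked] == [21.1, 31.0, 45.0]

    def test_ties_keep_input_order(self):
        ranked = rank_matched_values([mv("x", 17.0), mv("y", 17.0), mv("z", 35.0)])
        assert [m.record_id for m in ranked] == ["x", "y", "z"]

    def test_sorted_list_unchanged(self):
        vals = [mv("a", 1.0), mv("b", 2.0), mv("c", 3.0)]
        assert rank_matched_values(vals) == vals

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_matched_values([])


class TestSelectDTT:
    def test_tied_minimum_survives_single_drop(self):
        """Two records tie at 17%; dropping one leaves 17% as the threshold."""
        ranked = [mv("a", 17.0), mv("b", 17.0), mv("c", 35.0), mv("d", 60.0)]
        result = select_dtt(ranked, drop_count=1)
        assert result.threshold == 17.0
        assert result.dropped_ids == ("a",)

    def test_drop_lowest_moves_to_second_value(self):
        """21.1% dropped as aberrant -> threshold jumps to 31%."""
        ranked = [mv("a", 21.1), mv("b", 31.0), mv("c", 45.0)]
        result = select_dtt(ranked, drop_count=1)
        assert result.threshold == 31.0

    def test_no_drops_gives_global_minimum(self):
        result = select_dtt([mv("a", 40.0), mv("b", 25.0)])
        assert result.threshold == 25.0 and result.dropped_ids == ()

    def test_explicit_drop_ids(self):
        ranked = [mv("a", 10.0), mv("b", 20.0), mv("c", 30.0)]
        assert select_dtt(ranked, drop_ids=["a", "b"]).threshold == 30.0
        with pytest.raises(ValueError, match="zz"):
            select_dtt(ranked, drop_ids=["zz"])

    def test_dropping_all_records_rejected(self):
        with pytest.raises(ValueError):
            select_dtt([mv("a", 10.0)], drop_count=1)

    def test_threshold_monotone_in_drop_count(self, rng):
        vals = [mv(f"r{i}", v) for i, v in enumerate(rng.uniform(0, 100, 30))]
        thresholds = [select_dtt(vals, drop_count=k).threshold for k in range(29)]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))


class TestExtraction:
    def _series_single(self, values, year=2010):
        return AnnualSeries({year: make_raster(values)})

    def _record_at_pixel_center(self, series, row, col, rid="a", year=2010):
        t = series.grid.transform
        x, y = t.center_of(np.array(row), np.array(col))
        from rangehood.projection import inverse_project_points
        lon, lat = inverse_project_points([(float(x), float(y))], series.grid.crs)[0]
        return OccurrenceRecord(rid, lon, lat, year)

    def test_pixel_center_value_extracted(self):
        vals = np.full((3, 3), 80.0)
        vals[1, 2] = 17.0
        series = self._series_single(vals)
        rec = self._record_at_pixel_center(series, 1, 2)
        matched, _ = extract_matched_values(OccurrenceSet([rec]), series)
        assert matched[0].cover_value == 17.0
        assert matched[0].year_used == 2010

    def test_record_outside_extent_dropped_not_error(self):
        series = self._series_single(np.full((3, 3), 50.0))
        rec = OccurrenceRecord("far", 10.0, 10.0, 2010)
        matched, occ = extract_matched_values(OccurrenceSet([rec]), series)
        assert matched == []
        assert occ["far"].status is Status.DROPPED_NODATA

    def test_strict_year_policy_errors_with_record_name(self):
        series = self._series_single(np.full((3, 3), 50.0), year=2010)
        rec = self._record_at_pixel_center(series, 0, 0, year=2012)
        with pytest.raises(KeyError, match="2012"):
            extract_matched_values(OccurrenceSet([rec]), series)
        matched, _ = extract_matched_values(OccurrenceSet([rec]), series,
                                            year_policy="nearest")
        assert matched[0].year_used == 2010

    def test_matches_brute_force_point_lookup(self):
        """50 synthetic records vs an independent point-in-pixel scan."""
        config = LandscapeConfig(seed=7, n_occurrences=50, jitter_sd_m=300.0)
        series, _ = generate_cover_series(config)
        suit = generate_suitability(config)
        occ, _ = sample_occurrences(config, series, suit)
        matched, _ = extract_matched_values(occ, series)
        by_id = {m.record_id: m for m in matched}
        t = series.grid.transform
        for rec in occ.active():
            x, y = points_to_crs([(rec.lon, rec.lat)], series.grid.crs)[0]
            layer = series[rec.year]
            hit = None
            for r in range(layer.n_rows):
                for c in range(layer.n_cols):
                    west, north = t.corner_of(r, c)
                    east, south = t.corner_of(r + 1, c + 1)
                    if west <= x < east and south < y <= north:
                        hit = layer.values[r, c]
                        break
                if hit is not None:
                    break
            if hit is None:
                assert rec.record_id not in by_id
            else:
                assert by_id[rec.record_id].cover_value == hit


class TestHabitatFilter:
    def test_all_pixels_full_cover_all_retained(self):
        layer = make_raster(np.full((4, 4), 100.0))
        series = AnnualSeries({2019: layer})
        config = LandscapeConfig(seed=1, n_occurrences=5)
        # place records at interior pixel centres
        from rangehood.projection import inverse_project_points
        recs = []
        for i in range(5):
            x, y = layer.transform.center_of(np.array(i % 4), np.array(i % 4))
            lon, lat = inverse_project_points([(float(x), float(y))], layer.crs)[0]
            recs.append(OccurrenceRecord(f"r{i}", lon, lat, 2019))
        occ = OccurrenceSet(recs)
        assert filter_records_by_habitat(occ, layer, 100.0).n_active == 5

    def test_boundary_value_retained_below_dropped(self):
        vals = np.array([[31.0, 30.9999]])
        layer = make_raster(vals)
        from rangehood.projection import inverse_project_points
        recs = []
        for c in range(2):
            x, y = layer.transform.center_of(np.array(0), np.array(c))
            lon, lat = inverse_project_points([(float(x), float(y))], layer.crs)[0]
            recs.append(OccurrenceRecord(f"r{c}", lon, lat, 2019))
        out = filter_records_by_habitat(OccurrenceSet(recs), layer, 31.0)
        assert out["r0"].status is Status.ACTIVE
        assert out["r1"].status is Status.DROPPED_BELOW_DTT

    def test_constructed_subthreshold_count(self):
        """Jitter-free sampling at theta=40, filter at 40 keeps everyone;
        filtering at a higher bar drops exactly the records below it."""
        config = LandscapeConfig(seed=11, n_occurrences=50,
                                 true_tolerance_theta=40.0, n_years=1)
        series, _ = generate_cover_series(config)
        suit = generate_suitability(config)
        occ, truth = sample_occurrences(config, series, suit)
        layer = series[config.start_year]
        assert filter_records_by_habitat(occ, layer, 40.0).n_active == 50
        bar = 55.0
        expected = sum(1 for t in truth["records"] if t["true_cover"] >= bar)
        assert filter_records_by_habitat(occ, layer, bar).n_active == expected


class TestVarianceReduction:
    def test_neighborhood_values_less_variable_on_heterogeneous_fields(self):
        """Focal smoothing shrinks the sample variance of matched values on
        short-range-heterogeneous landscapes (>=95% of simulations)."""
        wins = 0
        n_sims = 40
        for seed in range(n_sims):
            config = LandscapeConfig(seed=seed, autocorr_length_m=400.0,
                                     n_occurrences=40, n_years=3,
                                     jitter_sd_m=500.0)
            series, _ = generate_cover_series(config)
            suit = generate_suitability(config)
            occ, _ = sample_occurrences(config, series, suit)
            exact, _ = extract_matched_values(occ, series, "exact")
            nbh_series = apply_focal_to_series(series, FocalConfig(3, "mean"))
            nbh, _ = extract_matched_values(occ, nbh_series, "neighborhood")
            v_exact = np.var([m.cover_value for m in exact])
            v_nbh = np.var([m.cover_value for m in nbh])
            wins += v_nbh < v_exact
        assert wins / n_sims >= 0.95
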