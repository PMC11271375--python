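import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gmean

from pseudosurvey.frame_grid import clip_grid, make_hex_grid
from pseudosurvey.harmonize import (UnitError, composite, conductance_to_salinity,
                                    do_mgL_to_percent, do_percent_to_mgL,
                                    flag_freshwater, flag_outliers,
                                    harmonize_records, iqr_fences,
                                    oxygen_solubility_mgL, resolve_replicates,
                                    salinity_to_conductance, screen_records,
                                    standardize_units, substitute_nondetects,
                                    winsorize)


def frame_of(records):
    return pd.DataFrame(records)


class TestScreening:
    def test_out_of_window_month_excluded(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(datetime="2015-05-10T10:00:00")]))
        assert kept.empty
        assert (log.reason == "outside-index-months").any()

    def test_missing_unit_excluded(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(unit=None)]))
        assert kept.empty
        assert (log.reason == "no-unit").any()

    def test_ph_unit_optional(self, record_factory):
        kept, _ = screen_records(frame_of([record_factory(parameter="PH", value=7.9, unit=None)]))
        assert len(kept) == 1 and kept.iloc[0]["unit"] == "su"

    def test_clean_record_kept_unchanged(self, record_factory):
        kept, log = screen_records(frame_of([record_factory()]))
        assert len(kept) == 1 and log.empty
        assert kept.iloc[0]["value"] == 3.0

    def test_duplicates_collapse_to_one(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(), record_factory()]))
        assert len(kept) == 1
        assert (log.reason == "duplicate").sum() == 1

    def test_exclusion_qualifier(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(qualifiers="K")]),
                                   qualifier_rules={"K": "exclude"})
        assert kept.empty
        assert (log.reason == "exclusion-qualifier").any()

    def test_unknown_qualifier_kept_and_logged(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(qualifiers="ZZ")]))
        assert len(kept) == 1
        assert (log.reason == "review-qualifier-kept").any()

    def test_every_exclusion_logged_once(self, record_factory):
        rows = [record_factory(site_id=f"S{i}", datetime="2015-03-01T00:00:00")
                for i in range(5)]
        kept, log = screen_records(frame_of(rows))
        assert kept.empty
        assert len(log) == 5 and log["index"].is_unique

    def test_year_filter(self, record_factory):
        kept, log = screen_records(frame_of([record_factory()]), years=[2016])
        assert kept.empty and (log.reason == "outside-index-years").any()

    def test_deep_measurement_excluded(self, record_factory):
        kept, log = screen_records(frame_of([record_factory(depth_m=2.0)]))
        assert kept.empty and (log.reason == "below-surface-depth").any()


class TestReplicates:
    def _screened(self, rows):
        kept, _ = screen_records(frame_of(rows))
        return kept

    def test_upcast_downcast_mean(self, record_factory):
        rows = self._screened([record_factory(value=6.0, qualifiers="up"),
                               record_factory(value=6.4, qualifiers="down")])
        out = resolve_replicates(rows)
        assert len(out) == 1
        assert out.iloc[0]["value"] == pytest.approx(6.2)

    def test_three_values(self, record_factory):
        rows = self._screened([record_factory(value=v, qualifiers=str(v)) for v in (1, 2, 3)])
        assert resolve_replicates(rows).iloc[0]["value"] == pytest.approx(2.0)

    def test_single_record_unchanged(self, record_factory):
        rows = self._screened([record_factory()])
        assert resolve_replicates(rows).iloc[0]["value"] == 3.0

    def test_mixed_units_error(self, record_factory):
        rows = self._screened([record_factory(parameter="TN", unit="mg/L", value=0.4),
                               record_factory(parameter="TN", unit="ug/L", value=400)])
        with pytest.raises(UnitError):
            resolve_replicates(rows)


class TestNondetects:
    def _screened(self, rows):
        kept, _ = screen_records(frame_of(rows))
        return kept

    def test_mdl_substitution(self, record_factory):
        rows = self._screened([record_factory(parameter="TP", unit="mg/L",
                                              value="ND", mdl=0.010)])
        out, _ = substitute_nondetects(rows)
        assert out.iloc[0]["value"] == pytest.approx(0.010)
        assert out.iloc[0]["nondetect_substituted"]

    def test_pql_preferred_over_mdl(self, record_factory):
        rows = self._screened([record_factory(parameter="TP", unit="mg/L",
                                              value="ND", mdl=0.010, pql=0.020)])
        out, _ = substitute_nondetects(rows)
        assert out.iloc[0]["value"] == pytest.approx(0.020)

    def test_detected_value_untouched(self, record_factory):
        rows = self._screened([record_factory(value=3.0)])
        out, _ = substitute_nondetects(rows)
        assert out.iloc[0]["value"] == 3.0
        assert not out.iloc[0]["nondetect_substituted"]

    def test_no_limit_excluded(self, record_factory):
        rows = self._screened([record_factory(value="ND")])
        out, log = substitute_nondetects(rows)
        assert out.empty and (log.reason == "nondetect-no-limit").any()


class TestConductanceToSalinity:
    def test_reference_point(self):
        assert conductance_to_salinity(53_087.0) == pytest.approx(35.000, abs=1e-3)

    def test_zero_clamped(self):
        assert conductance_to_salinity(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            conductance_to_salinity(-1.0)

    def test_monotone_increasing(self):
        sc = np.linspace(100, 60_000, 500)
        s = conductance_to_salinity(sc)
        assert np.all(np.diff(s) > 0)

    def test_inverse_roundtrip(self):
        for s in (0.5, 5.0, 20.0, 35.0):
            assert conductance_to_salinity(salinity_to_conductance(s)) == pytest.approx(s, rel=1e-9)


class TestOxygenConversion:
    def test_benson_krause_reference(self):
        assert do_percent_to_mgL(100.0, 20.0, 0.0) == pytest.approx(9.09, abs=0.02)

    def test_zero_percent(self):
        assert do_percent_to_mgL(0.0, 20.0, 0.0) == 0.0

    def test_linear_in_percent(self):
        full = do_percent_to_mgL(100.0, 20.0, 0.0)
        assert do_percent_to_mgL(50.0, 20.0, 0.0) == pytest.approx(full / 2)

    def test_salinity_lowers_solubility(self):
        assert oxygen_solubility_mgL(20.0, 35.0) < oxygen_solubility_mgL(20.0, 0.0)

    def test_roundtrip(self):
        pct = do_mgL_to_percent(do_percent_to_mgL(87.3, 25.0, 12.0), 25.0, 12.0)
        assert pct == pytest.approx(87.3, rel=1e-9)

    def test_temperature_range_enforced(self):
        with pytest.raises(ValueError):
            do_percent_to_mgL(100.0, 55.0, 0.0)


class TestStandardizeUnits:
    def test_chla_mg_to_ug(self, record_factory):
        kept, _ = screen_records(frame_of([record_factory(unit="mg/L", value=0.003)]))
        kept["nondetect"] = False
        out, _ = standardize_units(kept)
        assert out.iloc[0]["value"] == pytest.approx(3.0)
        assert out.iloc[0]["unit"] == "ug/L"

    def test_do_percent_needs_covariates(self, record_factory):
        rows = [record_factory(parameter="DO_MGL", unit="%", value=95.0)]
        kept, _ = screen_records(frame_of(rows))
        out, log = standardize_units(kept)
        assert out.empty
        assert (log.reason == "do-conversion-missing-covariates").any()

    def test_do_percent_with_covariates(self, record_factory):
        rows = [record_factory(parameter="DO_MGL", unit="%", value=100.0),
                record_factory(parameter="TEMP", unit="degC", value=20.0),
                record_factory(parameter="SAL", unit="pss", value=0.0)]
        kept, _ = screen_records(frame_of(rows))
        out, _ = standardize_units(kept)
        do = out[out.parameter == "DO_MGL"].iloc[0]
        assert do["value"] == pytest.approx(9.09, abs=0.02)
        assert do["unit"] == "mg/L"

    def test_unconvertible_excluded(self, record_factory):
        kept, _ = screen_records(frame_of([record_factory(parameter="TEMP", unit="K",
                                                          value=300.0)]))
        out, log = standardize_units(kept)
        assert out.empty and (log.reason == "unconvertible-unit").any()


class TestOutlierFlags:
    def test_fence_from_quantile_oracle(self, record_factory):
        vals = [2, 2, 2, 4, 4, 4, 11]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        lo, hi = iqr_fences(vals)
        assert (lo, hi) == (q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1))
        rows = frame_of([record_factory(value=float(v), site_id=f"S{i}")
                         for i, v in enumerate(vals)])
        kept, _ = screen_records(rows)
        flagged = flag_outliers(kept)
        assert flagged.loc[flagged.value == 11, "outlier_candidate"].all()
        assert not flagged.loc[flagged.value < hi, "outlier_candidate"].any()

    def test_inside_fences_not_flagged(self, record_factory):
        vals = [2, 2, 2, 4, 4, 4, 9]  # fence at 4 + 3*2 = 10
        kept, _ = screen_records(frame_of([record_factory(value=float(v), site_id=f"S{i}")
                                           for i, v in enumerate(vals)]))
        assert not flag_outliers(kept)["outlier_candidate"].any()

    def test_all_equal_no_flags(self, record_factory):
        kept, _ = screen_records(frame_of([record_factory(value=5.0, site_id=f"S{i}")
                                           for i in range(6)]))
        assert not flag_outliers(kept)["outlier_candidate"].any()

    def test_flags_never_drop(self, record_factory):
        vals = [1.0] * 6 + [1e6]
        kept, _ = screen_records(frame_of([record_factory(value=v, site_id=f"S{i}")
                                           for i, v in enumerate(vals)]))
        assert len(flag_outliers(kept)) == len(vals)


class TestFreshwaterScreen:
    @pytest.mark.parametrize("sal,expect", [(0.04, True), (0.05, True), (5.0, False)])
    def test_threshold_boundary_inclusive(self, record_factory, sal, expect):
        rows = [record_factory(parameter="SAL", unit="pss", value=sal),
                record_factory(parameter="CHLA", value=3.0)]
        kept, _ = screen_records(frame_of(rows))
        out = flag_freshwater(kept)
        assert out["freshwater"].eq(expect).all()  # whole visit flagged together


class TestWinsorize:
    def test_constant_unchanged(self):
        v = np.full(50, 3.3)
        assert np.array_equal(winsorize(v), v)

    def test_upper_clamp_matches_quantile_oracle(self, rng):
        v = rng.lognormal(1.0, 1.0, size=1000)
        out = winsorize(v)
        assert out.max() == pytest.approx(np.quantile(v, 0.995))
        assert out.min() == pytest.approx(np.quantile(v, 0.005))

    def test_interior_values_untouched(self, rng):
        v = rng.normal(0, 1, 200)
        lo, hi = np.quantile(v, [0.005, 0.995])
        out = winsorize(v)
        inside = (v > lo) & (v < hi)
        assert np.array_equal(out[inside], v[inside])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    def test_order_statistics_preserved(self, vals):
        v = np.array(vals)
        out = winsorize(v)
        # clamping never reorders: sorted inputs map to sorted outputs
        assert np.all(np.diff(out[np.argsort(v, kind="stable")]) >= 0)


class TestComposite:
    def _clean(self, rows):
        kept, _ = screen_records(frame_of(rows))
        kept["nondetect"] = kept.get("nondetect", False)
        return kept

    def test_geometric_mean(self, square_frame, record_factory):
        g = clip_grid(make_hex_grid(square_frame, 4), square_frame)
        rows = self._clean([record_factory(value=4.0, site_id="A"),
                            record_factory(value=9.0, site_id="B",
                                           datetime="2015-08-01T10:00:00")])
        out = composite(rows, g)
        assert out.iloc[0]["value"] == pytest.approx(6.0)
        assert out.iloc[0]["value"] == pytest.approx(gmean([4.0, 9.0]))

    def test_mean_coordinates(self, square_frame, record_factory):
        g = clip_grid(make_hex_grid(square_frame, 1), square_frame)
        rows = self._clean([record_factory(x=4.0, y=4.0, site_id="A"),
                            record_factory(x=6.0, y=6.0, site_id="B",
                                           datetime="2015-08-01T10:00:00")])
        out = composite(rows, g)
        assert out.iloc[0]["x"] == pytest.approx(5.0)
        assert out.iloc[0]["y"] == pytest.approx(5.0)

    def test_years_kept_separate(self, square_frame, record_factory):
        g = clip_grid(make_hex_grid(square_frame, 4), square_frame)
        rows = self._clean([record_factory(datetime="2015-07-01T10:00:00"),
                            record_factory(datetime="2016-07-01T10:00:00")])
        out = composite(rows, g)
        assert sorted(out["year"]) == [2015, 2016]

    def test_am_gm_inequality(self, square_frame, rng, record_factory):
        g = clip_grid(make_hex_grid(square_frame, 4), square_frame)
        vals = rng.lognormal(0, 1, 12)
        rows = self._clean([record_factory(value=float(v), site_id=f"S{i}", x=5.0, y=5.0)
                            for i, v in enumerate(vals)])
        out = composite(rows, g)
        assert out.iloc[0]["value"] <= np.mean(vals) + 1e-12

    def test_zero_positive_support_resolved(self, square_frame, record_factory):
        g = clip_grid(make_hex_grid(square_frame, 4), square_frame)
        rows = self._clean([record_factory(parameter="ENTERO", unit="MPN/100mL",
                                           value=0.0, mdl=1.0, site_id="A"),
                            record_factory(parameter="ENTERO", unit="MPN/100mL",
                                           value=10.0, site_id="B",
                                           datetime="2015-08-02T10:00:00")])
        out = composite(rows, g)
        assert np.isfinite(out.iloc[0]["value"]) and out.iloc[0]["value"] > 0


class TestPipeline:
    def test_bit_identical_reruns(self, two_source_records, estuary_grid):
        a = harmonize_records(two_source_records, estuary_grid)
        b = harmonize_records(two_source_records, estuary_grid)
        pd.testing.assert_frame_equal(a.composites, b.composites)
        pd.testing.assert_frame_equal(a.exclusions, b.exclusions)

    def test_exclusions_have_reasons(self, two_source_records, estuary_grid):
        res = harmonize_records(two_source_records, estuary_grid)
        assert res.exclusions["reason"].ne("").all()

    def test_composites_positive_for_positive_support(self, two_source_records, estuary_grid):
        res = harmonize_records(two_source_records, estuary_grid)
        pos = res.composites[res.composites.parameter.isin(["CHLA", "TN", "TP", "ENTERO"])]
        assert (pos["value"] > 0).all()
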