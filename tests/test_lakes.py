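"""Domain model: trophic taxonomy, shape index, suitability, CSV I/O."""

import math

import pytest
from hypothesis import given, strategies as st

import loonlakes as ll
from loonlakes.lakes import LAKE_TROPHIC_CODES, normalize_trophic_code

from conftest import make_lake


class TestShapeIndex:
    def test_circular_lake_of_100ha_scores_the_practical_minimum(self):
        # circle of 1 km^2: perimeter 2*sqrt(pi) km, area 100 ha
        perimeter = 2.0 * math.sqrt(math.pi)
        assert ll.compute_shape_index(perimeter, 100.0) == pytest.approx(0.35449, abs=5e-5)
        assert round(ll.compute_shape_index(perimeter, 100.0), 2) == 0.35

    def test_unit_square_lake(self):
        assert ll.compute_shape_index(4.0, 100.0) == pytest.approx(0.40)

    @given(st.floats(0.1, 100.0), st.floats(1.0, 5000.0), st.floats(1.1, 10.0))
    def test_scale_invariance_under_uniform_linear_rescaling(self, p, a, k):
        base = ll.compute_shape_index(p, a)
        scaled = ll.compute_shape_index(p * k, a * k * k)
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(1.0, 5000.0))
    def test_strictly_increasing_in_perimeter_decreasing_in_area(self, p, dp, a):
        assert ll.compute_shape_index(p + dp, a) > ll.compute_shape_index(p, a)
        assert ll.compute_shape_index(p, a * 2) < ll.compute_shape_index(p, a)

    @pytest.mark.parametrize("p,a", [(0.0, 100.0), (4.0, 0.0), (-1.0, 10.0)])
    def test_non_positive_inputs_rejected(self, p, a):
        with pytest.raises(ValueError):
            ll.compute_shape_index(p, a)


class TestTrophicClassification:
    @pytest.mark.parametrize("count,temp,clarity,two_story,code", [
        (6, "Cool", "Clear", False, "CCC"),
        (2, "Warm", "Dark", False, "SWD"),
        (5, "Cool", "Clear", True, "TS"),
        (4, "Warm", "Clear", False, "CWC"),  # boundary count -> Complex
        (3, "Cool", "Dark", False, "SCD"),
    ])
    def test_known_classifications(self, count, temp, clarity, two_story, code):
        assert ll.classify_trophic(count, temp, clarity, two_story).code == code

    def test_threshold_is_configurable(self):
        assert ll.classify_trophic(4, "Cool", "Clear", complex_threshold=5).code == "SCC"

    @given(st.integers(0, 12), st.sampled_from(["Warm", "Cool"]),
           st.sampled_from(["Clear", "Dark"]), st.booleans())
    def test_total_and_closed_over_the_twelve_code_taxonomy(self, n, t, c, ts):
        cls = ll.classify_trophic(n, t, c, ts)
        assert cls.code in ll.TROPHIC_CODES
        assert cls.code in LAKE_TROPHIC_CODES
        assert len(ll.TROPHIC_CODES) == 12

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            ll.classify_trophic(-1, "Cool", "Clear")
        with pytest.raises(ValueError):
            ll.classify_trophic(3, "Tepid", "Clear")


class TestSuitabilityFilter:
    def test_area_threshold(self):
        lakes = [make_lake("A", area_ha=8.0), make_lake("B", area_ha=12.0)]
        kept = ll.filter_loon_suitable(lakes)
        assert [l.lake_id for l in kept] == ["B"]

    def test_trout_pond_label_removed_even_in_free_text_form(self):
        lakes = [make_lake("A", trophic_class="trout pond", area_ha=50.0),
                 make_lake("B", area_ha=50.0)]
        kept = ll.filter_loon_suitable(lakes)
        assert [l.lake_id for l in kept] == ["B"]

    def test_no_thresholds_is_identity(self):
        lakes = [make_lake("A", area_ha=8.0), make_lake("B", area_ha=12.0)]
        kept = ll.filter_loon_suitable(lakes, min_area_ha=0, excluded_classes=set())
        assert kept == lakes

    def test_normalization_of_codes(self):
        assert normalize_trophic_code(" trout pond ") == "TROUT_POND"


class TestLakeTableIO:
    def _write(self, tmp_path, rows, header="lake_id,name,lat,lon,area_ha,perimeter_km,shape_index,max_depth,secchi,ph,trophic_code,suitable"):
        p = tmp_path / "lakes.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_well_formed_rows_complete(self, tmp_path):
        p = self._write(tmp_path, [
            "L1,One,45.7,-89.5,100,4,0.4,10,3,7.0,CCC,true",
            "L2,Two,45.8,-89.6,50,3,0.42,8,2,6.5,SCD,true",
        ])
        lakes, report = ll.read_lake_table(p)
        assert len(lakes) == 2
        assert report.n_complete == 2 and report.n_incomplete == 0
        assert "2 complete" in str(report)

    def test_missing_ph_loaded_and_counted_incomplete(self, tmp_path):
        p = self._write(tmp_path, ["L1,One,45.7,-89.5,100,4,0.4,10,3,,CCC,true"])
        lakes, report = ll.read_lake_table(p)
        assert lakes[0].ph is None
        assert report.n_incomplete == 1
        assert report.missing_by_field == {"ph": 1}

    def test_duplicate_id_names_the_offender(self, tmp_path):
        p = self._write(tmp_path, [
            "L7,One,45.7,-89.5,100,4,0.4,10,3,7,CCC,true",
            "L7,Two,45.8,-89.6,50,3,0.42,8,2,6.5,SCD,true",
        ])
        with pytest.raises(ValueError, match="L7"):
            ll.read_lake_table(p)

    def test_unparseable_coordinate_names_the_row(self, tmp_path):
        p = self._write(tmp_path, ["L1,One,not_a_number,-89.5,100,4,0.4,10,3,7,CCC,true"])
        with pytest.raises(ValueError, match="lat"):
            ll.read_lake_table(p)

    def test_round_trip_is_exact(self, tmp_path, grid_lakes):
        out = tmp_path / "out.csv"
        ll.write_lake_table(grid_lakes, out)
        back, _ = ll.read_lake_table(out)
        assert len(back) == len(grid_lakes)
        for a, b in zip(grid_lakes, back):
            for attr in ("lake_id", "lat", "lon", "area_ha", "perimeter_km",
                         "shape_index", "max_depth", "secchi", "ph",
                         "trophic_class", "loon_suitable"):
                assert getattr(a, attr) == getattr(b, attr), attr


class TestVisitTableIO:
    def _setup(self, tmp_path, rows):
        lakes = [make_lake("N1"), make_lake("D1", lat=45.8),
                 make_lake("D2", lat=45.9, secchi=None)]
        p = tmp_path / "visits.csv"
        p.write_text("juvenile_id,natal_lake_id,destination_lake_id,date\n"
                     + "\n".join(rows) + "\n")
        return lakes, p

    def test_all_known_and_complete(self, tmp_path):
        lakes, p = self._setup(tmp_path, [
            "J1,N1,D1,2014-09-10",
            "J2,N1,D1,2014-09-12",
            "J3,D1,N1,2014-10-01",
        ])
        visits, report = ll.read_visit_table(p, lakes, require_complete_traits=True)
        assert len(visits) == 3
        assert str(report) == "3 -> 3"

    def test_completeness_filter_drops_missing_secchi_destination(self, tmp_path):
        lakes, p = self._setup(tmp_path, [
            "J1,N1,D1,2014-09-10",
            "J2,N1,D2,2014-09-12",
            "J3,D1,N1,2014-10-01",
        ])
        visits, report = ll.read_visit_table(p, lakes, require_complete_traits=True)
        assert len(visits) == 2
        assert str(report) == "3 -> 2"

    def test_unknown_lake_rejected_by_name(self, tmp_path):
        lakes, p = self._setup(tmp_path, ["J1,N1,L99,2014-09-10"])
        visits, report = ll.read_visit_table(p, lakes)
        assert visits == []
        assert any("L99" in r for r in report.rejections)

    def test_self_visit_rejected(self, tmp_path):
        lakes, p = self._setup(tmp_path, ["J1,N1,N1,2014-09-10"])
        visits, report = ll.read_visit_table(p, lakes)
        assert visits == []
        assert any("same lake" in r for r in report.rejections)

    def test_month_window_filter(self, tmp_path):
        lakes, p = self._setup(tmp_path, [
            "J1,N1,D1,2014-09-10",
            "J2,N1,D1,2014-07-01",
        ])
        visits, _ = ll.read_visit_table(p, lakes, months=(9, 10))
        assert len(visits) == 1

    def test_visit_record_rejects_self_reference(self):
        with pytest.raises(ValueError):
            ll.VisitRecord("J1", "A", "A")

    def test_visit_round_trip(self, tmp_path):
        lakes, p = self._setup(tmp_path, ["J1,N1,D1,2014-09-10"])
        visits, _ = ll.read_visit_table(p, lakes)
        out = tmp_path / "again.csv"
        ll.write_visit_table(visits, out)
        back, _ = ll.read_visit_table(out, lakes)
        assert back == visits


class TestLakeValidation:
    @pytest.mark.parametrize("kw", [
        dict(lat=91.0), dict(lon=-181.0), dict(area_ha=-5.0), dict(ph=15.0),
        dict(shape_index=0.0),
    ])
    def test_invariant_violations_rejected(self, kw):
        with pytest.raises(ValueError):
            make_lake("X", **kw)
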