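"""Tabular IO: schema validation, error reporting, lossless round trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlamino.profiles_io import (
    AminoAcidComposition,
    CellAbundance,
    GeochemSample,
    Horizon,
    IsomerMeasurement,
    StationMetadata,
    TurnoverResult,
    read_results,
    read_station,
    write_results,
    write_station,
)

META_CSV = (
    "station_id,latitude_deg,longitude_deg,water_depth_m,core_recovery_cm,"
    "sedimentation_rate_mm_yr,temp_deepest_c,temp_gradient_c_per_m,location_type\n"
    'SO241-46,27.7069,-111.2275,664,1000,2.10,8.83,0.13,"Marine, OMZ"\n'
)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadStation:
    def test_metadata_row_parses_to_site_descriptors(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf,thaa_umol_gdw\n250,71\n")
        meta, horizons = read_station(table, meta_path)
        assert meta.sedimentation_rate == 2.10
        assert meta.temp_deepest == 8.83
        assert meta.temp_gradient == 0.13
        assert len(horizons) == 1

    def test_empty_sample_table_gives_empty_list_but_parsed_metadata(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf,thaa_umol_gdw\n")
        meta, horizons = read_station(table, meta_path)
        assert horizons == []
        assert meta.station_id == "SO241-46"

    def test_duplicate_depths_rejected(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf\n37\n87\n37\n")
        with pytest.raises(ValueError, match="duplicate depth"):
            read_station(table, meta_path)

    def test_unknown_column_rejected_by_name(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf,bogus_col\n37,1\n")
        with pytest.raises(ValueError, match="bogus_col"):
            read_station(table, meta_path)

    def test_negative_concentration_rejected_with_row(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf,thaa_umol_gdw\n37,5\n87,-1\n")
        with pytest.raises(ValueError, match="row 1"):
            read_station(table, meta_path)

    def test_missing_optional_columns_yield_absent_fields(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf\n37\n")
        _, horizons = read_station(table, meta_path)
        sample = horizons[0].sample
        assert sample.toc is None and sample.thaa is None
        assert horizons[0].isomers is None and horizons[0].cells is None

    def test_horizons_sorted_by_depth(self, tmp_path):
        meta_path = write(tmp_path, "metadata.csv", META_CSV)
        table = write(tmp_path, "samples.csv", "depth_cmbsf\n300\n100\n200\n")
        _, horizons = read_station(table, meta_path)
        assert [h.depth for h in horizons] == [100.0, 200.0, 300.0]


class TestStationRoundTrip:
    def test_full_station_survives_write_read(self, tmp_path, cold_station):
        comp = AminoAcidComposition({"asp": 1.5, "gly": 4.0, "ser": 1.4, "bala": 0.2})
        horizons = [
            Horizon(
                sample=GeochemSample(
                    depth=250.0, toc=2800.0, tn=230.0, thaa=6.9, composition=comp, formate=1.2
                ),
                isomers=IsomerMeasurement(d_asp=150.0, l_asp=1350.0),
                cells=CellAbundance(total_cells=1e8, bac_copies=4e8, arc_copies=1.6e8),
            )
        ]
        write_station(cold_station, horizons, tmp_path / "s.csv", tmp_path / "m.csv")
        meta, back = read_station(tmp_path / "s.csv", tmp_path / "m.csv")
        assert meta == cold_station
        h = back[0]
        assert h.sample.composition.get("gly") == pytest.approx(4.0, rel=1e-12)
        assert h.isomers.d_asp == pytest.approx(150.0)
        assert h.cells.total_cells == pytest.approx(1e8)
        assert h.sample.formate == pytest.approx(1.2)
        assert h.sample.acetate is None


results_strategy = st.lists(
    st.builds(
        TurnoverResult,
        depth=st.floats(0, 1e4, allow_nan=False),
        temperature=st.floats(-2, 120, allow_nan=False),
        k_asp=st.floats(1e-9, 10, allow_nan=False),
        d_necro=st.floats(0, 0.499),
        t_nm=st.floats(1e-3, 1e7),
        t_b=st.floats(0, 1e7),
        asp_bio=st.floats(0, 10),
        asp_necro=st.floats(0, 100),
        flags=st.sets(st.sampled_from(["clamped", "near_equilibrium", "below_live_ratio"])).map(
            frozenset
        ),
    ),
    min_size=1,
    max_size=6,
)


class TestResultsRoundTrip:
    @settings(max_examples=50, derandomize=True)
    @given(results=results_strategy)
    def test_round_trip_preserves_values(self, results, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "results.csv"
        write_results(results, path)
        back = read_results(path)
        assert len(back) == len(results)
        for a, b in zip(results, back):
            for field in ("depth", "temperature", "k_asp", "d_necro", "t_nm", "t_b", "asp_bio", "asp_necro"):
                assert math.isclose(getattr(a, field), getattr(b, field), rel_tol=1e-11, abs_tol=1e-300)
            assert a.flags == b.flags

    def test_near_equilibrium_serializes_inf_sentinel(self, tmp_path):
        r = TurnoverResult(
            depth=498.0, temperature=65.5, k_asp=0.22, d_necro=0.4999,
            t_nm=math.inf, t_b=math.inf, asp_bio=0.01, asp_necro=1.0,
            flags=frozenset({"near_equilibrium"}),
        )
        path = tmp_path / "r.csv"
        write_results(r_list := [r], path)
        assert ",inf," in path.read_text()
        assert math.isinf(read_results(path)[0].t_nm)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "r.csv")


class TestTypeInvariants:
    def test_station_metadata_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            StationMetadata("x", 0, 0, 100, 100, 0.0, 10, 1)

    def test_sample_rejects_thaa_composition_mismatch(self):
        comp = AminoAcidComposition({"gly": 1.0})
        with pytest.raises(ValueError, match="inconsistent"):
            GeochemSample(depth=0.0, thaa=2.0, composition=comp)

    def test_composition_excludes_nonprotein_from_thaa_sum(self):
        comp = AminoAcidComposition({"gly": 1.0, "bala": 5.0, "glcn": 5.0})
        assert comp.protein_thaa() == 1.0

    def test_isomer_d_fraction_in_unit_interval(self):
        m = IsomerMeasurement(d_asp=1.0, l_asp=3.0)
        assert m.d_fraction == pytest.approx(0.25)
        with pytest.raises(ValueError):
            IsomerMeasurement(d_asp=-1.0, l_asp=3.0)
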