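"""File-dialect tests: reading, validation, round-trips."""

import numpy as np
import pandas as pd
import pytest

import bayescr as b


def _write_traps_csv(path, n=30, k=None, effort=None):
    rows = {"station_id": [f"s{i}" for i in range(n)],
            "x": np.linspace(0, 10, n), "y": np.linspace(0, 8, n)}
    df = pd.DataFrame(rows)
    if effort is not None:
        for j in range(effort.shape[1]):
            df[f"occ_{j + 1}"] = effort[:, j]
    df.to_csv(path, index=False)
    return path


class TestReadTraps:
    def test_default_effort_counts_all_trap_nights(self, tmp_path):
        p = _write_traps_csv(tmp_path / "t.csv", n=30)
        traps = b.read_traps(p, n_occasions=53)
        assert traps.total_effort == 30 * 53 == 1590

    def test_zeroed_effort_gives_usable_trap_nights(self, tmp_path, rng):
        effort = np.ones((30, 53), dtype=int)
        fail = rng.choice(effort.size, size=146, replace=False)
        effort.ravel()[fail] = 0
        p = _write_traps_csv(tmp_path / "t.csv", n=30, effort=effort)
        traps = b.read_traps(p)
        assert traps.total_effort == 1444

    def test_duplicate_station_id_rejected_by_name(self, tmp_path):
        df = pd.DataFrame({"station_id": ["a", "b", "a"], "x": [0, 1, 2],
                           "y": [0, 0, 0]})
        df.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(ValueError, match="a"):
            b.read_traps(tmp_path / "t.csv", n_occasions=3)

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        df = pd.DataFrame({"station_id": ["a", "b", "c"], "x": [0, "oops", 2],
                           "y": [0, 0, 0]})
        df.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(ValueError, match="row 3"):
            b.read_traps(tmp_path / "t.csv", n_occasions=3)

    def test_metre_units_convert_to_km(self, tmp_path):
        df = pd.DataFrame({"station_id": ["a", "b"], "x": [0, 2100.0],
                           "y": [0, 0.0]})
        df.to_csv(tmp_path / "t.csv", index=False)
        traps = b.read_traps(tmp_path / "t.csv", n_occasions=2, units="m")
        assert traps.x[1] == pytest.approx(2.1)


class TestReadEncounters:
    @pytest.fixture
    def traps(self, tmp_path):
        return b.read_traps(_write_traps_csv(tmp_path / "t.csv", n=5), n_occasions=4)

    def test_long_records_collapse_duplicates(self, tmp_path, traps):
        df = pd.DataFrame({
            "individual_id": ["L1", "L1", "L1", "L2"],
            "station_id": ["s0", "s0", "s1", "s3"],
            "occasion": [1, 1, 2, 4],
        })
        df.to_csv(tmp_path / "e.csv", index=False)
        enc = b.read_encounters(tmp_path / "e.csv", traps)
        assert enc.n == 2
        assert enc.y.sum() == 3  # duplicate (L1, s0, 1) collapsed to a single 1
        assert list(enc.sex) == ["U", "U"]

    def test_wide_layout_equals_long(self, tmp_path, traps):
        long = pd.DataFrame({"individual_id": ["a", "a", "b"],
                             "station_id": ["s1", "s2", "s0"],
                             "occasion": [2, 3, 1]})
        long.to_csv(tmp_path / "long.csv", index=False)
        wide = pd.DataFrame({
            "individual_id": ["a", "a", "b"],
            "station_id": ["s1", "s2", "s0"],
            "occ_1": [0, 0, 1], "occ_2": [1, 0, 0], "occ_3": [0, 1, 0],
            "occ_4": [0, 0, 0],
        })
        wide.to_csv(tmp_path / "wide.csv", index=False)
        e1 = b.read_encounters(tmp_path / "long.csv", traps)
        e2 = b.read_encounters(tmp_path / "wide.csv", traps)
        assert np.array_equal(e1.y, e2.y)

    def test_sex_merge_defaults_unknown(self, tmp_path, traps):
        pd.DataFrame({"individual_id": ["a", "b"], "station_id": ["s0", "s1"],
                      "occasion": [1, 2]}).to_csv(tmp_path / "e.csv", index=False)
        pd.DataFrame({"individual_id": ["a"], "sex": ["f"]}).to_csv(
            tmp_path / "sex.csv", index=False)
        enc = b.read_encounters(tmp_path / "e.csv", traps, sex_path=tmp_path / "sex.csv")
        assert list(enc.sex) == ["F", "U"]

    def test_unknown_station_rejected(self, tmp_path, traps):
        pd.DataFrame({"individual_id": ["a"], "station_id": ["nope"],
                      "occasion": [1]}).to_csv(tmp_path / "e.csv", index=False)
        with pytest.raises(KeyError, match="nope"):
            b.read_encounters(tmp_path / "e.csv", traps)

    def test_detection_at_dead_trap_night_rejected(self, tmp_path):
        effort = np.ones((5, 4), dtype=int)
        effort[2, 0] = 0
        traps = b.read_traps(_write_traps_csv(tmp_path / "t.csv", n=5, effort=effort))
        pd.DataFrame({"individual_id": ["a"], "station_id": ["s2"],
                      "occasion": [1]}).to_csv(tmp_path / "e.csv", index=False)
        with pytest.raises(ValueError, match="non-functional"):
            b.read_encounters(tmp_path / "e.csv", traps)


class TestReadMask:
    def test_small_mask_counts_habitat(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "# pixel_area_km2=1.0\nx,y,habitat\n0,0,1\n1,0,1\n2,0,0\n")
        mask = b.read_mask(tmp_path / "m.csv")
        assert mask.n_pixels == 3 and mask.n_habitat == 2

    def test_580m_grid_has_printed_pixel_area(self, tmp_path):
        xs, ys = np.meshgrid(np.arange(5) * 0.58, np.arange(4) * 0.58)
        df = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(), "habitat": 1})
        df.to_csv(tmp_path / "m.csv", index=False)
        with pytest.warns(UserWarning, match="inferred"):
            mask = b.read_mask(tmp_path / "m.csv")
        assert mask.pixel_area == pytest.approx(0.3364, abs=1e-6)

    def test_missing_habitat_column_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("x,y\n0,0\n")
        with pytest.raises(ValueError, match="habitat"):
            b.read_mask(tmp_path / "m.csv")

    def test_all_non_habitat_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("# pixel_area_km2=1\nx,y,habitat\n0,0,0\n1,0,0\n")
        with pytest.raises(ValueError, match="habitat"):
            b.read_mask(tmp_path / "m.csv")


class TestRoundTrips:
    def test_fixture_files_round_trip(self, tmp_path):
        traps, mask, enc, truth = b.make_lmnp_fixture(
            seed=5, pixel_km=2.0, buffer_km=4.0, k_occasions=10)
        b.write_traps(traps, tmp_path / "traps.csv")
        b.write_encounters(enc, traps, tmp_path / "enc.csv", sex_path=tmp_path / "sex.csv")
        b.write_mask(mask, tmp_path / "mask.csv")
        traps2 = b.read_traps(tmp_path / "traps.csv")
        enc2 = b.read_encounters(tmp_path / "enc.csv", traps2,
                                 sex_path=tmp_path / "sex.csv")
        mask2 = b.read_mask(tmp_path / "mask.csv")
        assert np.array_equal(traps2.effort, traps.effort)
        assert np.allclose(traps2.x, traps.x) and np.allclose(traps2.y, traps.y)
        order = np.argsort(enc.individual_id)
        assert np.array_equal(enc2.y, enc.y[order])
        assert list(enc2.sex) == list(enc.sex[order])
        assert mask2.pixel_area == pytest.approx(mask.pixel_area)
        assert np.array_equal(mask2.habitat, mask.habitat)
        assert list(mask2.region) == list(mask.region)

    def test_geometry_validation(self):
        traps, mask, *_ = b.make_lmnp_fixture(seed=1, pixel_km=2.0, buffer_km=4.0,
                                              k_occasions=5)
        b.validate_geometry(traps, mask)  # fine as constructed
        far = b.TrapArray(traps.station_id, traps.x + 500, traps.y, traps.effort)
        with pytest.raises(ValueError, match="bounding box"):
            b.validate_geometry(far, mask)

    def test_recentre_shifts_jointly(self):
        traps, mask, *_ = b.make_lmnp_fixture(seed=1, pixel_km=2.0, buffer_km=4.0,
                                              k_occasions=5)
        t2, m2 = b.recentre(traps, mask)
        assert abs(t2.x.mean()) < 1e-9 and abs(t2.y.mean()) < 1e-9
        # relative geometry preserved
        assert np.allclose(t2.x[0] - m2.x[0], traps.x[0] - mask.x[0])


class TestChainIO:
    def test_written_table_shape_and_round_trip(self, tmp_path, coarse_chain,
                                                coarse_survey):
        chain = coarse_chain[0]
        path = tmp_path / "chain.csv"
        b.write_chain(chain, path, include_latents=True)
        df = pd.read_csv(path)
        # 7 parameters + one realized-N column per region (park, buffer)
        assert df.shape == (chain.n_draws, 9)
        back = b.read_chain(path)
        assert np.array_equal(back.params, chain.params)
        assert np.array_equal(back.region_counts["park"], chain.region_counts["park"])
        assert np.array_equal(back.s_draws, chain.s_draws)
        assert back.spec == chain.spec
        assert back.fingerprint == chain.fingerprint

    def test_empty_chain_rejected(self, tmp_path, coarse_chain):
        import copy

        empty = copy.copy(coarse_chain[0])
        empty.params = empty.params[:0]
        with pytest.raises(ValueError, match="empty"):
            b.write_chain(empty, tmp_path / "c.csv")
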