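"""Geometry descriptors: BLA, dihedrals, distortion indices, conformer
classification, hop channels and photoisomerization detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyhop.geometry import (DihedralError, build_chain, characterize_hops,
                              classify_conformer, compute_bla,
                              compute_dihedral, describe_frame,
                              detect_photoisomerization, distortion_index,
                              distortion_index_geometry, lutein_like_topology)

import oracles


def alternating_chain(single=1.45, double=1.35, torsions=None):
    """All-trans 22-atom chain matching lutein_like_topology bond parity
    (odd bonds single, even bonds double)."""
    lengths = [single if k % 2 == 1 else double for k in range(21)]
    if torsions is None:
        torsions = [180.0] * 19
    return build_chain(lengths, torsions)


def random_rigid_transform(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
    shift = rng.normal(0.0, 10.0, 3)
    return lambda c: c @ rot.T + shift


class TestBLA:
    def test_constructed_alternating_chain(self, topology):
        coords = alternating_chain(1.45, 1.35)
        assert compute_bla(coords, topology) == pytest.approx(0.10, abs=1e-9)

    def test_all_equal_bonds_give_zero(self, topology):
        coords = alternating_chain(1.40, 1.40)
        assert compute_bla(coords, topology) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_sum_oracle_on_random_chain(self, topology, rng):
        lengths = rng.uniform(1.30, 1.50, 21)
        torsions = rng.uniform(-180.0, 180.0, 19)
        coords = build_chain(lengths, torsions)
        ref = oracles.bla_direct(coords, topology.single_bonds,
                                 topology.double_bonds)
        assert compute_bla(coords, topology) == pytest.approx(ref, abs=1e-12)

    def test_rigid_transform_invariance(self, topology, rng):
        coords = alternating_chain()
        ref = compute_bla(coords, topology)
        for _ in range(3):
            moved = random_rigid_transform(rng)(coords)
            assert compute_bla(moved, topology) == pytest.approx(ref,
                                                                 abs=1e-9)

    def test_empty_bond_list_raises(self, topology):
        import dataclasses
        bad = dataclasses.replace(topology, single_bonds=[])
        with pytest.raises(ValueError):
            compute_bla(alternating_chain(), bad)


class TestDihedral:
    def test_planar_trans_is_180(self):
        coords = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                           [1.0, 0.0, 0.0], [1.0, -1.0, 0.0]])
        assert compute_dihedral(coords, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        coords = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                           [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        assert compute_dihedral(coords, (0, 1, 2, 3)) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_matches_atan2_oracle_on_random_coords(self, rng):
        for _ in range(10):
            coords = rng.normal(0.0, 2.0, (4, 3))
            try:
                got = compute_dihedral(coords, (0, 1, 2, 3))
            except DihedralError:
                continue
            ref = oracles.dihedral_atan2(*coords)
            assert got == pytest.approx(ref, abs=1e-10)

    def test_collinear_raises(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                           [2.0, 0.0, 0.0], [3.0, 1.0, 0.0]])
        with pytest.raises(DihedralError):
            compute_dihedral(coords, (0, 1, 2, 3))

    def test_range_is_half_open(self, rng):
        for _ in range(20):
            coords = rng.normal(0.0, 1.5, (4, 3))
            try:
                ang = compute_dihedral(coords, (0, 1, 2, 3))
            except DihedralError:
                continue
            assert -180.0 < ang <= 180.0

    def test_rigid_transform_invariance(self, rng):
        coords = rng.normal(0.0, 2.0, (4, 3))
        ref = compute_dihedral(coords, (0, 1, 2, 3))
        moved = random_rigid_transform(rng)(coords)
        assert compute_dihedral(moved, (0, 1, 2, 3)) == pytest.approx(
            ref, abs=1e-9)


class TestDistortionIndex:
    def test_all_planar_gives_zero(self):
        assert distortion_index([180.0] * 9) == 0.0
        assert distortion_index([0.0, 180.0, -180.0]) == pytest.approx(
            0.0, abs=1e-15)

    def test_all_90_gives_one(self):
        assert distortion_index([90.0] * 4) == pytest.approx(1.0)
        assert distortion_index([-90.0] * 4) == pytest.approx(1.0)

    def test_matches_per_term_oracle(self, rng):
        angles = rng.uniform(-180.0, 180.0, 9)
        ref = sum(1.0 - abs(np.cos(np.radians(a))) for a in angles) / 9
        assert distortion_index(angles) == pytest.approx(ref, abs=1e-14)

    def test_total_d_lies_between_lum_and_strom_for_mean_form(self, topology,
                                                              rng):
        torsions = rng.uniform(-25.0, 25.0, 19) + 180.0
        coords = build_chain([1.4] * 21, torsions)
        d_all = distortion_index_geometry(coords, topology, "all")
        d_lum = distortion_index_geometry(coords, topology, "lumenal")
        d_str = distortion_index_geometry(coords, topology, "stromal")
        assert min(d_lum, d_str) - 1e-12 <= d_all <= max(d_lum, d_str) + 1e-12

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            distortion_index([])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-179.9, 180.0), min_size=1, max_size=12))
    def test_bounded_in_unit_interval(self, angles):
        assert 0.0 <= distortion_index(angles) <= 1.0


class TestConformerClassification:
    @pytest.mark.parametrize("ds2,expected", [
        (178.0, "s-trans"), (5.0, "s-cis"), (90.0, "s-trans"),
        (-178.0, "s-trans"), (-89.9, "s-cis"), (180.0, "s-trans"),
    ])
    def test_classification_rule(self, ds2, expected):
        assert classify_conformer(ds2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_conformer(-180.0)


class TestCharacterizeHops:
    def fixture_table(self):
        """38 BLA-channel hops, 33 before 2 ps (plus unrelated hops)."""
        rows = []
        for i in range(38):
            t = 500.0 + i * 40.0 if i < 33 else 3000.0 + i * 500.0
            rows.append({"time": t, "from_state": 1, "to_state": 0,
                         "bla": -0.03, "d_lum": 0.05, "conformer": "s-trans"})
        for i in range(10):  # distortion-channel hops
            rows.append({"time": 800.0 + i * 100.0, "from_state": 1,
                         "to_state": 0, "bla": 0.0, "d_lum": 0.15,
                         "conformer": "s-trans"})
        for i in range(5):   # upper-state hops must be ignored
            rows.append({"time": 150.0, "from_state": 2, "to_state": 1,
                         "bla": np.nan, "d_lum": np.nan,
                         "conformer": "s-trans"})
        return pd.DataFrame(rows)

    def test_within_cutoff_percentage_rounds_to_87(self):
        _, summary = characterize_hops(self.fixture_table())
        ch = summary["bla_channel"]
        assert ch["n"] == 38
        assert ch["n_within_cutoff"] == 33
        assert ch["pct_within_cutoff"] == 87

    def test_no_hops_yields_empty_table_and_zero_counts(self):
        table, summary = characterize_hops(pd.DataFrame(
            columns=["time", "from_state", "to_state", "bla", "d_lum"]))
        assert len(table) == 0
        assert summary["n_hops"] == 0

    def test_counts_match_independent_filter_oracle(self, rng):
        n = 300
        df = pd.DataFrame({
            "time": rng.uniform(0.0, 15000.0, n),
            "from_state": np.ones(n, int), "to_state": np.zeros(n, int),
            "bla": rng.normal(-0.01, 0.02, n),
            "d_lum": np.abs(rng.normal(0.07, 0.05, n))})
        table, summary = characterize_hops(df)
        n_bla = int(((df["bla"] < -0.02)).sum())
        n_dist = int(((df["d_lum"] > 0.10) & (df["bla"] >= -0.02)).sum())
        assert summary["bla_channel"]["n"] == n_bla
        assert summary["distortion_channel"]["n"] == n_dist
        assert int(table["bla_channel"].sum()) == n_bla

    def test_channels_are_disjoint(self, rng):
        df = pd.DataFrame({
            "time": rng.uniform(0.0, 15000.0, 200),
            "from_state": np.ones(200, int), "to_state": np.zeros(200, int),
            "bla": rng.normal(-0.02, 0.02, 200),
            "d_lum": np.abs(rng.normal(0.1, 0.05, 200))})
        table, _ = characterize_hops(df)
        assert not np.any(table["bla_channel"] & table["distortion_channel"])


class TestPhotoisomerization:
    def test_thermal_fluctuation_produces_no_events(self, rng):
        series = 180.0 - np.abs(rng.normal(0.0, 12.0, 2000))
        assert detect_photoisomerization(series, dwell_frames=20) == []

    def test_constructed_switch_gives_one_event(self):
        series = np.concatenate([np.full(200, 178.0), np.full(300, 2.0)])
        events = detect_photoisomerization({"dd3": series}, dwell_frames=50)
        assert len(events) == 1
        name, frame, frm, to = events[0]
        assert (name, frame, frm, to) == ("dd3", 200, "trans", "cis")

    def test_brief_excursion_below_dwell_not_counted(self):
        series = np.concatenate([np.full(100, 175.0), np.full(10, 20.0),
                                 np.full(100, 175.0)])
        assert detect_photoisomerization(series, dwell_frames=30) == []

    def test_random_walk_matches_bruteforce_oracle(self, rng):
        series = 120.0 + np.cumsum(rng.normal(0.0, 8.0, 1500))
        got = detect_photoisomerization(series, dwell_frames=25)
        ref = oracles.basin_switches_bruteforce(series, 25)
        assert [(f, a, b) for (_, f, a, b) in got] == ref


class TestDescribeFrame:
    def test_full_descriptor_set_on_twisted_chain(self, topology):
        torsions = [180.0] * 19
        torsions[2] = 150.0   # ds2 quartet is atoms (2,3,4,5) -> torsion idx 2
        coords = build_chain(
            [1.45 if k % 2 == 1 else 1.35 for k in range(21)], torsions)
        d = describe_frame(coords, topology)
        assert d.conformer == "s-trans"
        assert d.ds["ds2"] == pytest.approx(150.0, abs=1e-6)
        assert 0.0 <= d.d_lum <= 1.0 and 0.0 <= d.d_strom <= 1.0
        assert d.bla == pytest.approx(0.10, abs=1e-9)
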