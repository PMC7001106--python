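"""Density maps, site detection, distance traces, contact durations."""
import numpy as np
import pandas as pd
import pytest

from memsite.core import Role
from memsite.mapping import (DensityMap, contact_events, contact_table_report,
                             detect_sites, distance_to_site_series,
                             occupancy_density, read_contact_table,
                             residue_contact_durations)

from conftest import make_system, make_traj


class TestOccupancyDensity:
    def test_static_particle_single_voxel(self):
        coords = np.tile([[1.23, 4.56, 2.0]], (100, 1, 1))
        traj = make_traj(coords, box=(5.0, 5.0, 5.0))
        dmap = occupancy_density(traj, spacing=0.1)
        assert dmap.values.max() == pytest.approx(1.0)
        assert np.count_nonzero(dmap.values) == 1

    def test_alternating_particle_half_half(self):
        a, b = [1.05, 1.05, 1.05], [3.05, 3.05, 3.05]
        coords = np.array([[a], [b]] * 10)
        traj = make_traj(coords, box=(5.0, 5.0, 5.0))
        dmap = occupancy_density(traj, spacing=0.1)
        nz = sorted(dmap.values[dmap.values > 0])
        assert nz == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_grid_sum_is_mean_particle_count(self, rng):
        # brute-force tally: per-frame deposits sum to the selection size
        coords = rng.uniform(0, 5, size=(50, 7, 3))
        traj = make_traj(coords, box=(5.0, 5.0, 5.0))
        dmap = occupancy_density(traj, spacing=0.25)
        assert dmap.values.sum() == pytest.approx(7.0, abs=1e-9)

    def test_sum_conserved_under_subsampling(self, rng):
        coords = rng.uniform(0, 5, size=(40, 5, 3))
        traj = make_traj(coords, box=(5.0, 5.0, 5.0))
        from memsite.core import Trajectory

        sub = Trajectory(system=traj.system, times=traj.times[::4],
                         coords=traj.coords[::4])
        for t in (traj, sub):
            dmap = occupancy_density(t, spacing=0.2)
            assert dmap.values.sum() == pytest.approx(5.0, abs=1e-9)

    def test_bad_spacing_and_empty_selection(self, rng):
        traj = make_traj(rng.uniform(0, 5, (3, 2, 3)), box=(5, 5, 5))
        with pytest.raises(ValueError, match="spacing"):
            occupancy_density(traj, spacing=0.0)
        with pytest.raises(ValueError, match="selection"):
            occupancy_density(traj, {"species": "NOPE"})


def _map_from(values):
    return DensityMap(origin=np.zeros(3), spacing=0.1,
                      values=np.asarray(values, dtype=float), n_frames=1)


class TestDetectSites:
    def test_single_gaussian_blob(self):
        x, y, z = np.mgrid[0:20, 0:20, 0:5]
        blob = np.exp(-((x - 10.0) ** 2 + (y - 7.0) ** 2 + (z - 2.0) ** 2) / 4)
        sites = detect_sites(_map_from(blob), threshold=0.5)
        assert len(sites) == 1
        assert tuple(np.argwhere(blob == blob.max())[0]) == (10, 7, 2)
        # center of mass sits at the mode voxel's center
        assert np.allclose(sites[0].center, [1.05, 0.75, 0.25], atol=0.02)

    def test_uniform_map_single_component(self):
        sites = detect_sites(_map_from(np.ones((4, 4, 4))), threshold=1.0)
        assert len(sites) == 1
        assert len(sites[0].voxels) == 64

    def test_six_connectivity(self):
        # two diagonal voxels are NOT connected under face adjacency
        v = np.zeros((4, 4, 1))
        v[1, 1, 0] = 1.0
        v[2, 2, 0] = 1.0
        sites = detect_sites(_map_from(v), threshold=0.5)
        assert len(sites) == 2

    def test_four_synthetic_blobs(self):
        v = np.zeros((30, 30, 3))
        for cx, cy in [(7, 15), (15, 7), (23, 15), (15, 23)]:
            x, y = np.mgrid[0:30, 0:30]
            v[:, :, 1] += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / 2)
        sites = detect_sites(_map_from(v), threshold=0.5)
        assert len(sites) == 4

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_sites(_map_from(np.ones((2, 2, 2))), threshold=0.0)

    def test_min_peak_floor(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 0.05
        assert detect_sites(_map_from(v), min_peak=0.1) == []
        assert len(detect_sites(_map_from(v), min_peak=0.01)) == 1


class TestDistanceSeries:
    def _system(self, lipid_xyz, anchor_xyz=(0.0, 0.0, 3.0), box=(10, 10, 6)):
        coords = np.array([anchor_xyz, lipid_xyz])
        return make_system(coords,
                           roles=[Role.SITE_ANCHOR, Role.LIPID_HEAD],
                           species=["ANCHOR", "PIP2"],
                           chains=["A", "inner"], box=box)

    def test_lipid_at_anchor_is_zero(self):
        sys_ = self._system([0.0, 0.0, 1.0])
        from memsite.core import Trajectory

        traj = Trajectory(system=sys_, times=[0.0, 1.0],
                          coords=np.tile(sys_.coordinates, (2, 1, 1)))
        series = distance_to_site_series(traj, {"species": "PIP2"})
        assert np.allclose(series.distances, 0.0)

    def test_min_image_across_boundary(self):
        # anchor at origin, lipid at (L - 0.5, 0): distance 0.5 nm
        sys_ = self._system([9.5, 0.0, 1.0])
        from memsite.core import Trajectory

        traj = Trajectory(system=sys_, times=[0.0],
                          coords=sys_.coordinates[None])
        series = distance_to_site_series(traj, {"species": "PIP2"})
        assert series.distances[0, 0] == pytest.approx(0.5)

    def test_planar_projection_ignores_z(self):
        sys_ = self._system([1.0, 0.0, 0.0])  # dz = 3 ignored
        from memsite.core import Trajectory

        traj = Trajectory(system=sys_, times=[0.0],
                          coords=sys_.coordinates[None])
        series = distance_to_site_series(traj, {"species": "PIP2"})
        assert series.distances[0, 0] == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        sys_ = self._system([1.0, 1.0, 1.0])
        from memsite.core import Trajectory

        traj = Trajectory(system=sys_, times=[0.0],
                          coords=sys_.coordinates[None])
        with pytest.raises(ValueError, match="empty"):
            distance_to_site_series(traj, {"species": "CHOL"})


def brute_force_durations(distances, on, off, dt=1.0):
    """Independent state machine written longhand."""
    events, run, bound = [], 0, False
    for d in distances:
        if bound:
            if d > off:
                events.append(run * dt)
                run, bound = 0, False
            else:
                run += 1
        if not bound and d < on:
            bound, run = True, 1
    if bound:
        events.append(run * dt)
    return events


class TestContactDurations:
    def _traj_from_distances(self, distances, dt=1.0):
        """Residue particle at origin; lipid moves along x by script."""
        F = len(distances)
        coords = np.zeros((F, 2, 3))
        coords[:, 1, 0] = distances
        coords[:, :, 2] = 1.0
        return make_traj(coords, dt=dt,
                         roles=[Role.PROTEIN, Role.LIPID_HEAD],
                         species=["PROT", "PIP2"],
                         labels=["R504", ""], chains=["A", "inner"],
                         box=(50.0, 50.0, 10.0))

    def test_scripted_pattern(self):
        # 10 ns in, 5 ns out, 5 ns in (dt = 1 ns) -> events [10, 5]
        d = [0.3] * 10 + [1.5] * 5 + [0.3] * 5
        traj = self._traj_from_distances(d)
        table = residue_contact_durations(traj, "PIP2", 0.55, 1.0)
        row = table.iloc[0]
        assert row["n_events"] == 2
        assert row["max_duration"] == pytest.approx(10.0)
        assert row["mean_duration"] == pytest.approx(7.5)

    def test_always_bound_single_full_event(self):
        traj = self._traj_from_distances([0.2] * 20)
        row = residue_contact_durations(traj, "PIP2", 0.55, 1.0).iloc[0]
        assert row["n_events"] == 1
        assert row["mean_duration"] == pytest.approx(20.0)
        assert row["occupancy"] == pytest.approx(1.0)

    def test_never_bound(self):
        traj = self._traj_from_distances([2.0] * 20)
        row = residue_contact_durations(traj, "PIP2", 0.55, 1.0).iloc[0]
        assert row["n_events"] == 0
        assert row["mean_duration"] == 0.0

    def test_rattling_within_cutoffs_not_split(self):
        # excursions between on and off must not close the event
        d = [0.3, 0.8, 0.3, 0.8, 0.3]
        traj = self._traj_from_distances(d)
        row = residue_contact_durations(traj, "PIP2", 0.55, 1.0).iloc[0]
        assert row["n_events"] == 1
        assert row["mean_duration"] == pytest.approx(5.0)

    def test_cutoff_inversion_rejected(self):
        traj = self._traj_from_distances([0.3] * 3)
        with pytest.raises(ValueError):
            residue_contact_durations(traj, "PIP2", 1.0, 0.55)

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(30):
            d = rng.uniform(0.1, 2.0, size=60)
            got = contact_events(d < 0.55, d > 1.0)
            expect = brute_force_durations(d, 0.55, 1.0)
            assert [float(g) for g in got] == expect

    def test_total_duration_monotone_in_off_cutoff(self, rng):
        # widening the off cutoff can only merge/extend events
        for _ in range(20):
            steps = rng.normal(0, 0.15, size=80)
            d = np.abs(np.cumsum(steps) + 0.8)
            totals = [sum(contact_events(d < 0.4, d > off))
                      for off in (0.4, 0.6, 0.9, 1.3)]
            assert all(a <= b for a, b in zip(totals, totals[1:]))


class TestContactReport:
    def _table(self, means):
        return pd.DataFrame({
            "chain": ["A"] * len(means),
            "residue": [f"R{i}" for i in range(len(means))],
            "species": "PIP2", "mean_duration": means,
            "max_duration": means, "n_events": 1, "occupancy": 0.5,
        })

    def test_linear_scaling(self):
        out = contact_table_report(self._table([0.0, 5.0, 10.0]))
        assert list(out["color_scale"]) == [0.0, 0.5, 1.0]

    def test_all_equal_maps_to_one(self):
        out = contact_table_report(self._table([3.0, 3.0, 3.0]))
        assert list(out["color_scale"]) == [1.0, 1.0, 1.0]

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "c.tsv"
        out = contact_table_report(self._table([0.0, 4.0, 8.0]), path)
        back = read_contact_table(path)
        pd.testing.assert_frame_equal(back, out, check_dtype=False)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contact_table_report(pd.DataFrame())
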