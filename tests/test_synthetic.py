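"""Generator: composition rounding, planted wells, Brownian dynamics."""
import numpy as np
import pytest
from scipy.integrate import quad

from memsite.core import Role, min_image_distance
from memsite.dynamics import DynamicsParams, simulate
from memsite.potentials import GaussianWell, HarmonicPoint
from memsite.synthetic import (BilayerSpec, INNER_COMPOSITION,
                               OUTER_COMPOSITION, build_bilayer,
                               largest_remainder_counts,
                               make_geometry_fixtures,
                               make_planted_site_system)
from memsite.units import kBT


class TestComposition:
    def test_inner_leaflet_counts(self):
        # 10:40:15:10:25 over 200 lipids
        counts = largest_remainder_counts(INNER_COMPOSITION, 200)
        assert counts == {"PC": 20, "PE": 80, "PS": 30, "PIP2": 20, "CHOL": 50}

    def test_overall_pip2_five_percent(self):
        spec = BilayerSpec(lipids_per_leaflet=200)
        system = build_bilayer(spec, seed=0)
        pip2 = int(system.select(species="PIP2").sum())
        assert pip2 / system.n_particles == pytest.approx(0.05, abs=1e-12)

    def test_largest_remainder_conserves_total(self, rng):
        for _ in range(20):
            w = rng.uniform(0.01, 1, size=4)
            fracs = dict(zip("ABCD", w / w.sum()))
            n = int(rng.integers(1, 500))
            assert sum(largest_remainder_counts(fracs, n).values()) == n

    def test_single_species(self):
        spec = BilayerSpec(leaflets={"inner": {"POPC": 1.0}},
                           lipids_per_leaflet=37)
        system = build_bilayer(spec, seed=1)
        assert set(system.species) == {"POPC"}
        assert system.n_particles == 37

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            BilayerSpec(leaflets={"inner": {"POPC": 0.6, "POPS": 0.3}})

    def test_min_spacing_respected(self):
        spec = BilayerSpec(leaflets={"inner": {"POPC": 1.0}},
                           lipids_per_leaflet=50, box=(10.0, 10.0, 6.0))
        system = build_bilayer(spec, seed=3, min_spacing=0.4)
        xy = system.coordinates[:, :2]
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                d = min_image_distance(system.coordinates[i],
                                       system.coordinates[j], system.box)
                assert d >= 0.4 - 1e-9

    def test_build_deterministic(self):
        spec = BilayerSpec(lipids_per_leaflet=50)
        a = build_bilayer(spec, seed=7)
        b = build_bilayer(spec, seed=7)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestPlantedWells:
    def test_potential_at_anchor_equals_depth(self):
        system, pots = make_planted_site_system(depth=37.0, sigma=0.3)
        well = pots[0]
        assert well.energy(well.anchor) == pytest.approx(-37.0)

    def test_zero_depth_is_flat(self, rng):
        _, pots = make_planted_site_system(depth=0.0, sigma=0.3)
        xy = rng.uniform(0, 12, size=(50, 2))
        assert np.allclose(pots[0].energy(xy), 0.0)

    def test_four_fold_symmetry(self):
        system, pots = make_planted_site_system(depth=20.0, sigma=0.3,
                                                four_fold=True)
        centers = np.array([w.anchor for w in pots[:4]])
        box_center = system.box[:2] / 2
        r = np.linalg.norm(centers - box_center, axis=1)
        assert np.allclose(r, r[0])
        angles = np.sort(np.degrees(np.arctan2(*(centers - box_center).T[::-1])))
        assert np.allclose(np.diff(angles), 90.0)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            make_planted_site_system(depth=10.0, sigma=0.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            make_planted_site_system(depth=-5.0, sigma=0.3)


class TestDynamics:
    def test_zero_diffusion_freezes_everything(self):
        system, pots = make_planted_site_system(depth=10.0, sigma=0.3)
        params = DynamicsParams(D=0.0, n_steps=50, save_every=10, seed=0)
        traj = simulate(system, pots, params)
        assert np.allclose(traj.coords, traj.coords[0])

    def test_anchors_and_protein_never_move(self):
        system, pots = make_planted_site_system(
            depth=10.0, sigma=0.3, four_fold=True, with_protein=True,
            n_lipids=4)
        params = DynamicsParams(D=0.1, n_steps=200, save_every=50, seed=2)
        traj = simulate(system, pots, params)
        frozen = ~system.mobile_mask()
        assert np.allclose(traj.coords[:, frozen], traj.coords[0, frozen])

    def test_msd_matches_einstein_relation(self):
        # free 2D diffusion: ensemble MSD(t) = 4 D t
        from conftest import make_system

        n = 500
        system = make_system(np.full((n, 3), 50.0), box=(100.0, 100.0, 10.0))
        D = 0.1
        params = DynamicsParams(D=D, dt=0.01, n_steps=2000, save_every=200,
                                seed=11)
        traj = simulate(system, [], params)
        disp = traj.coords[:, :, :2] - traj.coords[0, :, :2]
        msd = np.mean(np.sum(disp**2, axis=2), axis=1)
        expected = 4 * D * traj.times
        assert np.allclose(msd[1:], expected[1:], rtol=0.10)

    def test_equipartition_in_harmonic_trap(self):
        from conftest import make_system

        system = make_system(np.array([[50.0, 50.0, 5.0]]),
                             box=(100.0, 100.0, 10.0))
        kappa = 100.0
        trap = HarmonicPoint(anchor=np.array([50.0, 50.0]), k=kappa)
        params = DynamicsParams(D=0.1, dt=0.01, n_steps=60_000, save_every=2,
                                seed=5)
        traj = simulate(system, [trap], params)
        var = traj.coords[5000:, 0, 0].var()
        assert var == pytest.approx(kBT(310.0) / kappa, rel=0.10)

    def test_seed_reproducibility(self):
        system, pots = make_planted_site_system(depth=15.0, sigma=0.3,
                                                n_lipids=3)
        params = DynamicsParams(n_steps=300, save_every=30, seed=42)
        a = simulate(system, pots, params)
        b = simulate(system, pots, params)
        assert np.array_equal(a.coords, b.coords)

    def test_composition_conserved(self):
        spec = BilayerSpec(lipids_per_leaflet=30)
        system = build_bilayer(spec, seed=0)
        before = {s: int(system.select(species=s).sum())
                  for s in set(system.species)}
        traj = simulate(system, [], DynamicsParams(n_steps=100, save_every=50))
        after = {s: int(traj.system.select(species=s).sum())
                 for s in set(traj.system.species)}
        assert before == after

    def test_stability_guard(self):
        system, pots = make_planted_site_system(depth=10.0, sigma=0.1)
        params = DynamicsParams(D=0.1, dt=0.1, n_steps=10, save_every=1)
        with pytest.raises(ValueError, match="unstable"):
            simulate(system, pots, params)

    def test_boltzmann_occupancy_in_planted_well(self):
        """Long unbiased runs reproduce the quadrature occupancy ratio
        between the well core (r < sigma) and a bulk annulus."""
        depth, sigma = 5.0, 0.3
        kT = kBT(310.0)
        system, pots = make_planted_site_system(
            depth=depth, sigma=sigma, box=(6.0, 6.0, 6.0), n_lipids=50,
            start="random", seed=9)
        params = DynamicsParams(D=0.1, dt=0.01, n_steps=30_000, save_every=10,
                                seed=9)
        traj = simulate(system, pots, params)
        lip = traj.system.select(role=Role.LIPID_HEAD)
        anchor = pots[0].anchor
        xy = traj.coords[500:, lip, :2]
        d = xy - anchor
        d -= 6.0 * np.floor(d / 6.0 + 0.5)
        r = np.hypot(d[..., 0], d[..., 1]).ravel()
        r_lo, r_hi = 1.5, 2.5
        observed = np.mean(r < sigma) / np.mean((r > r_lo) & (r < r_hi))

        boltz = lambda rr: rr * np.exp(depth * np.exp(-rr**2 / (2 * sigma**2)) / kT)
        core, _ = quad(boltz, 0, sigma)
        shell, _ = quad(boltz, r_lo, r_hi)
        # shell integral is clipped by the box corners beyond L/2; the
        # annulus chosen stays inside the inscribed circle at 2.5 < 3
        expected = core / shell
        assert observed == pytest.approx(expected, rel=0.25)


class TestGeometryFixtures:
    def test_hbond_fixture_has_two_bonds_by_construction(self):
        from memsite.geometry import HBondCriterion

        traj = make_geometry_fixtures("hbond")
        crit = HBondCriterion()
        coords = traj.coords[0]
        sys_ = traj.system
        donors = np.flatnonzero([s == "DON" for s in sys_.species])
        hydros = np.flatnonzero([s == "HYD" for s in sys_.species])
        accept = np.flatnonzero([s == "ACC" for s in sys_.species])
        # brute force over all D x A pairs with explicit geometry
        n = 0
        for d, h in zip(donors, hydros):
            for a in accept:
                dist = np.linalg.norm(coords[a] - coords[d])
                v1 = coords[h] - coords[d]
                v2 = coords[a] - coords[h]
                ang = np.degrees(np.arccos(
                    np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                            -1, 1)))
                if dist <= crit.max_distance and ang <= crit.max_angle:
                    n += 1
        assert n == 2

    def test_zero_drift_pose_fixture_is_static(self):
        from memsite.geometry import ligand_rmsd_series

        traj = make_geometry_fixtures("ligand_pose", drift=0.0, n_frames=20)
        series = ligand_rmsd_series(traj)
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_fixture_regeneration_deterministic(self):
        a = make_geometry_fixtures("ligand_pose", seed=3)
        b = make_geometry_fixtures("ligand_pose", seed=3)
        assert np.array_equal(a.coords, b.coords)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            make_geometry_fixtures("nonsense")
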