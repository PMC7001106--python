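"""Umbrella orchestration and the WHAM estimator."""
import numpy as np
import pytest

from memsite.potentials import GaussianWell
from memsite.protocols import recover_well_depth
from memsite.synthetic import make_planted_site_system
from memsite.umbrella import (ReactionCoordinate, UmbrellaSet, UmbrellaSpec,
                              generate_windows, run_umbrella_sampling,
                              window_overlap)
from memsite.units import kBT
from memsite.wham import (ConvergenceError, PMFResult, WHAM,
                          bootstrap_well_depth_error, convergence_by_duration,
                          ddg_from_pmfs, well_depth)

kT = kBT(310.0)


class TestWindows:
    def test_default_ladder(self):
        spec = UmbrellaSpec()
        centers = generate_windows(spec)
        assert len(centers) == 38
        assert centers[0] == pytest.approx(-0.7)
        assert centers[-1] == pytest.approx(3.0)
        assert np.allclose(np.diff(centers), 0.1)

    def test_two_windows(self):
        centers = generate_windows(UmbrellaSpec(n_windows=2))
        assert np.allclose(centers, [-0.7, 3.0])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaSpec(n_windows=1)


def _run(spec, depth=0.0, seed=0):
    system, pots = make_planted_site_system(depth=depth, sigma=0.3, seed=seed)
    rc = ReactionCoordinate.from_system(system)
    return run_umbrella_sampling(system, pots, rc, spec, seed=seed)


class TestUmbrellaSampling:
    def test_stiff_spring_limit(self):
        # k = 1e6 pins each window: per-window SD < 0.01 nm
        spec = UmbrellaSpec(n_windows=5, k=1e6, lateral_k=100.0,
                            steps_per_window=2000, dt=2e-6, min_samples=10)
        uset = _run(spec)
        assert np.all(uset.s.std(axis=1) < 0.01)

    def test_flat_landscape_equipartition(self):
        # sample variance of s ~ kT / k in every window
        spec = UmbrellaSpec(n_windows=6, steps_per_window=20_000)
        uset = _run(spec, depth=0.0, seed=3)
        assert np.allclose(uset.s.var(axis=1), kT / 500.0, rtol=0.15)

    def test_planted_well_windows_overlap(self):
        spec = UmbrellaSpec(steps_per_window=8000)
        uset = _run(spec, depth=37.0, seed=1)
        assert np.all(window_overlap(uset) >= 0.05)

    def test_unstable_dt_guard(self):
        spec = UmbrellaSpec(n_windows=3, k=1e6, steps_per_window=100,
                            dt=0.0025)
        with pytest.raises(ValueError, match="unstable"):
            _run(spec)

    def test_tsv_round_trip(self, tmp_path):
        spec = UmbrellaSpec(n_windows=4, steps_per_window=500, min_samples=10)
        uset = _run(spec, seed=2)
        path = tmp_path / "w.tsv"
        uset.to_tsv(path)
        back = UmbrellaSet.from_tsv(path)
        assert np.allclose(back.centers, uset.centers)
        assert np.allclose(back.s, uset.s, atol=1e-7)
        assert back.k == uset.k

    def test_no_tagged_lipid(self):
        system, pots = make_planted_site_system(depth=5.0, sigma=0.3,
                                                n_lipids=0)
        rc = ReactionCoordinate.from_system(system)
        with pytest.raises(ValueError, match="tagged"):
            run_umbrella_sampling(system, pots, rc, UmbrellaSpec())


def exact_biased_uset(a, centers, k, n, seed, temperature=310.0):
    """Samples drawn exactly from the biased Boltzmann densities of the
    quadratic landscape G(s) = a/2 s^2 -- the analytic WHAM oracle."""
    kT_ = kBT(temperature)
    rng = np.random.default_rng(seed)
    mean = k * centers / (a + k)
    sd = np.sqrt(kT_ / (a + k))
    s = mean[:, None] + sd * rng.standard_normal((len(centers), n))
    y = rng.standard_normal((len(centers), n))  # irrelevant lateral
    return UmbrellaSet(centers=centers, k=k, lateral_k=0.0, s=s, y=y,
                       temperature=temperature, dt=1.0)


class TestWHAM:
    def test_recovers_analytic_harmonic_landscape(self):
        a, k = 100.0, 500.0
        centers = np.linspace(-1.2, 1.2, 13)
        uset = exact_biased_uset(a, centers, k, n=20_000, seed=5)
        res = WHAM(uset, bin_width=0.04).fit()
        keep = res.counts > 500
        g = res.pmf[keep] - res.pmf[keep].min()
        expected = 0.5 * a * res.bins[keep] ** 2
        expected -= expected.min()
        assert np.max(np.abs(g - expected)) < 0.5

    def test_single_window_equals_direct_reweighting(self):
        a, k = 50.0, 200.0
        centers = np.array([0.3])
        uset = exact_biased_uset(a, centers, k, n=200_000, seed=8)
        res = WHAM(uset, bin_width=0.05).fit()
        # direct inversion: G = -kT ln rho + bias correction
        mids = res.bins
        hist, _ = np.histogram(uset.s[0],
                               bins=np.concatenate([mids - 0.025, [mids[-1] + 0.025]]))
        with np.errstate(divide="ignore"):
            direct = -kT * np.log(hist / hist.sum()) - 0.5 * k * (mids - 0.3) ** 2
        keep = hist > 200
        diff = (res.pmf - direct)[keep]
        assert np.max(diff) - np.min(diff) < 0.1  # equal up to a constant

    def test_flat_landscape_is_flat(self):
        uset = exact_biased_uset(0.0, np.linspace(-1, 1, 9), 500.0,
                                 n=20_000, seed=2)
        res = WHAM(uset, bin_width=0.05).fit()
        keep = res.counts > 500
        g = res.pmf[keep]
        assert np.max(g) - np.min(g) < 1.0

    def test_nonoverlapping_windows_reported(self):
        rng = np.random.default_rng(0)
        s = np.stack([rng.normal(-1.0, 0.01, 500), rng.normal(1.0, 0.01, 500)])
        uset = UmbrellaSet(centers=np.array([-1.0, 1.0]), k=500.0,
                           lateral_k=0.0, s=s, y=np.zeros_like(s),
                           temperature=310.0, dt=1.0)
        with pytest.raises(ConvergenceError, match="gap"):
            WHAM(uset).fit()


def _toy_profile(values, bins=None):
    values = np.asarray(values, dtype=float)
    bins = np.arange(len(values), dtype=float) if bins is None else bins
    return PMFResult(bins=bins, pmf=values, window_f=np.zeros(1),
                     temperature=310.0, n_iter=1, converged=True)


class TestWellDepth:
    def test_toy_profile(self):
        prof = _toy_profile([0.0, -5.0, -10.0, -3.0, 0.0, 0.0])
        # bulk = last two bins
        assert well_depth(prof, bulk_interval=(3.5, 5.5)) == pytest.approx(-10.0)

    def test_flat_profile_zero(self):
        prof = _toy_profile([2.0] * 6)
        assert well_depth(prof, bulk_interval=(3.5, 5.5)) == pytest.approx(0.0)

    def test_bulk_outside_profile(self):
        prof = _toy_profile([0.0, -1.0])
        with pytest.raises(ValueError, match="bulk"):
            well_depth(prof, bulk_interval=(10.0, 11.0))

    def test_ddg_arithmetic(self):
        # printed depths -37/-20 and -37/-28 give +17 and +9
        pip2 = _toy_profile([0.0, -37.0, 0.0, 0.0])
        pip = _toy_profile([0.0, -20.0, 0.0, 0.0])
        pip3 = _toy_profile([0.0, -28.0, 0.0, 0.0])
        bulk = (1.5, 3.5)
        assert ddg_from_pmfs(pip2, pip, bulk) == pytest.approx(17.0)
        assert ddg_from_pmfs(pip2, pip3, bulk) == pytest.approx(9.0)
        assert ddg_from_pmfs(pip2, pip2, bulk) == pytest.approx(0.0)


class TestConvergenceAndErrors:
    def test_identical_halves_zero_deviation(self):
        rng = np.random.default_rng(4)
        centers = np.linspace(-0.5, 0.5, 6)
        half = rng.normal(centers[:, None], 0.07, size=(6, 400))
        s = np.concatenate([half, half], axis=1)
        uset = UmbrellaSet(centers=centers, k=500.0, lateral_k=0.0, s=s,
                           y=np.ones_like(s) + 0.01 * np.concatenate(
                               [half, half], axis=1),
                           temperature=310.0, dt=1.0)
        cps, profiles, dev = convergence_by_duration(
            uset, [800, 400], bulk_interval=(0.3, 0.5),
            lateral_correction=False)
        assert cps == [400, 800]  # sorted internally
        assert dev[0] == pytest.approx(0.0, abs=1e-9)

    def test_checkpoint_exceeding_data(self):
        uset = exact_biased_uset(0.0, np.linspace(0, 1, 3), 500.0, n=100,
                                 seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            convergence_by_duration(uset, [1000], bulk_interval=(0.8, 1.0))

    def test_deviation_shrinks_with_sampling(self):
        spec = UmbrellaSpec(steps_per_window=60_000)
        system, pots = make_planted_site_system(depth=20.0, sigma=0.3, seed=6)
        rc = ReactionCoordinate.from_system(system)
        uset = run_umbrella_sampling(system, pots, rc, spec, seed=6)
        _, _, dev = convergence_by_duration(uset, [2000, 6000, 45_000, 15_000])
        assert dev[-1] < dev[0]

    def test_zero_variance_bootstrap_error_is_zero(self):
        s = np.full((3, 200), 1.0)
        uset = UmbrellaSet(centers=np.array([0.9, 1.0, 1.1]), k=500.0,
                           lateral_k=0.0, s=s, y=np.zeros_like(s),
                           temperature=310.0, dt=1.0)
        err = bootstrap_well_depth_error(uset, n_boot=4, seed=0,
                                         bulk_interval=(0.5, 1.5),
                                         lateral_correction=False)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_tracks_repeat_run_spread(self):
        """Block-bootstrap SD within a factor ~2 of the SD over
        independent repeat simulations."""
        spec = UmbrellaSpec(steps_per_window=15_000)
        depths = [recover_well_depth(9.0, spec=spec, seed=s).recovered_depth
                  for s in range(8)]
        repeat_sd = np.std(depths, ddof=1)
        est = recover_well_depth(9.0, spec=spec, seed=100)
        boot_sd = bootstrap_well_depth_error(est.uset, n_boot=12, seed=1)
        assert boot_sd / repeat_sd < 2.5
        assert repeat_sd / boot_sd < 2.5


def test_pmf_plot_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    prof = _toy_profile([0.0, -5.0, -10.0, -3.0, 0.0, 0.0])
    ax = prof.plot()
    assert ax.get_ylabel().startswith("G")
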