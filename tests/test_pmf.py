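import numpy as np
import pytest

import oxmem
from oxmem.pmf import (DiffusionProfile, PMFError, PMFProfile,
                       diffusion_from_force_autocorrelation,
                       equilibration_trim, make_window_schedule, permeability,
                       wham)
from oxmem.synthetic import gen_force_series, gen_umbrella_samples
from oxmem.trajectory import WindowSeries
from oxmem.units import CM2_S_TO_NM2_PS, R_KJ, kT as kT_of

KT = kT_of(298.0)


def _two_well(z):
    z = np.asarray(z, float)
    return (20.0 * np.exp(-z ** 2 / (2 * 0.8 ** 2))
            - 4.0 * np.exp(-(z - 2.0) ** 2 / (2 * 0.3 ** 2))
            - 4.0 * np.exp(-(z + 2.0) ** 2 / (2 * 0.3 ** 2)))


def _windows(n_per=5000, seed=0, span=(4.0, -4.0)):
    sched = make_window_schedule(span[0], span[1], 0.2, 100.0)
    return gen_umbrella_samples(_two_well, sched.centers,
                                sched.force_constant, n_per, KT, seed=seed)


def _anchored_reference(prof, G):
    ref = G(prof.z)
    bulk = (prof.z >= prof.z[-1] - 0.5) & np.isfinite(prof.dG)
    return ref - ref[bulk].mean()


class TestSchedule:
    def test_default_is_40_windows(self):
        s = make_window_schedule()
        assert len(s.centers) == 40
        assert s.centers[0] == 4.0 and s.centers[-1] == pytest.approx(-3.8)
        assert s.force_constant == 100.0

    def test_direction_and_errors(self):
        up = make_window_schedule(-1.0, 1.0, 0.5)
        assert np.allclose(up.centers, [-1.0, -0.5, 0.0, 0.5])
        with pytest.raises(PMFError):
            make_window_schedule(1.0, 1.0, 0.5)
        with pytest.raises(PMFError):
            make_window_schedule(0.0, 1.0, -0.5)
        with pytest.raises(PMFError):
            make_window_schedule(0.0, 0.1, 0.5)


class TestTrim:
    def test_drops_leading_fraction(self):
        w = WindowSeries(0.0, 100.0, np.arange(10.0), np.arange(10.0),
                         forces=np.arange(10.0))
        t = equilibration_trim(w, 0.5)
        assert t.n_samples == 5 and t.positions[0] == 5.0
        assert t.forces[0] == 5.0

    def test_bad_fraction(self):
        w = WindowSeries(0.0, 100.0, np.arange(10.0), np.arange(10.0))
        with pytest.raises(PMFError):
            equilibration_trim(w, 1.0)
        with pytest.raises(PMFError):
            equilibration_trim(w, -0.1)


class TestWHAM:
    def test_recovers_two_well_profile(self):
        windows, _ = _windows(20000, seed=1)
        prof = wham(windows, KT)
        ref = _anchored_reference(prof, _two_well)
        core = np.isfinite(prof.dG) & (prof.z >= -3.8) & (prof.z <= 4.0)
        assert np.abs(prof.dG[core] - ref[core]).max() < 0.5
        assert prof.barrier_height("bulk") == pytest.approx(20.0, abs=0.5)
        # interfacial wells recovered at the right place and depth
        well = core & (np.abs(np.abs(prof.z) - 2.0) < 0.3)
        assert prof.dG[well].min() == pytest.approx(ref[well].min(),
                                                    abs=0.5)

    def test_barrier_height_references(self):
        z = np.linspace(-4, 4, 161)
        dG = 20.0 * np.exp(-z ** 2) - 3.0 * np.exp(-(z - 2) ** 2)
        prof = PMFProfile(z, dG, np.zeros_like(z))
        assert prof.barrier_height("bulk") == pytest.approx(dG.max())
        assert prof.barrier_height("minimum") == pytest.approx(
            dG.max() - dG.min())
        with pytest.raises(PMFError):
            prof.barrier_height("sea-level")

    def test_invariant_under_window_reordering(self):
        windows, _ = _windows(3000, seed=2)
        a = wham(windows, KT, tol=1e-9)
        rng = np.random.default_rng(0)
        b = wham([windows[i] for i in rng.permutation(len(windows))], KT,
                 tol=1e-9)
        assert np.allclose(a.dG, b.dG, atol=1e-6, equal_nan=True)

    def test_invariant_under_constant_pmf_offset(self):
        # G and G + c define identical biased densities, hence identical
        # anchored profiles from identical seeds
        sched = make_window_schedule()
        w1, _ = gen_umbrella_samples(_two_well, sched.centers, 100.0, 2000,
                                     KT, seed=12)
        w2, _ = gen_umbrella_samples(lambda z: _two_well(z) + 25.0,
                                     sched.centers, 100.0, 2000, KT, seed=12)
        a = wham(w1, KT)
        b = wham(w2, KT)
        assert np.allclose(a.dG, b.dG, atol=1e-9, equal_nan=True)

    def test_anchor_follows_pull_start_side(self):
        down, _ = _windows(3000, seed=3, span=(4.0, -4.0))
        up, _ = _windows(3000, seed=3, span=(-4.0, 4.0))
        pd_ = wham(down, KT)
        pu = wham(up, KT)
        # started at +4: anchored near the top; started at -4: near the bottom
        top = pd_.z >= pd_.z[-1] - 0.5
        bot = pu.z <= pu.z[0] + 0.5
        assert abs(np.nanmean(pd_.dG[top])) < 1e-9
        assert abs(np.nanmean(pu.dG[bot])) < 1e-9

    def test_gap_detection(self):
        sched = make_window_schedule()
        keep = [w for w in _windows(2000, seed=4)[0]
                if not (-1.3 < w.window_center < 1.3)]
        assert len(keep) < len(sched.centers)
        with pytest.raises(PMFError, match="gap"):
            wham(keep, KT)

    def test_monotone_error_decrease_with_samples(self):
        # the dominant error is a random walk of window free energies, so a
        # single realization need not be monotone: average over seeds, with
        # 10x sample-size steps
        errs = []
        for n in (500, 5000, 50000):
            rms = []
            for seed in range(4):
                windows, _ = _windows(n, seed=100 + seed)
                prof = wham(windows, KT)
                ref = _anchored_reference(prof, _two_well)
                core = np.isfinite(prof.dG) & (np.abs(prof.z) <= 3.8)
                rms.append(np.sqrt(np.mean(
                    (prof.dG[core] - ref[core]) ** 2)))
            errs.append(np.mean(rms))
        assert errs[0] > errs[1] > errs[2]

    def test_non_convergence_reported(self):
        windows, _ = _windows(1000, seed=6)
        with pytest.raises(PMFError, match="converge"):
            wham(windows, KT, max_iter=3)

    def test_no_windows(self):
        with pytest.raises(PMFError, match="no windows"):
            wham([], KT)


class TestDiffusionProfile:
    def test_ou_recovery(self):
        windows, truth = gen_force_series(
            [4e-4, 8e-4], 298.0, tau=1.0, n=100_000, dt=0.2, seed=7,
            centers=np.array([0.0, 1.0]))
        prof = diffusion_from_force_autocorrelation(windows, 298.0)
        assert np.allclose(prof.D, truth.D_of_z, rtol=0.10)

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(8)
        w = WindowSeries(0.0, 0.0, np.arange(5000) * 0.2, np.zeros(5000),
                         forces=rng.normal(size=5000))
        with pytest.raises(PMFError, match="white-noise"):
            diffusion_from_force_autocorrelation([w], 298.0)

    def test_missing_forces_rejected(self):
        w = WindowSeries(0.0, 0.0, np.arange(10.0), np.zeros(10))
        with pytest.raises(PMFError, match="no forces"):
            diffusion_from_force_autocorrelation([w], 298.0)

    def test_unknown_policy(self):
        with pytest.raises(PMFError, match="policy"):
            diffusion_from_force_autocorrelation([], 298.0, policy="magic")

    def test_exp_tail_close_to_zero_crossing(self):
        windows, _ = gen_force_series(5e-4, 298.0, tau=1.0, n=50_000,
                                      dt=0.2, seed=9, centers=np.array([0.0]))
        a = diffusion_from_force_autocorrelation(windows, 298.0)
        b = diffusion_from_force_autocorrelation(windows, 298.0,
                                                 policy="exp_tail")
        assert b.D[0] == pytest.approx(a.D[0], rel=0.1)


class TestPermeability:
    def _flat(self, L=8.0, nbins=401):
        z = np.linspace(-L / 2, L / 2, nbins)
        pmf = PMFProfile(z, np.zeros(nbins), np.zeros(nbins))
        D = 1e-5 * CM2_S_TO_NM2_PS
        dprof = DiffusionProfile(z, np.full(nbins, D), np.zeros(nbins))
        return pmf, dprof

    def test_flat_profile_equals_D_over_L(self):
        pmf, dprof = self._flat()
        res = permeability(pmf, dprof, T=298.0, bounds=(-4.0, 4.0))
        assert res.P == pytest.approx(12.5, rel=1e-6)
        assert res.recompute() == pytest.approx(res.P, rel=1e-12)

    def test_mirror_symmetry(self):
        z = np.linspace(-4, 4, 401)
        dG = 15.0 * np.exp(-(z - 0.7) ** 2)  # asymmetric barrier
        D = np.full_like(z, 1e-3) + 1e-4 * z  # asymmetric D
        a = permeability(PMFProfile(z, dG, 0 * z),
                         DiffusionProfile(z, D, 0 * z))
        b = permeability(PMFProfile(z, dG[::-1], 0 * z),
                         DiffusionProfile(z, D[::-1], 0 * z))
        assert a.P == pytest.approx(b.P, rel=1e-12)

    def test_higher_barrier_lower_P(self):
        z = np.linspace(-4, 4, 401)
        D = np.full_like(z, 1e-3)
        lo = permeability(PMFProfile(z, 10 * np.exp(-z ** 2), 0 * z),
                          DiffusionProfile(z, D, 0 * z))
        hi = permeability(PMFProfile(z, 30 * np.exp(-z ** 2), 0 * z),
                          DiffusionProfile(z, D, 0 * z))
        assert hi.P < lo.P

    def test_unsampled_bins_rejected(self):
        pmf, dprof = self._flat()
        pmf.dG[100] = np.nan
        with pytest.raises(PMFError, match="unsampled"):
            permeability(pmf, dprof)

    def test_coverage_check(self):
        pmf, dprof = self._flat()
        narrow = DiffusionProfile(dprof.z[100:300], dprof.D[100:300],
                                  dprof.acf_integral[:200]
                                  if dprof.acf_integral.size else
                                  np.zeros(200))
        with pytest.raises(PMFError, match="spans"):
            permeability(pmf, narrow)

    def test_nonpositive_D_rejected(self):
        pmf, dprof = self._flat()
        dprof.D[5] = 0.0
        with pytest.raises(PMFError, match="non-positive"):
            permeability(pmf, dprof)
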