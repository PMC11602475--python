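import math

import numpy as np
import pytest

import oxmem
from oxmem.synthetic import (SyntheticError, gen_brownian_membrane,
                             gen_force_series, gen_hbond_fixture,
                             gen_layered_bilayer, gen_ordered_chains,
                             gen_umbrella_samples)
from oxmem.units import R_KJ, UM2_S_TO_NM2_PS


class TestBrownian:
    def test_step_statistics_match_target(self, native):
        D = {name: 3.0 for name in native.species_counts()}
        traj, truth = gen_brownian_membrane(native, D, n_frames=400,
                                            dt=50.0, seed=4)
        tracks = truth.extras["unwrapped_tracks"]
        steps = np.diff(tracks, axis=0)
        var = steps.var()
        assert var == pytest.approx(2 * 3.0 * UM2_S_TO_NM2_PS * 50.0,
                                    rel=0.05)

    def test_drift_imposed(self, native):
        D = {name: 1.0 for name in native.species_counts()}
        traj, truth = gen_brownian_membrane(
            native, D, n_frames=500, dt=100.0,
            leaflet_drift={"outer": (2e-3, 0.0)}, seed=5)
        tracks = truth.extras["unwrapped_tracks"]
        outer = traj.atoms["leaflet"].to_numpy() == "outer"
        vx = (tracks[-1, outer, 0] - tracks[0, outer, 0]).mean() \
            / (traj.times[-1] - traj.times[0])
        assert vx == pytest.approx(2e-3, rel=0.2)

    def test_determinism(self, native):
        D = {name: 1.0 for name in native.species_counts()}
        a, _ = gen_brownian_membrane(native, D, 10, 1.0, seed=6)
        b, _ = gen_brownian_membrane(native, D, 10, 1.0, seed=6)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_parameter_validation(self, native):
        D = {name: 1.0 for name in native.species_counts()}
        with pytest.raises(SyntheticError):
            gen_brownian_membrane(native, D, 1, 1.0)
        with pytest.raises(SyntheticError):
            gen_brownian_membrane(native, D, 10, -1.0)
        with pytest.raises(SyntheticError, match="POPC"):
            bad = dict(D)
            bad.pop("POPC")
            gen_brownian_membrane(native, bad, 10, 1.0)


class TestOrderedChains:
    def test_skeletal_tilt_is_exact(self):
        frame, atoms, truth = gen_ordered_chains(20, 16, 25.0, 0.0, seed=1)
        # every C(j-1)->C(j+1) vector makes exactly 25 deg with -z (outer)
        for c in range(20):
            sel = atoms[(atoms["resid"] == c + 1)
                        & atoms["name"].str.startswith("C")]
            order = sel["name"].str.lstrip("C").astype(int).argsort()
            pos = frame.coordinates[sel.index.to_numpy()[order]]
            v = pos[2:] - pos[:-2]
            cos = (v @ np.array([0, 0, -1.0])) / np.linalg.norm(v, axis=1)
            assert np.allclose(np.degrees(np.arccos(cos)), 25.0, atol=1e-9)

    def test_expected_scd_in_truth(self):
        _, _, truth = gen_ordered_chains(5, 10, 30.0, 0.0)
        assert truth.extras["expected_scd"] == pytest.approx(0.625)
        _, _, t2 = gen_ordered_chains(5, 10, "isotropic", 0.0)
        assert t2.extras["expected_scd"] is None

    def test_gauche_disorders_chains(self):
        _, atoms, _ = gen_ordered_chains(5, 16, 0.0, 0.5, seed=2)
        assert len(atoms) == 5 * 17  # P + 16 carbons

    def test_validation(self):
        with pytest.raises(SyntheticError):
            gen_ordered_chains(5, 10, 120.0)
        with pytest.raises(SyntheticError):
            gen_ordered_chains(5, 10, "sideways")


class TestLayeredBilayer:
    def test_layer_means_and_mirroring(self):
        layers = {"phosphate": {"z_mean": 2.26, "sigma": 0.15,
                                "n_per_leaflet": 200, "mass": 94.97}}
        traj, _ = gen_layered_bilayer(layers, n_frames=50, seed=3)
        z = traj.coordinates[:, :, 2]
        inner = traj.atoms["leaflet"].to_numpy() == "inner"
        assert z[:, inner].mean() == pytest.approx(-2.26, abs=0.01)
        assert z[:, ~inner].mean() == pytest.approx(2.26, abs=0.01)

    def test_water_exclusion_slab(self):
        layers = {"phosphate": {"z_mean": 2.0, "sigma": 0.1,
                                "n_per_leaflet": 10, "mass": 94.97}}
        traj, _ = gen_layered_bilayer(layers, n_frames=20, n_waters=200,
                                      water_exclusion_halfwidth=2.8, seed=4)
        w = traj.atoms["species"].to_numpy() == "water"
        assert np.all(np.abs(traj.coordinates[:, w, 2]) >= 2.8)

    def test_validation(self):
        with pytest.raises(SyntheticError):
            gen_layered_bilayer({"x": {"z_mean": 1, "sigma": 0,
                                       "n_per_leaflet": 1, "mass": 1}}, 5)
        with pytest.raises(SyntheticError, match="slab"):
            gen_layered_bilayer(
                {"x": {"z_mean": 1, "sigma": 0.1, "n_per_leaflet": 1,
                       "mass": 1}}, 5, n_waters=5,
                water_exclusion_halfwidth=10.0)


class TestUmbrellaSamples:
    def test_sample_moments_match_biased_density(self):
        kT = 2.577
        G = lambda z: 10.0 * z ** 2  # noqa: E731
        windows, truth = gen_umbrella_samples(G, [0.0], 100.0, 100_000, kT,
                                              seed=5)
        # combined bias: (10 + 50) z^2 -> Gaussian with var = kT / 120
        var = kT / (2 * (10.0 + 50.0))
        assert windows[0].positions.mean() == pytest.approx(
            0.0, abs=4 * math.sqrt(var / 1e5))
        assert windows[0].positions.var() == pytest.approx(var, rel=0.02)
        grid, pdf = truth.biased_densities[0]
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, rel=1e-6)

    def test_zero_force_constant_needs_span(self):
        with pytest.raises(SyntheticError, match="span"):
            gen_umbrella_samples(lambda z: 0 * z, [0.0], 0.0, 10, 2.5)
        windows, _ = gen_umbrella_samples(lambda z: 0 * z, [0.0], 0.0, 1000,
                                          2.5, span=(-1.0, 1.0), seed=6)
        assert np.all(np.abs(windows[0].positions) <= 1.0)

    def test_non_finite_pmf_rejected(self):
        with pytest.raises(SyntheticError, match="finite"):
            gen_umbrella_samples(lambda z: np.where(z > 0, np.inf, 0.0),
                                 [0.0], 100.0, 10, 2.5)


class TestForceSeries:
    def test_autocovariance_matches_target(self):
        T, tau, dt = 298.0, 2.0, 0.2
        windows, truth = gen_force_series(1e-3, T, tau, 200_000, dt, seed=7)
        f = windows[0].forces
        sigma2 = (R_KJ * T) ** 2 / (1e-3 * tau)
        assert f.var() == pytest.approx(sigma2, rel=0.02)
        lag1 = np.mean((f[:-1] - f.mean()) * (f[1:] - f.mean()))
        assert lag1 / f.var() == pytest.approx(math.exp(-dt / tau), rel=0.02)

    def test_scalar_target_broadcasts_over_centers(self):
        windows, truth = gen_force_series(5e-4, 298.0, 1.0, 100, 0.2,
                                          centers=np.array([0.0, 1.0, 2.0]))
        assert len(windows) == 3
        assert len(truth.D_of_z) == 3

    def test_under_resolved_rejected(self):
        with pytest.raises(SyntheticError, match="under-resolved"):
            gen_force_series(1e-3, 298.0, tau=0.1, n=100, dt=0.2)

    def test_mismatched_targets_rejected(self):
        with pytest.raises(SyntheticError):
            gen_force_series([1e-3, 2e-3], 298.0, 1.0, 100, 0.2,
                             centers=np.array([0.0]))


class TestHBondFixture:
    def test_planted_counts(self):
        frame, donors, acceptors, atoms = gen_hbond_fixture(12, 7, seed=8)
        assert len(donors) == 19 and len(acceptors) == 19
        bonds = oxmem.detect_hbonds(frame, donors, acceptors)
        assert len(bonds) == 12

    def test_zero_margin_rejected(self):
        with pytest.raises(SyntheticError, match="margin"):
            gen_hbond_fixture(1, 1, dist_margin=0.0)
        with pytest.raises(SyntheticError, match="margin"):
            gen_hbond_fixture(1, 1, angle_margin=0.0)

    def test_overfull_box_rejected(self):
        with pytest.raises(SyntheticError, match="box"):
            gen_hbond_fixture(500, 500, box=(3.0, 3.0, 3.0))


def test_truth_serializes_to_json(native):
    D = {name: 1.0 for name in native.species_counts()}
    _, truth = gen_brownian_membrane(native, D, 5, 1.0)
    import json
    parsed = json.loads(truth.to_json())
    assert parsed["seed"] == 0
    assert "unwrapped_tracks" in parsed["extras"]
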