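import numpy as np
import pandas as pd
import pytest

import oxmem
from oxmem.structure import (StructureError, area_per_lipid, assign_leaflets,
                             chain_angles, chain_indices_from_atoms,
                             deuterium_order_parameter, mass_density_profile,
                             membrane_thickness, pooled_fatty_acid_average,
                             profile_peak_shift, water_zone_counts)
from oxmem.synthetic import gen_layered_bilayer, gen_ordered_chains
from oxmem.units import AMU_PER_NM3_TO_KG_M3


def _layered(z_mean=2.26, n=300, frames=100, seed=0, **kw):
    layers = {"phosphate": {"z_mean": z_mean, "sigma": 0.15,
                            "n_per_leaflet": n, "mass": 94.97}}
    return gen_layered_bilayer(layers, frames, seed=seed, **kw)[0]


class TestDensityProfile:
    def test_total_mass_conserved(self):
        traj = _layered()
        prof = mass_density_profile(traj, {"phosphate": "phosphate"})
        area = traj.boxes[0, 0] * traj.boxes[0, 1]
        integrated = prof.densities["phosphate"].sum() * prof.bin_width \
            * area / AMU_PER_NM3_TO_KG_M3
        assert integrated == pytest.approx(600 * 94.97, rel=1e-6)

    def test_gaussian_shape_recovered(self):
        traj = _layered(frames=300, seed=1)
        prof = mass_density_profile(traj, {"phosphate": "phosphate"})
        y = prof.densities["phosphate"]
        # two symmetric peaks near +-2.26
        z_pk = prof.bin_centers[np.argmax(y * (prof.bin_centers > 0))]
        assert z_pk == pytest.approx(2.26, abs=0.05)

    def test_selection_forms_equivalent(self):
        traj = _layered(frames=5)
        mask = (traj.atoms["species"] == "phosphate").to_numpy()
        idx = np.flatnonzero(mask)
        a = mass_density_profile(traj, {"p": "phosphate"})
        b = mass_density_profile(traj, {"p": mask})
        c = mass_density_profile(traj, {"p": idx})
        assert np.array_equal(a.densities["p"], b.densities["p"])
        assert np.array_equal(a.densities["p"], c.densities["p"])

    def test_empty_selection_rejected(self):
        traj = _layered(frames=2)
        with pytest.raises(StructureError, match="empty"):
            mass_density_profile(traj, {"x": "nonexistent"})

    def test_bad_bin_width(self):
        traj = _layered(frames=2)
        with pytest.raises(StructureError):
            mass_density_profile(traj, {"p": "phosphate"}, bin_width=0.0)


class TestThickness:
    def test_peak_recovery(self):
        traj = _layered(z_mean=2.26, n=400, frames=200, seed=2)
        prof = mass_density_profile(traj, {"phosphate": "phosphate"})
        res = membrane_thickness(prof, "phosphate")
        assert res.thickness == pytest.approx(4.52, abs=prof.bin_width)
        assert res.leaflet_thickness["inner"] == pytest.approx(2.26,
                                                               abs=0.05)

    def test_peak_shift_sign_convention(self):
        a = mass_density_profile(_layered(2.26, frames=200, seed=3),
                                 {"p": "phosphate"})
        b = mass_density_profile(_layered(2.10, frames=200, seed=4),
                                 {"p": "phosphate"})
        shift = profile_peak_shift(a, b, "p")
        # B's peaks moved toward the center: positive by convention
        assert shift["inner"] == pytest.approx(0.16, abs=0.05)
        assert shift["outer"] == pytest.approx(0.16, abs=0.05)

    def test_flat_profile_has_no_peak(self):
        traj = _layered(frames=2)
        prof = mass_density_profile(traj, {"p": "phosphate"})
        flat = dict(prof.densities)
        flat["p"] = np.ones_like(flat["p"])
        prof.densities = flat
        with pytest.raises(StructureError, match="peak"):
            membrane_thickness(prof, "p")


class TestWaterZones:
    def test_zone_occupancy(self):
        traj = _layered(frames=30, n_waters=500,
                        water_exclusion_halfwidth=2.8, seed=5)
        zones = water_zone_counts(traj, "water", zone_width=0.4, n_zones=6)
        # all waters sit beyond |z| = 2.8 nm: zones 1..6 cover |z| < 2.4
        assert zones.to_numpy().sum() == 0
        zones2 = water_zone_counts(traj, "water", zone_width=0.8, n_zones=6)
        assert zones2.to_numpy().sum() > 0
        assert zones2[["zone1", "zone2", "zone3"]].to_numpy().sum() == 0


class TestAreaPerLipid:
    def test_counts_exclude_cholesterol(self, native):
        frame, atoms = oxmem.place_toy_coordinates(native, (15.0, 15.0, 8.0),
                                                   seed=1)
        traj = oxmem.Trajectory(frame.coordinates[None], frame.box[None],
                                np.array([0.0]), atoms)
        _, apl_in = area_per_lipid(traj, "inner")
        assert apl_in == pytest.approx(15.0 * 15.0 / 107)  # 157 - 50 CHOL
        _, apl_all = area_per_lipid(traj, "inner", include_cholesterol=True)
        assert apl_all == pytest.approx(15.0 * 15.0 / 157)

    def test_unknown_leaflet(self, native):
        frame, atoms = oxmem.place_toy_coordinates(native, (15.0, 15.0, 8.0))
        traj = oxmem.Trajectory(frame.coordinates[None], frame.box[None],
                                np.array([0.0]), atoms)
        with pytest.raises(StructureError):
            area_per_lipid(traj, "middle")


class TestOrderParameter:
    @pytest.mark.parametrize("tilt,expected", [(0.0, 1.0), (30.0, 0.625),
                                               (90.0, -0.5)])
    def test_analytic_tilts(self, tilt, expected):
        frame, atoms, _ = gen_ordered_chains(30, 16, tilt, 0.0, seed=6)
        chains = chain_indices_from_atoms(atoms)
        prof = deuterium_order_parameter(frame, chains)
        assert np.abs(prof.table["scd"].to_numpy() - expected).max() < 1e-12

    def test_rotation_about_z_invariance(self):
        frame, atoms, _ = gen_ordered_chains(10, 14, 35.0, 0.0, seed=7)
        chains = chain_indices_from_atoms(atoms)
        a = deuterium_order_parameter(frame, chains).table["scd"].to_numpy()
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        frame.coordinates = frame.coordinates @ R.T
        b = deuterium_order_parameter(frame, chains).table["scd"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    def test_internal_carbons_only(self):
        frame, atoms, _ = gen_ordered_chains(5, 16, 0.0, 0.0)
        prof = deuterium_order_parameter(frame,
                                         chain_indices_from_atoms(atoms))
        carbons = sorted(prof.table["carbon"].unique())
        assert carbons == list(range(2, 16))  # j = 2..n-1

    def test_short_chain_rejected(self):
        frame, atoms, _ = gen_ordered_chains(2, 16, 0.0, 0.0)
        with pytest.raises(StructureError, match="3 carbons"):
            deuterium_order_parameter(frame, {"x": [np.array([0, 1])]})

    def test_bounds_for_disordered_chains(self):
        frame, atoms, _ = gen_ordered_chains(50, 16, "isotropic", 0.4,
                                             seed=8)
        prof = deuterium_order_parameter(frame,
                                         chain_indices_from_atoms(atoms))
        s = prof.table["scd"].to_numpy()
        assert np.all(s >= -0.5 - 1e-12) and np.all(s <= 1.0 + 1e-12)

    def test_per_chain_average_and_pooling(self):
        frame, atoms, _ = gen_ordered_chains(10, 16, 30.0, 0.0, seed=9)
        prof = deuterium_order_parameter(frame,
                                         chain_indices_from_atoms(atoms))
        avg = prof.per_chain_average()
        assert avg["scd"].iloc[0] == pytest.approx(0.625)
        pooled = pooled_fatty_acid_average(prof, {"all": ["CHN"]})
        assert pooled["scd"].iloc[0] == pytest.approx(0.625)


class TestChainAngles:
    def _markers(self, n, leaflet="outer"):
        # outer leaflet: inward normal is -z; tails pointing straight down
        P = np.column_stack([np.arange(n, dtype=float), np.zeros(n),
                             np.full(n, 2.0)])
        down = np.array([0, 0, -1.8])
        return {
            "P": P, "sn1_ch3": P + down, "sn2_ch3": P + down,
            "sn1_cooh": P + np.array([0, 0, -0.2]),
            "sn2_cooh": P + np.array([0, 0, -0.2]),
        }, np.array([leaflet] * n)

    def test_straight_down_chain_angles(self):
        markers, leaf = self._markers(8)
        res = chain_angles(markers, leaf,
                           pivots={"1": markers["P"] + [0, 0, -1.0]})
        s = res.summary.set_index("angle")["mean"]
        assert s["alpha1"] == pytest.approx(0.0, abs=1e-9)
        assert s["beta"] == pytest.approx(0.0, abs=1e-9)
        assert s["gamma1"] == pytest.approx(180.0, abs=1e-9)
        assert s["gamma2_1"] == pytest.approx(180.0, abs=1e-9)
        assert s["delta1"] == pytest.approx(0.0, abs=1e-9)

    def test_inner_leaflet_normal_flips(self):
        markers, _ = self._markers(4)
        # same geometry tagged inner: inward normal +z, so alpha = 180
        res = chain_angles(markers, np.array(["inner"] * 4))
        s = res.summary.set_index("angle")["mean"]
        assert s["alpha1"] == pytest.approx(180.0, abs=1e-9)

    def test_nan_rows_skipped_and_counted(self):
        markers, leaf = self._markers(10)
        markers["sn1_ch3"][0] = np.nan
        res = chain_angles(markers, leaf)
        row = res.summary[(res.summary["angle"] == "alpha1")]
        assert int(row["n"].iloc[0]) == 9
        assert res.skipped >= 1

    def test_too_many_missing_rejected(self):
        markers, leaf = self._markers(10)
        markers["sn1_ch3"][:] = np.nan
        markers["sn2_ch3"][:] = np.nan
        markers["sn1_cooh"][:] = np.nan
        with pytest.raises(StructureError, match="missing"):
            chain_angles(markers, leaf)

    def test_cholesterol_axis(self):
        markers, leaf = self._markers(4)
        chol = {"o3": np.zeros((3, 3)) + [0, 0, 2.0],
                "c17": np.zeros((3, 3)) + [0, 0, 1.0],
                "leaflet": np.array(["outer"] * 3)}
        res = chain_angles(markers, leaf, cholesterol=chol)
        s = res.summary.set_index("angle")["mean"]
        assert s["alpha3"] == pytest.approx(0.0, abs=1e-9)


class TestAssignLeaflets:
    def test_toy_membrane(self, native):
        frame, atoms = oxmem.place_toy_coordinates(native, (15.0, 15.0, 8.0),
                                                   seed=3)
        traj = oxmem.Trajectory(frame.coordinates[None], frame.box[None],
                                np.array([0.0]), atoms)
        tags = assign_leaflets(traj)
        assert (tags == atoms["leaflet"]).all()

    def test_no_heads_rejected(self):
        traj = _layered(frames=2)
        with pytest.raises(StructureError, match="head"):
            assign_leaflets(traj)
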