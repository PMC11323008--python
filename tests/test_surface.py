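"""SASA, hydrogen bonds, contact maps and the (Rg, SASA) density."""

import numpy as np
import pytest

from coedecomp import (Ensemble, PerResidueMatrix, assign_rg_groups,
                       detect_hydrogen_bonds, hbond_map, normalized_sasa,
                       radius_of_gyration, residue_distance_map, residue_sasa,
                       sasa_per_group, sasa_rg_density, shrake_rupley_sasa)
from coedecomp.ensemble_io import Topology
from coedecomp.rg import RgGroupSet
from conftest import random_rigid_motion


def atom_topology(elements, res_index=None, names=None, radii=None):
    n = len(elements)
    res_index = np.ones(n, dtype=int) if res_index is None else np.asarray(res_index)
    names = list(elements) if names is None else names
    resnames = ["GLY"] * int(res_index.max())
    topo = Topology(names, list(elements), res_index, resnames)
    if radii is not None:
        topo.vdw_radius = np.asarray(radii, dtype=float)
    return topo


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        topo = atom_topology(["O"], radii=[1.5])
        area = shrake_rupley_sasa(np.zeros((1, 3)), topo, 1.4, 960)[0]
        assert area == pytest.approx(4 * np.pi * 2.9 ** 2, rel=0.02)

    def test_additivity_at_infinite_separation(self):
        topo = atom_topology(["O", "N"], radii=[1.5, 1.6])
        frame = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = shrake_rupley_sasa(frame, topo, 1.4, 960)
        assert areas[0] == pytest.approx(4 * np.pi * 2.9 ** 2, rel=0.02)
        assert areas[1] == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.02)

    def test_fully_caged_atom_has_zero_area(self):
        # 26-point cage of large spheres surrounding a small central atom
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        cage = np.array([2.4 * o / np.linalg.norm(o) for o in offsets])
        frame = np.vstack([[0.0, 0.0, 0.0], cage])
        topo = atom_topology(["C"] * len(frame), radii=[1.2] + [1.9] * len(cage))
        areas = shrake_rupley_sasa(frame, topo, 1.4, 960)
        assert areas[0] == 0.0

    def test_point_count_convergence(self, helix_frame, hst5_topology):
        lo = shrake_rupley_sasa(helix_frame, hst5_topology, 1.4, 480).sum()
        hi = shrake_rupley_sasa(helix_frame, hst5_topology, 1.4, 960).sum()
        assert abs(hi - lo) / hi < 0.01

    def test_rigid_motion_invariance(self, helix_frame, hst5_topology):
        # the quadrature lattice is fixed in space, so invariance holds to
        # within the point-sampling error; totals converge much faster
        ref = shrake_rupley_sasa(helix_frame, hst5_topology, 1.4, 960)
        rng = np.random.default_rng(5)
        R, t = random_rigid_motion(rng)
        moved = shrake_rupley_sasa(helix_frame @ R.T + t, hst5_topology, 1.4, 960)
        assert moved.sum() == pytest.approx(ref.sum(), rel=0.01)
        np.testing.assert_allclose(moved, ref, atol=3.0)

    def test_residue_sum_equals_atom_sum(self, helix_frame, hst5_topology):
        per_res = residue_sasa(helix_frame, hst5_topology, 1.4, 240)
        per_atom = shrake_rupley_sasa(helix_frame, hst5_topology, 1.4, 240)
        assert per_res.sum() == pytest.approx(per_atom.sum(), abs=1e-9)

    def test_agreement_with_mdtraj(self, helix_frame, hst5_topology, tmp_path):
        md = pytest.importorskip("mdtraj")
        from coedecomp import write_pdb_ensemble
        ens = Ensemble(helix_frame[None], hst5_topology)
        p = tmp_path / "h.pdb"
        write_pdb_ensemble(ens, p)
        theirs = md.shrake_rupley(md.load(str(p)), mode="residue",
                                  n_sphere_points=960)[0] * 100.0
        ours = residue_sasa(helix_frame, hst5_topology, 1.4, 960)
        # different vdW radius tables; agreement to a few percent
        np.testing.assert_allclose(ours, theirs, rtol=0.05)


class TestNormalizedSasa:
    def _observed(self, values, groups=(10, 12)):
        values = np.asarray(values, dtype=float)
        return PerResidueMatrix(values, np.zeros_like(values),
                                [f"G{i+1}" for i in range(values.shape[0])],
                                list(groups))

    def test_observed_equals_expected_gives_zero(self):
        obs = self._observed(np.full((2, 2), 104.0))
        norm = normalized_sasa(obs, ["GLY", "GLY"])
        np.testing.assert_allclose(norm.values, 0.0)
        np.testing.assert_allclose(norm.variance, 0.0)

    def test_offset_in_one_group_shows_in_that_column(self):
        obs = self._observed([[104.0, 114.0], [104.0, 104.0]])
        norm = normalized_sasa(obs, ["GLY", "GLY"])
        np.testing.assert_allclose(norm.values, [[0.0, 10.0], [0.0, 0.0]])
        assert norm.variance[0, 0] > 0
        assert norm.variance[1, 0] == 0.0

    def test_missing_residue_type_rejected(self):
        obs = self._observed(np.full((1, 2), 1.0))
        with pytest.raises(KeyError):
            normalized_sasa(obs, ["XXX"])

    def test_normalized_sasa_rises_with_group_rg(self, mixed_ensemble):
        from scipy.stats import spearmanr
        sub = Ensemble(mixed_ensemble.coords[:200], mixed_ensemble.topology)
        groups = assign_rg_groups(sub)
        labels = [l for l in groups.labels if len(groups.members[l]) >= 5]
        obs = sasa_per_group(sub, groups, labels, n_sphere_points=240)
        norm = normalized_sasa(obs, sub.topology.residue_name)
        means = norm.values.mean(axis=0)
        rho, _ = spearmanr(labels, means)
        assert rho > 0.8


class TestSasaRgDensity:
    def test_integral_is_one(self):
        rng = np.random.default_rng(0)
        rg = rng.normal(13, 2, 400)
        sasa = rng.normal(2000, 150, 400)
        x, y, dens = sasa_rg_density(sasa, rg)
        dx = x[1] - x[0]
        dy = y[1] - y[0]
        assert dens.sum() * dx * dy == pytest.approx(1.0, abs=0.01)

    def test_two_separated_clouds_are_bimodal(self):
        rng = np.random.default_rng(1)
        rg = np.concatenate([rng.normal(9, 0.3, 200), rng.normal(18, 0.3, 200)])
        sasa = np.concatenate([rng.normal(1500, 30, 200), rng.normal(2500, 30, 200)])
        x, y, dens = sasa_rg_density(sasa, rg)
        ridge = dens.max(axis=1)
        peaks = [i for i in range(1, len(ridge) - 1)
                 if ridge[i] > ridge[i - 1] and ridge[i] > ridge[i + 1]]
        assert len(peaks) >= 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="jitter|variance"):
            sasa_rg_density(np.ones(10), np.arange(10.0))


def two_residue_hbond_frame(distance=2.9, angle_deg=0.0):
    """Donor N-H of residue 1 aimed at acceptor O (residue 3 numbering gap)."""
    topo = Topology(["N", "H", "CA", "C", "O", "N", "H", "CA", "C", "O"],
                    ["N", "H", "C", "C", "O", "N", "H", "C", "C", "O"],
                    np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]), ["GLY", "GLY"])
    frame = np.zeros((10, 3))
    frame[2] = (0.0, 1.4, 0.0)    # CA1
    frame[3] = (0.5, 2.6, 0.0)    # C1
    frame[4] = (1.6, 3.1, 0.0)    # O1
    ang = np.radians(angle_deg)
    frame[1] = (np.cos(ang), -np.sin(ang), 0.0)  # H on N, tilted by angle
    frame[5] = (distance, 0.0, 0.0)              # acceptor N2
    frame[6] = (distance, -1.0, 0.0)
    frame[7] = (distance + 1.2, 0.8, 0.0)
    frame[8] = (distance + 2.0, 2.0, 0.0)
    frame[9] = (distance + 3.1, 2.2, 0.0)
    return frame, topo


class TestHydrogenBonds:
    def test_ideal_linear_geometry_detected(self):
        frame, topo = two_residue_hbond_frame(2.9, 0.0)
        bonds = detect_hydrogen_bonds(frame, topo)
        assert any(d == 0 and a == 5 for d, _, a in bonds)

    def test_long_distance_not_detected(self):
        frame, topo = two_residue_hbond_frame(4.0, 0.0)
        assert not any(d == 0 and a == 5 for d, _, a in detect_hydrogen_bonds(frame, topo))

    def test_bent_geometry_not_detected(self):
        frame, topo = two_residue_hbond_frame(2.9, 45.0)
        assert not any(d == 0 and a == 5 for d, _, a in detect_hydrogen_bonds(frame, topo))

    def test_matches_brute_force_oracle(self, mixed_ensemble):
        topo = mixed_ensemble.topology
        d_cut, a_cut = 3.5, 30.0
        for fi in range(6):
            frame = mixed_ensemble.coords[fi]
            ours = set(detect_hydrogen_bonds(frame, topo, d_cut, a_cut))
            # oracle: all (donor, H, acceptor) triples, plain loops
            na = [i for i, e in enumerate(topo.elements) if e in ("N", "O")]
            hs = [i for i, e in enumerate(topo.elements) if e == "H"]
            expected = set()
            for h in hs:
                dists = [np.linalg.norm(frame[h] - frame[d]) for d in na]
                donor = na[int(np.argmin(dists))]
                if min(dists) > 1.25:
                    continue
                for acc in na:
                    if acc == donor or topo.residue_index[acc] == topo.residue_index[donor]:
                        continue
                    v_da = frame[acc] - frame[donor]
                    if np.linalg.norm(v_da) > d_cut:
                        continue
                    v_dh = frame[h] - frame[donor]
                    cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * np.linalg.norm(v_da))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= a_cut:
                        expected.add((donor, h, acc))
            assert ours == expected

    def test_helix_group_occupancy_map(self, helix_frame, hst5_topology):
        ens = Ensemble(np.stack([helix_frame] * 3), hst5_topology)
        groups = RgGroupSet(labels=[11], members={11: np.arange(3)})
        occ, records = hbond_map(ens, groups)[11]
        assert np.allclose(occ, occ.T)
        # ideal helix: every i -> i-4 backbone bond present in all frames
        assert occ[0, 4] == pytest.approx(1.0)
        assert records[0].occupancy == pytest.approx(1.0)

    def test_no_bonds_gives_zero_matrix(self, extended_frame, hst5_topology):
        ens = Ensemble(extended_frame[None], hst5_topology)
        groups = RgGroupSet(labels=[20], members={20: np.array([0])})
        occ, records = hbond_map(ens, groups)[20]
        assert occ.sum() == 0.0
        assert records == []

    def test_compact_group_has_more_hbond_mass(self, compact_ensemble, extended_ensemble):
        g_c = RgGroupSet(labels=[1], members={1: np.arange(30)})
        occ_c, _ = hbond_map(compact_ensemble, g_c)[1]
        occ_e, _ = hbond_map(extended_ensemble, g_c)[1]
        assert occ_c.sum() > occ_e.sum()


class TestDistanceMap:
    def test_ca_mode_rod_closed_form(self):
        n = 8
        coords = np.zeros((n, 3))
        coords[:, 0] = 3.8 * np.arange(n)
        topo = Topology(["CA"] * n, ["C"] * n, np.arange(1, n + 1), ["GLY"] * n)
        ens = Ensemble(coords[None], topo)
        groups = RgGroupSet(labels=[9], members={9: np.array([0])})
        mat = residue_distance_map(ens, groups, mode="ca")[9]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        np.testing.assert_allclose(mat, 3.8 * np.abs(i - j), atol=1e-9)

    def test_identical_frames_and_symmetry(self, helix_frame, hst5_topology):
        ens = Ensemble(np.stack([helix_frame] * 2), hst5_topology)
        groups = RgGroupSet(labels=[11], members={11: np.arange(2)})
        mat = residue_distance_map(ens, groups, mode="min-atom")[11]
        single = residue_distance_map(
            Ensemble(helix_frame[None], hst5_topology),
            RgGroupSet(labels=[11], members={11: np.array([0])}), mode="min-atom")[11]
        np.testing.assert_allclose(mat, single)
        np.testing.assert_allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_extended_group_has_larger_long_range_distances(self, compact_ensemble,
                                                            extended_ensemble):
        g = RgGroupSet(labels=[1], members={1: np.arange(30)})
        m_c = residue_distance_map(compact_ensemble, g, mode="ca")[1]
        m_e = residue_distance_map(extended_ensemble, g, mode="ca")[1]
        nres = m_c.shape[0]
        i, j = np.meshgrid(np.arange(nres), np.arange(nres), indexing="ij")
        far = np.abs(i - j) > 10
        assert m_e[far].mean() > m_c[far].mean()
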