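"""Superposition, RMSF, GROMOS clustering, tICA and landscapes."""

import numpy as np
import pytest

from coedecomp import (Ensemble, GeneratorConfig, featurize,
                       free_energy_landscape, generate_ensemble, gromos_cluster,
                       kabsch_superpose, rmsf_per_group, tica_fit)
from coedecomp.flexibility import pairwise_rmsd
from coedecomp.rg import RgGroupSet
from coedecomp.ensemble_io import Topology
from conftest import random_rigid_motion


def ca_topology(n):
    return Topology(["CA"] * n, ["C"] * n, np.arange(1, n + 1), ["GLY"] * n)


class TestKabsch:
    def test_rigid_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 3)) * 4
        R, t = random_rigid_motion(rng)
        moved, rmsd = kabsch_superpose(A @ R.T + t, A)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved, A, atol=1e-9)

    def test_matches_brute_force_rotation_search(self):
        # coarse grid over Euler angles as an independent minimizer
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 3)) * 3
        B = rng.standard_normal((6, 3)) * 3
        _, rmsd = kabsch_superpose(B, A)
        A0 = A - A.mean(axis=0)
        B0 = B - B.mean(axis=0)
        grid = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        half = np.linspace(0, np.pi, 30)
        best = np.inf
        for a in grid:
            ca, sa = np.cos(a), np.sin(a)
            Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            for b in half:
                cb, sb = np.cos(b), np.sin(b)
                Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                M = Ry @ Rz1
                for c in grid:
                    cc, sc = np.cos(c), np.sin(c)
                    Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
                    R = Rz2 @ M
                    val = np.sqrt(np.mean(np.sum((B0 @ R.T - A0) ** 2, axis=1)))
                    if val < best:
                        best = val
        assert rmsd <= best + 1e-9
        assert best - rmsd < 1e-2  # grid resolution

    def test_reflection_is_forbidden(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((10, 3)) * 5
        mirrored = A * np.array([-1.0, 1.0, 1.0])
        _, rmsd = kabsch_superpose(mirrored, A)
        assert rmsd > 0.1

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 1.0)


class TestRmsf:
    def test_identical_frames_give_zero(self, helix_frame, hst5_topology):
        ens = Ensemble(np.stack([helix_frame] * 4), hst5_topology)
        groups = RgGroupSet(labels=[11], members={11: np.arange(4)})
        mat = rmsf_per_group(ens, groups)
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-9)

    def test_single_perturbed_residue_shows_its_delta(self):
        # large chain so the superposition absorbs little of the local motion
        n = 60
        topo = ca_topology(n)
        rng = np.random.default_rng(8)
        base = rng.standard_normal((n, 3)) * 10
        delta = 0.4
        frames = []
        for k in range(20):
            f = base.copy()
            f[30, 0] += delta if k % 2 == 0 else -delta
            frames.append(f)
        ens = Ensemble(np.array(frames), topo)
        groups = RgGroupSet(labels=[5], members={5: np.arange(20)})
        mat = rmsf_per_group(ens, groups)
        assert mat.values[30, 0] == pytest.approx(delta, rel=0.1)
        others = np.delete(mat.values[:, 0], 30)
        assert np.all(others < 0.1)

    def test_singleton_group_rejected_by_name(self, helix_frame, hst5_topology):
        ens = Ensemble(helix_frame[None], hst5_topology)
        groups = RgGroupSet(labels=[11], members={11: np.array([0])})
        with pytest.raises(ValueError, match="11"):
            rmsf_per_group(ens, groups)

    def test_rigid_motion_invariance(self, compact_ensemble):
        sub = Ensemble(compact_ensemble.coords[:10], compact_ensemble.topology)
        groups = RgGroupSet(labels=[1], members={1: np.arange(10)})
        ref = rmsf_per_group(sub, groups)
        rng = np.random.default_rng(12)
        moved = sub.coords.copy()
        for k in range(10):
            R, t = random_rigid_motion(rng)
            moved[k] = moved[k] @ R.T + t
        out = rmsf_per_group(Ensemble(moved, sub.topology), groups)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-6)

    def test_chain_ends_fluctuate_most(self, mixed_ensemble):
        sub = Ensemble(mixed_ensemble.coords[:80], mixed_ensemble.topology)
        groups = RgGroupSet(labels=[1], members={1: np.arange(80)})
        mat = rmsf_per_group(sub, groups)
        vals = mat.values[:, 0]
        interior = np.median(vals[6:-6])
        assert max(vals[0], vals[-1]) > interior


class TestGromosClustering:
    def test_identical_frames_form_one_cluster(self, helix_frame, hst5_topology):
        ens = Ensemble(np.stack([helix_frame] * 5), hst5_topology)
        clusters = gromos_cluster(ens, rmsd_cutoff=1.0)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_two_separated_bundles(self, helix_frame, extended_frame, hst5_topology):
        rng = np.random.default_rng(3)
        frames = [helix_frame + 0.05 * rng.standard_normal(helix_frame.shape) for _ in range(4)]
        frames += [extended_frame + 0.05 * rng.standard_normal(helix_frame.shape) for _ in range(3)]
        ens = Ensemble(np.array(frames), hst5_topology)
        clusters = gromos_cluster(ens, rmsd_cutoff=2.0)
        assert len(clusters) == 2
        assert sorted(len(c.members) for c in clusters) == [3, 4]
        assert set(clusters[0].members) == {0, 1, 2, 3}

    def test_tiny_cutoff_isolates_every_frame(self, mixed_ensemble):
        sub = Ensemble(mixed_ensemble.coords[:6], mixed_ensemble.topology)
        clusters = gromos_cluster(sub, rmsd_cutoff=1e-9)
        assert len(clusters) == 6

    def test_deterministic_and_matches_daura_oracle(self, mixed_ensemble):
        sub = Ensemble(mixed_ensemble.coords[:12], mixed_ensemble.topology)
        ours = gromos_cluster(sub, rmsd_cutoff=5.0)
        again = gromos_cluster(sub, rmsd_cutoff=5.0)
        assert [(c.center, list(c.members)) for c in ours] == \
               [(c.center, list(c.members)) for c in again]
        # independent plain-python Daura implementation
        D = pairwise_rmsd(sub.coords, sub.topology.select_name("CA"))
        alive = set(range(12))
        expected = []
        while alive:
            best, best_n = None, -1
            for i in sorted(alive):
                n = sum(1 for j in alive if D[i, j] <= 5.0)
                if n > best_n:
                    best, best_n = i, n
            members = sorted(j for j in alive if D[best, j] <= 5.0)
            expected.append((best, members))
            alive -= set(members)
        expected.sort(key=lambda c: (-len(c[1]), c[0]))
        assert [(c.center, sorted(c.members)) for c in ours] == expected


class TestFeaturize:
    def test_distance_feature_combinatorics(self):
        ens = Ensemble(np.random.default_rng(0).standard_normal((2, 4, 3)),
                       ca_topology(4))
        feats = featurize(ens)
        assert feats.shape == (2, 3)  # (1,3), (1,4), (2,4)

    def test_rigid_motion_gives_identical_rows(self, helix_frame, hst5_topology):
        rng = np.random.default_rng(1)
        R, t = random_rigid_motion(rng)
        ens = Ensemble(np.stack([helix_frame, helix_frame @ R.T + t]), hst5_topology)
        feats = featurize(ens)
        np.testing.assert_allclose(feats[0], feats[1], atol=1e-9)

    def test_dihedral_mode_round_trips_angles(self, mixed_ensemble):
        from coedecomp import backbone_dihedrals
        sub = Ensemble(mixed_ensemble.coords[:3], mixed_ensemble.topology)
        feats = featurize(sub, mode="dihedrals")
        dih = backbone_dihedrals(sub)
        phi_def = dih.phi[:, 1:]
        k = phi_def.shape[1]
        recovered = np.degrees(np.arctan2(feats[:, :k], feats[:, k:2 * k]))
        np.testing.assert_allclose(recovered, phi_def, atol=1e-3)


class TestTica:
    def test_white_noise_has_no_slow_modes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 4))
        model = tica_fit(X, lag=5, n_components=4)
        assert np.max(np.abs(model.eigenvalues)) < 0.1

    def test_ar1_leading_eigenvalue(self):
        rng = np.random.default_rng(1)
        n, rho, lag = 20000, 0.9, 3
        x = np.empty(n)
        x[0] = 0.0
        for t in range(1, n):
            x[t] = rho * x[t - 1] + rng.standard_normal()
        model = tica_fit(x, lag=lag, n_components=1)
        assert model.eigenvalues[0] == pytest.approx(rho ** lag, abs=0.05)

    def test_eigenvalues_real_sorted_and_bounded(self, mixed_ensemble):
        feats = featurize(mixed_ensemble)
        model = tica_fit(feats, lag=5, n_components=4)
        assert np.all(np.isreal(model.eigenvalues))
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.max(np.abs(model.eigenvalues)) <= 1.0 + 1e-6

    def test_projections_uncorrelated_and_c0_orthonormal(self, mixed_ensemble):
        feats = featurize(mixed_ensemble)
        lag = 5
        model = tica_fit(feats, lag=lag, n_components=3)
        # rebuild the training covariance estimate and check V' (C0+eps I) V = I
        n = feats.shape[0]
        Xc = feats - model.mean
        X0, X1 = Xc[:-lag], Xc[lag:]
        C0 = 0.5 * (X0.T @ X0 + X1.T @ X1) / (n - lag)
        C0 += model.regularization * np.eye(C0.shape[0])
        G = model.components.T @ C0 @ model.components
        np.testing.assert_allclose(G, np.eye(3), atol=1e-6)

    def test_collinear_features_survive_regularization(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        y = np.cumsum(rng.standard_normal(2000)) * 0.01
        X = np.column_stack([x + y, x + y, x - y])  # duplicated column
        model = tica_fit(X, lag=3, n_components=2, regularization=1e-8)
        assert np.all(np.isfinite(model.eigenvalues))

    def test_bad_lag_rejected(self):
        with pytest.raises(ValueError):
            tica_fit(np.zeros((10, 2)), lag=10)

    def test_hidden_state_recovery_and_timescale(self):
        cfg = GeneratorConfig(n_frames=5000, switch_prob=0.01, seed=13)
        ens = generate_ensemble(cfg)
        feats = featurize(ens)
        model = tica_fit(feats, lag=10, n_components=2)
        proj = model.transform(feats)[:, 0]
        states = ens.hidden_states
        agree = max(np.mean((proj > 0) == states), np.mean((proj > 0) != states))
        assert agree > 0.8
        # the leading implied timescale estimates the chain's relaxation time
        # -1/ln(1-2p); for symmetric switching that is half the dwell time
        relax = -1.0 / np.log(1.0 - 2.0 * cfg.switch_prob)
        t1 = model.implied_timescales()[0]
        assert relax / 2 < t1 < relax * 2


class TestLandscape:
    def test_uniform_occupancy_is_flat_zero(self):
        rng = np.random.default_rng(0)
        # two bins exactly, equal occupancy
        pts = np.array([[0.25, 0.5], [0.75, 0.5]] * 50)
        scape = free_energy_landscape(pts, n_bins=2, percentile_range=(0, 100))
        occupied = scape.free_energy[~scape.mask]
        np.testing.assert_allclose(occupied, 0.0, atol=1e-12)

    def test_ten_to_one_occupancy_gap(self):
        pts = np.array([[0.25, 0.5]] * 100 + [[0.75, 0.5]] * 10)
        scape = free_energy_landscape(pts, n_bins=2, percentile_range=(0, 100))
        occupied = np.sort(scape.free_energy[~scape.mask])
        assert occupied[0] == 0.0
        assert occupied[-1] == pytest.approx(np.log(10), abs=1e-9)

    def test_single_occupied_bin_rejected(self):
        pts = np.zeros((50, 2))
        with pytest.raises(ValueError):
            free_energy_landscape(pts, n_bins=4, percentile_range=(0, 100))

    def test_two_state_ensemble_shows_two_minima(self):
        cfg = GeneratorConfig(n_frames=2000, switch_prob=0.005, seed=17)
        ens = generate_ensemble(cfg)
        feats = featurize(ens)
        model = tica_fit(feats, lag=10, n_components=2)
        scape = free_energy_landscape(model.transform(feats), n_bins=25)
        assert len(scape.minima()) >= 2
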