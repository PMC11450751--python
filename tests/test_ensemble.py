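"""Superposition, RMSD/RMSF descriptors, featurization and clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epitope_decomp import (
    EnsembleSpec,
    FeatureMatrix,
    ToyComplexSpec,
    featurize,
    make_conformers,
    make_toy_complex,
    rmsd_series,
    rmsf_per_residue,
    select_representatives,
    superpose,
)
from epitope_decomp.ensemble import dihedral, kabsch
from epitope_decomp.errors import EpitopeDecompError
from epitope_decomp.structures import Trajectory


def _base(n=6):
    structure, _ = make_toy_complex(ToyComplexSpec(n_res_per_chain=n))
    return structure


def _rigidly_moved(structure, seed=3):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
    shift = rng.normal(0, 5.0, size=3)
    moved = structure.copy()
    moved.set_coords(structure.coord_array() @ rot.T + shift)
    return moved


class TestSuperpose:
    def test_self_fit_is_identity(self):
        s = _base()
        result = superpose(s, s)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_fits_to_zero(self):
        s = _base()
        result = superpose(_rigidly_moved(s), s)
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_rotation_always_proper(self, rng):
        # a reflected point set must still yield det(R) = +1
        coords = rng.normal(size=(4, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        result = kabsch(mirrored, coords)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_matches_rotation_grid_search(self, rng):
        mobile = rng.normal(size=(4, 3))
        reference = rng.normal(size=(4, 3))
        result = kabsch(mobile, reference)
        mc = mobile - mobile.mean(axis=0)
        rc = reference - reference.mean(axis=0)
        best = np.inf
        grid = np.arange(0.0, 360.0, 12.0)
        for a in grid:
            for b in np.arange(0.0, 180.0, 12.0):
                for c in grid:
                    rot = Rotation.from_euler("zyz", [a, b, c], degrees=True)
                    rmsd = np.sqrt(((rot.apply(mc) - rc) ** 2).sum(axis=1).mean())
                    best = min(best, rmsd)
        assert result.rmsd <= best + 1e-9
        assert result.rmsd == pytest.approx(best, abs=0.1)

    def test_mismatched_counts_rejected(self):
        s5, s6 = _base(5), _base(6)
        with pytest.raises(EpitopeDecompError):
            superpose(s5, s6)


class TestRmsdSeries:
    def test_constant_trajectory_zero(self):
        s = _base()
        series = rmsd_series(Trajectory([s.copy() for _ in range(4)]))
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_first_value_zero_and_rigid_invariance(self):
        s = _base()
        frames = [s.copy(), _rigidly_moved(s, 1), _rigidly_moved(s, 2)]
        series = rmsd_series(Trajectory(frames))
        np.testing.assert_allclose(series, 0.0, atol=1e-6)

    def test_hand_computed_two_frame_value(self):
        # 5 points: a symmetric square in the z=0 plane plus its centre;
        # moving the centre atom by d along z leaves the optimal rotation
        # at identity, so RMSD = 2d/5 after the centroid shift.
        import epitope_decomp.structures as st

        def frame(dz):
            atoms = [
                ([1, 0, 0], "C1"), ([-1, 0, 0], "C2"),
                ([0, 1, 0], "C3"), ([0, -1, 0], "C4"),
                ([0, 0, dz], "C5"),
            ]
            res = st.Residue(st.ResidueRef("A", 1, "", "GLY"), [
                st.Atom(name, "C", np.array(xyz, dtype=float))
                for xyz, name in atoms
            ])
            return st.Structure([res])

        d = 0.7
        series = rmsd_series(Trajectory([frame(0.0), frame(d)]),
                             atom_selection="all")
        assert series[0] == 0.0
        assert series[1] == pytest.approx(2 * d / 5)


class TestRmsf:
    def test_constant_trajectory_zero(self):
        s = _base()
        rmsf = rmsf_per_residue(Trajectory([s.copy() for _ in range(3)]))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf.values())

    def test_single_frame_warns_and_zeroes(self):
        s = _base()
        with pytest.warns(UserWarning):
            rmsf = rmsf_per_residue(Trajectory([s]))
        assert set(rmsf.values()) == {0.0}

    def test_matches_brute_force_definition(self):
        s = _base()
        traj, _ = make_conformers(s, EnsembleSpec(
            k_modes=1, noise_sigma=0.15, n_frames_per_mode=12, seed=5))
        rmsf = rmsf_per_residue(traj, atom_selection="c_alpha")
        # brute force: superpose to the mean (same two-pass scheme), then
        # per-residue sqrt of the time-averaged squared deviation
        from epitope_decomp.ensemble import _selection_mask

        mask = _selection_mask(traj.frames[0], "c_alpha")
        coords = traj.coords()[:, mask, :]
        ref = coords[0]
        for _ in range(2):
            fitted = np.stack([kabsch(c, ref).apply(c) for c in coords])
            ref = fitted.mean(axis=0)
        msf = ((fitted - ref) ** 2).sum(axis=-1).mean(axis=0)
        refs = [r.ref for r in traj.frames[0].polymer_residues()]
        for i, res_ref in enumerate(refs):
            assert rmsf[res_ref] == pytest.approx(np.sqrt(msf[i]))

    def test_oscillating_residue_closed_form(self):
        # large system so the rigid fit absorbs a negligible share of the
        # single-residue oscillation
        s = _base(40)
        d = 0.4
        frames = []
        target = s.residues[20].ref  # mid-chain: minimal rigid-fit lever arm
        for sign in (+1, -1, +1, -1):
            f = s.copy()
            for atom in f.residue(target).atoms:
                atom.coords = atom.coords + np.array([0.0, 0.0, sign * d])
            frames.append(f)
        rmsf = rmsf_per_residue(Trajectory(frames), atom_selection="all")
        # the oscillation is a small internal motion: the moving residue
        # fluctuates by ~d, all others by an order of magnitude less
        assert rmsf[target] == pytest.approx(d, rel=0.05)
        others = [v for k, v in rmsf.items() if k != target]
        assert max(others) < 0.3 * d


class TestFeaturize:
    def test_extended_strand_dihedrals(self):
        s = _base()
        feats = featurize(Trajectory([s]))
        sin_cols = [i for i, c in enumerate(feats.columns) if "_sin" in c]
        cos_cols = [i for i, c in enumerate(feats.columns) if "_cos" in c]
        np.testing.assert_allclose(feats.values[0, sin_cols], 0.0, atol=1e-6)
        np.testing.assert_allclose(feats.values[0, cos_cols], -1.0, atol=1e-6)

    def test_identical_frames_zero_variance(self):
        s = _base()
        feats = featurize(Trajectory([s.copy() for _ in range(3)]))
        assert np.ptp(feats.values, axis=0).max() == 0.0

    def test_feature_count(self):
        s = _base(5)
        feats = featurize(Trajectory([s]))
        n_res = 10          # two chains of 5
        n_dihedral = 6      # interior residues only (3 per chain)
        n_pairs = n_res * (n_res - 1) // 2
        assert feats.values.shape[1] == 4 * n_dihedral + n_pairs
        assert len(feats.columns) == feats.values.shape[1]

    def test_dihedral_sign_convention(self):
        p = [np.array(x, dtype=float) for x in
             ([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])]
        assert dihedral(*p) == pytest.approx(np.pi / 2)


class TestSelectRepresentatives:
    def _blobs(self, rng, k=3, n=20, sep=10.0, sigma=0.3, dim=4):
        centers = rng.normal(0, 1, size=(k, dim))
        centers = centers / np.linalg.norm(centers, axis=1, keepdims=True)
        centers = centers * sep * np.arange(1, k + 1)[:, None]
        x = np.concatenate([
            c + rng.normal(0, sigma, size=(n, dim)) for c in centers
        ])
        labels = np.repeat(np.arange(k), n)
        return FeatureMatrix(x, [f"f{i}" for i in range(dim)]), labels

    def test_planted_three_blob_recovery(self, rng):
        feats, truth = self._blobs(rng)
        model = select_representatives(feats, k_range=(2, 6), seed=0)
        assert model.n_clusters == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_representative_is_hub(self, rng):
        feats, _ = self._blobs(rng)
        model = select_representatives(feats, k_range=(2, 6), seed=0)
        for cluster, frame in enumerate(model.representatives):
            members = np.flatnonzero(model.labels == cluster)
            mean = feats.values[members].mean(axis=0)
            d = np.linalg.norm(feats.values[members] - mean, axis=1)
            # hub = nearest member to the (mixture) cluster mean; with tight
            # blobs this coincides with the nearest-to-centroid member
            assert frame == members[np.argmin(d)]

    def test_deterministic_given_seed(self, rng):
        feats, _ = self._blobs(rng)
        m1 = select_representatives(feats, k_range=(2, 5), seed=42)
        m2 = select_representatives(feats, k_range=(2, 5), seed=42)
        assert m1.n_clusters == m2.n_clusters
        assert m1.representatives == m2.representatives
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_degenerate_identical_frames(self):
        feats = FeatureMatrix(np.ones((8, 3)), ["a", "b", "c"])
        with pytest.warns(UserWarning):
            model = select_representatives(feats, k_range=(2, 4))
        assert model.n_clusters == 1
        assert model.representatives == [0]

    def test_too_few_frames_rejected(self, rng):
        feats = FeatureMatrix(rng.normal(size=(4, 2)), ["a", "b"])
        with pytest.raises(EpitopeDecompError):
            select_representatives(feats, k_range=(2, 10))
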