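"""Trajectory descriptors and representative-conformation selection.

RMSD/RMSF are computed after least-squares rigid superposition (Kabsch, SVD
with reflection rejection).  Representative conformations are selected by
featurizing each frame (backbone φ/ψ dihedrals as sin/cos pairs plus
Cα–Cα distances), optionally reducing dimensionality with UMAP, fitting
Gaussian mixture models over a range of cluster counts, scoring each with the
mean silhouette, and extracting the frame nearest each cluster mean — the
cluster "hub".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .errors import EpitopeDecompError, FeatureError
from .structures import ResidueRef, Structure, Trajectory


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # (3,3), proper (det +1)
    translation: np.ndarray  # (3,)
    rmsd: float              # Å, post-fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _selection_mask(structure: Structure, atom_selection: str) -> list[int]:
    mask = []
    for i, (res, atom) in enumerate(structure.iter_atoms()):
        if atom_selection == "all":
            mask.append(i)
        elif atom_selection == "all_heavy":
            if not atom.is_hydrogen:
                mask.append(i)
        elif atom_selection == "c_alpha":
            if atom.name == "CA" and not res.is_water:
                mask.append(i)
        else:
            raise EpitopeDecompError(f"unknown atom selection {atom_selection!r}")
    return mask


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (both (n,3))."""
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise EpitopeDecompError("superposition requires equal (n,3) coordinate sets")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = cr - rotation @ cm
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation, translation, rmsd)


def superpose(
    mobile: Structure, reference: Structure, atom_selection: str = "all_heavy"
) -> SuperpositionResult:
    """Least-squares optimal rigid fit of one structure onto another."""
    mi = _selection_mask(mobile, atom_selection)
    ri = _selection_mask(reference, atom_selection)
    if len(mi) != len(ri) or not mi:
        raise EpitopeDecompError(
            f"selection {atom_selection!r}: {len(mi)} vs {len(ri)} atoms"
        )
    return kabsch(mobile.coord_array()[mi], reference.coord_array()[ri])


def rmsd_series(
    traj: Trajectory, reference_frame: int = 0, atom_selection: str = "all_heavy"
) -> np.ndarray:
    """Per-frame post-superposition RMSD against one reference frame."""
    ref = traj.frames[reference_frame]
    mask = _selection_mask(ref, atom_selection)
    ref_coords = ref.coord_array()[mask]
    return np.array([
        kabsch(f.coord_array()[mask], ref_coords).rmsd for f in traj.frames
    ])


def rmsf_per_residue(
    traj: Trajectory, atom_selection: str = "c_alpha"
) -> dict[ResidueRef, float]:
    """Root-mean-square fluctuation of each residue about its mean position.

    Frames are first superposed onto the ensemble-average structure (two
    passes: fit to frame 0, average, refit to the average).
    """
    if len(traj) == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
    mask = _selection_mask(traj.frames[0], atom_selection)
    coords = traj.coords()[:, mask, :]
    ref = coords[0]
    for _ in range(2):
        fitted = np.stack([kabsch(c, ref).apply(c) for c in coords])
        ref = fitted.mean(axis=0)
    fluct = fitted - ref  # (frames, atoms, 3)
    msf = (fluct**2).sum(axis=-1).mean(axis=0)  # per-atom mean square fluctuation

    atoms = list(traj.frames[0].iter_atoms())
    out: dict[ResidueRef, list[float]] = {}
    for local, global_i in enumerate(mask):
        ref_res = atoms[global_i][0].ref
        out.setdefault(ref_res, []).append(msf[local])
    return {ref_res: float(np.sqrt(np.mean(v))) for ref_res, v in out.items()}


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (radians) of four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.arctan2(np.cross(b1, v) @ w, v @ w))


@dataclass
class FeatureMatrix:
    values: np.ndarray           # (frames, features)
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains non-finite values")


def _backbone(structure: Structure, ref: ResidueRef) -> dict[str, np.ndarray]:
    res = structure.residue(ref)
    out = {}
    for name in ("N", "CA", "C"):
        if not res.has_atom(name):
            raise FeatureError(f"residue {ref} is missing backbone atom {name}")
        out[name] = res.atom(name).coords
    return out


def featurize(
    traj: Trajectory,
    residue_selection: Sequence[ResidueRef] | None = None,
    distance_pairs: Sequence[tuple[ResidueRef, ResidueRef]] | None = None,
) -> FeatureMatrix:
    """Backbone φ/ψ sin–cos features plus Cα–Cα distances.

    φ/ψ are emitted for every selected residue that has both defined (interior
    residues); distances default to all selected residue pairs.  Columns are
    named and their order is stable: dihedrals first (phi_sin, phi_cos,
    psi_sin, psi_cos per residue), then distances.
    """
    frame0 = traj.frames[0]
    if residue_selection is None:
        residue_selection = [r.ref for r in frame0.polymer_residues()]
    chains: dict[str, list[ResidueRef]] = {}
    for r in frame0.polymer_residues():
        chains.setdefault(r.ref.chain_id, []).append(r.ref)

    dihedral_refs: list[ResidueRef] = []
    for ref in residue_selection:
        chain = chains[ref.chain_id]
        i = next(k for k, r in enumerate(chain) if r.key == ref.key)
        if 0 < i < len(chain) - 1:
            dihedral_refs.append(ref)
    if distance_pairs is None:
        distance_pairs = list(itertools.combinations(residue_selection, 2))

    columns: list[str] = []
    for ref in dihedral_refs:
        columns += [f"phi_sin:{ref}", f"phi_cos:{ref}",
                    f"psi_sin:{ref}", f"psi_cos:{ref}"]
    columns += [f"dCA:{a}:{b}" for a, b in distance_pairs]

    rows = []
    for frame in traj.frames:
        feats: list[float] = []
        for ref in dihedral_refs:
            chain = chains[ref.chain_id]
            i = next(k for k, r in enumerate(chain) if r.key == ref.key)
            prev_c = _backbone(frame, chain[i - 1])["C"]
            bb = _backbone(frame, ref)
            next_n = _backbone(frame, chain[i + 1])["N"]
            phi = dihedral(prev_c, bb["N"], bb["CA"], bb["C"])
            psi = dihedral(bb["N"], bb["CA"], bb["C"], next_n)
            feats += [np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)]
        for a, b in distance_pairs:
            ca_a = _backbone(frame, a)["CA"]
            ca_b = _backbone(frame, b)["CA"]
            feats.append(float(np.linalg.norm(ca_a - ca_b)))
        rows.append(feats)
    return FeatureMatrix(np.asarray(rows, dtype=float), columns)


# ---------------------------------------------------------------------------
# Representative selection
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    n_clusters: int
    labels: np.ndarray                  # per frame
    representatives: list[int]          # frame index of each cluster hub
    silhouette_by_k: dict[int, float]
    reduced: bool = False

    def __post_init__(self) -> None:
        for cluster, frame in enumerate(self.representatives):
            if self.labels[frame] != cluster:
                raise ValueError("representative must belong to its own cluster")


def select_representatives(
    features: FeatureMatrix,
    k_range: tuple[int, int] = (2, 10),
    reduce: bool = False,
    seed: int = 0,
) -> EnsembleModel:
    """Choose the cluster count by mean silhouette over Gaussian-mixture fits
    and return the hub frame (nearest to the cluster mean) of each cluster.

    Clustering runs on raw features by default; ``reduce=True`` first embeds
    the frames with UMAP (seeded), matching the original workflow at the cost
    of seed-sensitive geometry.  Silhouette ties prefer the smaller k.
    """
    x = features.values
    n_frames = x.shape[0]
    k_lo, k_hi = k_range
    if k_lo < 1 or k_hi < k_lo:
        raise EpitopeDecompError(f"invalid k_range {k_range}")
    if n_frames < k_hi + 1:
        raise EpitopeDecompError(
            f"{n_frames} frames cannot support k_range up to {k_hi}"
        )

    if np.allclose(x, x[0]):
        warnings.warn("all frames identical: returning a single cluster")
        return EnsembleModel(1, np.zeros(n_frames, dtype=int), [0], {1: 0.0}, reduce)

    if reduce:
        import umap

        x = umap.UMAP(n_components=2, random_state=seed).fit_transform(x)

    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    means: dict[int, np.ndarray] = {}
    for k in range(max(2, k_lo), k_hi + 1):
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=10, random_state=seed
        ).fit(x)
        labels = gmm.predict(x)
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(x, labels))
        fits[k] = labels
        means[k] = gmm.means_

    best_k = max(scores, key=lambda k: (scores[k], -k))
    labels = fits[best_k]

    # relabel clusters by first appearance so output is deterministic
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels])
    mean_by_new = {order[old]: means[best_k][old] for old in order}

    representatives = []
    for cluster in range(len(order)):
        members = np.flatnonzero(labels == cluster)
        d = np.linalg.norm(x[members] - mean_by_new[cluster], axis=1)
        representatives.append(int(members[np.argmin(d)]))
    return EnsembleModel(len(order), labels, representatives, scores, reduce)


def extract_representatives(traj: Trajectory, model: EnsembleModel) -> list[Structure]:
    return [traj.frames[i] for i in model.representatives]
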