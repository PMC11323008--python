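"""Per-group fluctuation and landscape analyses.

Covers: optimal rigid-body superposition (Kabsch), per-residue RMSF about an
iteratively converged mean structure, GROMOS (Daura neighbor-counting) RMSD
clustering, time-lagged independent component analysis (tICA) from the
symmetrized generalized eigenproblem, and −ln(density) free-energy
landscapes over the two leading components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .ensemble_io import Ensemble
from .rg import RgGroupSet
from .surface import PerResidueMatrix

__all__ = [
    "TicaModel",
    "Landscape",
    "Cluster",
    "kabsch_superpose",
    "pairwise_rmsd",
    "rmsf_per_group",
    "gromos_cluster",
    "featurize",
    "tica_fit",
    "free_energy_landscape",
]


# ---------------------------------------------------------------------------
# Superposition and RMSF


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: Optional[np.ndarray] = None) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The optimal proper rotation (det = +1, reflections forbidden) and
    translation are found on ``selection`` (all atoms by default) and applied
    to the full frame. Returns (moved frame, minimized RMSD over the
    selection in Å). Collinear or <3-point selections are degenerate and
    raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    P = mobile[sel]
    Q = reference[sel]
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom selection")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (mobile - pc) @ R.T + qc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return moved, rmsd


def pairwise_rmsd(coords: np.ndarray, selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Symmetric matrix of pairwise minimized RMSDs over a frame stack."""
    F = coords.shape[0]
    out = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            _, r = kabsch_superpose(coords[j], coords[i], selection)
            out[i, j] = out[j, i] = r
    return out


def rmsf_per_group(ensemble: Ensemble, groups: RgGroupSet,
                   selected_labels: Optional[Sequence[int]] = None,
                   tol: float = 1e-4, max_iter: int = 10) -> PerResidueMatrix:
    """Per-residue RMSF (Å) about the converged mean structure of each group.

    Frames are superposed on their Cα atoms onto the group mean, the mean is
    re-averaged, and the procedure iterates until the mean moves by less than
    ``tol`` Å (or ``max_iter``). The variance companion is the across-frame
    variance of the per-residue deviation.
    """
    if selected_labels is None:
        selected_labels = groups.labels
    topo = ensemble.topology
    ca = topo.select_name("CA")
    nres = topo.n_residues
    values = np.zeros((nres, len(selected_labels)))
    variance = np.zeros_like(values)
    for c, lab in enumerate(selected_labels):
        frames = groups.members[lab]
        if len(frames) < 2:
            raise ValueError(f"group {lab} has a single frame; RMSF undefined")
        X = ensemble.coords[frames].copy()
        mean = X[0].copy()
        for _ in range(max_iter):
            for k in range(len(X)):
                X[k], _ = kabsch_superpose(X[k], mean, ca)
            new_mean = X.mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
            mean = new_mean
            if shift < tol:
                break
        dev2 = np.sum((X[:, ca] - mean[ca]) ** 2, axis=2)  # F x nres
        values[:, c] = np.sqrt(dev2.mean(axis=0))
        variance[:, c] = np.sqrt(dev2).var(axis=0)
    return PerResidueMatrix(values, variance, topo.residue_labels, list(selected_labels))


# ---------------------------------------------------------------------------
# GROMOS clustering


@dataclass
class Cluster:
    """One GROMOS cluster: its center frame and member frames (0-based)."""

    center: int
    members: np.ndarray


def gromos_cluster(ensemble: Ensemble, frame_indices: Optional[Sequence[int]] = None,
                   rmsd_cutoff: float = 7.0) -> list[Cluster]:
    """Daura neighbor-counting clustering on pairwise Cα RMSD.

    Repeatedly takes the frame with the most neighbors within
    ``rmsd_cutoff`` Å (ties → lowest frame index) as a cluster center and
    removes it with its neighbors. Clusters are returned largest first
    (equal sizes: by center index). The 7 Å default mirrors the 0.7 nm
    cutoff customary for ``gmx cluster``.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    if frame_indices is None:
        frame_indices = range(ensemble.n_frames)
    frame_indices = np.asarray(list(frame_indices), dtype=int)
    ca = ensemble.topology.select_name("CA")
    D = pairwise_rmsd(ensemble.coords[frame_indices], ca)
    neighbor = D <= rmsd_cutoff  # includes self
    alive = np.ones(len(frame_indices), dtype=bool)
    clusters: list[Cluster] = []
    while alive.any():
        counts = (neighbor & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbor[center] & alive)[0]
        clusters.append(Cluster(int(frame_indices[center]),
                                frame_indices[members]))
        alive[members] = False
    clusters.sort(key=lambda c: (-len(c.members), c.center))
    return clusters


# ---------------------------------------------------------------------------
# tICA


def featurize(ensemble: Ensemble, mode: str = "distances",
              min_separation: int = 2) -> np.ndarray:
    """Frame-wise feature matrix for tICA.

    ``'distances'`` (default): all Cα–Cα distances with sequence separation
    ≥ ``min_separation`` — rigid-motion invariant and defined for
    backbone-only chains. ``'dihedrals'``: sin/cos of each defined φ and ψ.
    """
    topo = ensemble.topology
    if mode == "distances":
        ca = topo.select_name("CA")
        nres = len(ca)
        if nres < 4:
            raise ValueError("need at least 4 residues for distance features")
        pairs = [(i, j) for i in range(nres) for j in range(i + min_separation, nres)]
        X = ensemble.coords[:, ca]
        i_idx = np.array([p[0] for p in pairs])
        j_idx = np.array([p[1] for p in pairs])
        return np.linalg.norm(X[:, i_idx] - X[:, j_idx], axis=-1)
    if mode == "dihedrals":
        from .secondary import backbone_dihedrals
        dih = backbone_dihedrals(ensemble)
        cols = []
        for arr in (dih.phi, dih.psi):
            defined = np.all(np.isfinite(arr), axis=0)
            rad = np.radians(arr[:, defined])
            cols += [np.sin(rad), np.cos(rad)]
        return np.concatenate(cols, axis=1)
    raise ValueError("mode must be 'distances' or 'dihedrals'")


@dataclass
class TicaModel:
    """Fitted tICA model.

    ``components`` (n_features × n_components) are generalized eigenvectors
    of the symmetrized lagged covariance in the instantaneous-covariance
    metric (vᵀ C₀ v = 1); ``eigenvalues`` are the corresponding
    autocorrelations at the training lag, sorted descending.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    lag: int
    regularization: float

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) @ self.components

    def implied_timescales(self) -> np.ndarray:
        """t = −lag / ln λ for eigenvalues in (0, 1)."""
        lam = np.clip(self.eigenvalues, 1e-12, 1.0 - 1e-12)
        return -self.lag / np.log(lam)


def tica_fit(features: np.ndarray, lag: int = 10,
             n_components: Optional[int] = None,
             regularization: Optional[float] = None) -> TicaModel:
    """Fit tICA by the symmetrized generalized eigenproblem.

    With mean-centered head/tail blocks X₀ = x[:-lag], X₁ = x[lag:]:
    C₀ = ½(X₀ᵀX₀ + X₁ᵀX₁)/(n−lag), C_τ = ½(X₀ᵀX₁ + X₁ᵀX₀)/(n−lag); solve
    C_τ v = λ (C₀ + εI) v. Symmetrization keeps eigenvalues real and within
    [−1, 1] up to regularization. ε defaults to 10⁻⁶·trace(C₀)/dim.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n, d = X.shape
    if lag < 1 or lag >= n:
        raise ValueError(f"lag must be in [1, n_frames); got {lag} for {n} frames")
    if n_components is None:
        n_components = min(d, 2)
    if n - lag <= n_components:
        raise ValueError("not enough frames for the requested lag and components")
    mean = X.mean(axis=0)
    X0 = X[:-lag] - mean
    X1 = X[lag:] - mean
    m = n - lag
    C0 = 0.5 * (X0.T @ X0 + X1.T @ X1) / m
    Ct = 0.5 * (X0.T @ X1 + X1.T @ X0) / m
    if regularization is None:
        regularization = 1e-6 * np.trace(C0) / d
    C0r = C0 + regularization * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(Ct, C0r)
    order = np.argsort(eigvals)[::-1][:n_components]
    lam = eigvals[order]
    vecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude entry of each component positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return TicaModel(mean=mean, components=vecs, eigenvalues=lam,
                     lag=lag, regularization=float(regularization))


# ---------------------------------------------------------------------------
# Free-energy landscapes


@dataclass
class Landscape:
    """Free energy (kT) over a 2D grid of component values.

    ``free_energy`` is −ln(relative occupancy), shifted so the occupied
    minimum is 0; empty bins are masked (NaN + ``mask`` True).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray

    def minima(self) -> list[tuple[int, int]]:
        """Occupied local minima (4-neighborhood) of the landscape."""
        F = np.where(self.mask, np.inf, self.free_energy)
        out = []
        nx, ny = F.shape
        for i in range(nx):
            for j in range(ny):
                if not np.isfinite(F[i, j]):
                    continue
                nb = []
                if i > 0:
                    nb.append(F[i - 1, j])
                if i < nx - 1:
                    nb.append(F[i + 1, j])
                if j > 0:
                    nb.append(F[i, j - 1])
                if j < ny - 1:
                    nb.append(F[i, j + 1])
                if all(F[i, j] < v for v in nb):
                    out.append((i, j))
        return out

    def write_tsv(self, path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        with open(path, "w") as fh:
            fh.write("x\ty\tfree_energy_kT\tmasked\n")
            for i, x in enumerate(xc):
                for j, y in enumerate(yc):
                    f = self.free_energy[i, j]
                    fh.write(f"{x:.6g}\t{y:.6g}\t{'nan' if self.mask[i, j] else f'{f:.6g}'}\t{int(self.mask[i, j])}\n")


def free_energy_landscape(projections: np.ndarray, n_bins: int = 60,
                          percentile_range: tuple[float, float] = (1.0, 99.0)) -> Landscape:
    """F = −ln(density) in kT over the two leading component projections.

    The grid spans the 1st–99th percentile of each component by default;
    empty bins are masked; the occupied minimum is shifted to 0.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("projections must be (n_frames, >=2)")
    x, y = P[:, 0], P[:, 1]
    lo, hi = percentile_range
    xr = np.percentile(x, [lo, hi])
    yr = np.percentile(y, [lo, hi])
    counts, xe, ye = np.histogram2d(x, y, bins=n_bins, range=[xr, yr])
    occupied = counts > 0
    if occupied.sum() < 2:
        raise ValueError("all points fall in a single bin; landscape undefined")
    F = np.full_like(counts, np.nan)
    F[occupied] = -np.log(counts[occupied] / counts.sum())
    F[occupied] -= np.nanmin(F[occupied])
    return Landscape(xe, ye, F, ~occupied)
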