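"""Solvent-accessible surface area, hydrogen-bond maps, and contact maps.

SASA uses the Shrake–Rupley rolling-probe algorithm: deterministic
golden-spiral test points on each atom's probe-expanded sphere, a point
counting as accessible when it lies outside every other expanded sphere.
Hydrogen bonds use the geometric donor–acceptor criterion of ``gmx hbond``
(distance ≤ 3.5 Å, H–donor–acceptor angle ≤ 30°); the energetic
Kabsch–Sander criterion lives in :mod:`coedecomp.secondary`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .ensemble_io import Ensemble, Topology
from .rg import RgGroupSet

__all__ = [
    "PerResidueMatrix",
    "ContactRecord",
    "sphere_points",
    "shrake_rupley_sasa",
    "residue_sasa",
    "sasa_per_group",
    "MAX_ASA_TIEN",
    "normalized_sasa",
    "sasa_rg_density",
    "detect_hydrogen_bonds",
    "hbond_map",
    "residue_distance_map",
]


@dataclass
class PerResidueMatrix:
    """Residues × groups table of a scalar observable with its variance.

    Units depend on the observable: Ų for SASA, Å for RMSF, fractions for
    secondary structure. Columns follow ``group_labels``.
    """

    values: np.ndarray
    variance: np.ndarray
    residue_labels: list[str]
    group_labels: list[int]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.variance = np.atleast_2d(np.asarray(self.variance, dtype=float))
        if self.values.shape != self.variance.shape:
            raise ValueError("values and variance shapes differ")
        if self.values.shape != (len(self.residue_labels), len(self.group_labels)):
            raise ValueError("shape does not match residue/group labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.variance < -1e-12):
            raise ValueError("variance must be non-negative")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(f"Rg_{g}" for g in self.group_labels)
                     + "\t" + "\t".join(f"var_Rg_{g}" for g in self.group_labels) + "\n")
            for i, lab in enumerate(self.residue_labels):
                row = "\t".join(f"{v:.6g}" for v in self.values[i])
                var = "\t".join(f"{v:.6g}" for v in self.variance[i])
                fh.write(f"{lab}\t{row}\t{var}\n")


@dataclass
class ContactRecord:
    """One donor→acceptor contact with its occupancy over a frame set."""

    donor_res: int      # 1-based
    acceptor_res: int   # 1-based
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def shrake_rupley_sasa(frame: np.ndarray, topology: Topology,
                       probe_radius: float = 1.4, n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Ų.

    Each atom's expanded radius is r_vdw + probe; its area is
    4πR² × (fraction of test points outside all other expanded spheres).
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 16:
        raise ValueError("need at least 16 sphere points")
    frame = np.asarray(frame, dtype=float)
    radii = topology.vdw_radius + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(frame)
    rmax = radii.max()
    areas = np.empty(len(frame))
    for i in range(len(frame)):
        pts = frame[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(frame[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_sphere_points
    return areas


def residue_sasa(frame: np.ndarray, topology: Topology,
                 probe_radius: float = 1.4, n_sphere_points: int = 960) -> np.ndarray:
    """Per-residue SASA (sum of its atoms' areas)."""
    atom_areas = shrake_rupley_sasa(frame, topology, probe_radius, n_sphere_points)
    out = np.zeros(topology.n_residues)
    np.add.at(out, topology.residue_index - 1, atom_areas)
    return out


def sasa_per_group(ensemble: Ensemble, groups: RgGroupSet,
                   selected_labels: Optional[Sequence[int]] = None,
                   probe_radius: float = 1.4, n_sphere_points: int = 960) -> PerResidueMatrix:
    """Mean and variance of per-residue SASA within each Rg group."""
    if selected_labels is None:
        selected_labels = groups.labels
    topo = ensemble.topology
    means = np.zeros((topo.n_residues, len(selected_labels)))
    variances = np.zeros_like(means)
    for c, lab in enumerate(selected_labels):
        per_frame = np.array([
            residue_sasa(ensemble.coords[fi], topo, probe_radius, n_sphere_points)
            for fi in groups.members[lab]
        ])
        means[:, c] = per_frame.mean(axis=0)
        variances[:, c] = per_frame.var(axis=0)
    return PerResidueMatrix(means, variances, topo.residue_labels, list(selected_labels))


#: Theoretical maximum accessible surface areas per residue (Ų), from the
#: Gly-X-Gly tripeptide scale of Tien et al. (2013); the "expected" baseline
#: for normalized SASA. User-overridable.
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def normalized_sasa(observed: PerResidueMatrix, residue_names: Sequence[str],
                    expected: Optional[dict[str, float]] = None) -> PerResidueMatrix:
    """Observed minus expected SASA per residue (signed Ų).

    ``expected`` maps 3-letter residue codes to baseline areas (defaults to
    the theoretical maximum-ASA scale); the variance column is the
    across-group variance of the normalized values, one number per residue
    broadcast over groups.
    """
    if expected is None:
        expected = MAX_ASA_TIEN
    baseline = np.empty(len(residue_names))
    for i, name in enumerate(residue_names):
        if name not in expected:
            raise KeyError(f"no expected SASA for residue type {name!r}")
        baseline[i] = expected[name]
    values = observed.values - baseline[:, None]
    across = np.var(values, axis=1)
    variance = np.broadcast_to(across[:, None], values.shape).copy()
    return PerResidueMatrix(values, variance, observed.residue_labels, observed.group_labels)


def sasa_rg_density(total_sasa: np.ndarray, rg: np.ndarray,
                    bandwidths: Optional[tuple[float, float]] = None,
                    grid_size: int = 100) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-product KDE of frames over the (Rg, total SASA) plane.

    Bandwidths default to Scott's rule per dimension (σ·n^(−1/6)). Returns
    (rg_grid, sasa_grid, density); the density integrates to ≈1 over the
    grid, which extends 4 bandwidths beyond the data.
    """
    rg = np.asarray(rg, dtype=float)
    s = np.asarray(total_sasa, dtype=float)
    if rg.size < 2 or s.size != rg.size:
        raise ValueError("need >=2 paired (SASA, Rg) observations")
    if np.std(rg) == 0 or np.std(s) == 0:
        raise ValueError("zero variance in Rg or SASA; add jitter or more frames")
    n = rg.size
    if bandwidths is None:
        factor = n ** (-1.0 / 6.0)
        bandwidths = (np.std(rg) * factor, np.std(s) * factor)
    hx, hy = bandwidths
    x = np.linspace(rg.min() - 4 * hx, rg.max() + 4 * hx, grid_size)
    y = np.linspace(s.min() - 4 * hy, s.max() + 4 * hy, grid_size)
    gx = np.exp(-0.5 * ((x[:, None] - rg[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    gy = np.exp(-0.5 * ((y[:, None] - s[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = gx @ gy.T / n
    return x, y, density


# ---------------------------------------------------------------------------
# Hydrogen bonds (geometric) and contact maps


def detect_hydrogen_bonds(frame: np.ndarray, topology: Topology,
                          d_cutoff: float = 3.5, angle_cutoff: float = 30.0
                          ) -> list[tuple[int, int, int]]:
    """Geometric H-bonds in one frame: (donor atom, hydrogen, acceptor atom).

    Donor = N/O with a covalently attached H (nearest heavy N/O within
    1.25 Å); acceptor = any N/O of a different residue. Criterion:
    donor–acceptor distance ≤ d_cutoff and H–donor–acceptor angle ≤
    angle_cutoff (the ``gmx hbond`` convention). Donors without a resolvable
    H are skipped with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    heavy_na = np.array([i for i, e in enumerate(topology.elements) if e in ("N", "O")])
    h_atoms = [i for i, e in enumerate(topology.elements) if e == "H"]
    if len(heavy_na) == 0:
        return []
    tree = cKDTree(frame[heavy_na])
    donor_h: dict[int, list[int]] = {}
    for h in h_atoms:
        d, k = tree.query(frame[h])
        if d <= 1.25:
            donor_h.setdefault(int(heavy_na[k]), []).append(h)
        else:
            warnings.warn(f"hydrogen atom {h} has no bonded N/O donor; skipped")
    bonds = []
    cos_cut = np.cos(np.radians(angle_cutoff))
    for donor, hs in donor_h.items():
        d_res = topology.residue_index[donor]
        near = tree.query_ball_point(frame[donor], d_cutoff)
        for k in near:
            acc = int(heavy_na[k])
            if acc == donor or topology.residue_index[acc] == d_res:
                continue
            v_da = frame[acc] - frame[donor]
            n_da = np.linalg.norm(v_da)
            if n_da > d_cutoff or n_da == 0:
                continue
            for h in hs:
                v_dh = frame[h] - frame[donor]
                cosang = np.dot(v_dh, v_da) / (np.linalg.norm(v_dh) * n_da)
                if cosang >= cos_cut:
                    bonds.append((donor, h, acc))
                    break
    return bonds


def hbond_map(ensemble: Ensemble, groups: RgGroupSet,
              selected_labels: Optional[Sequence[int]] = None,
              d_cutoff: float = 3.5, angle_cutoff: float = 30.0,
              min_separation: int = 2) -> dict[int, tuple[np.ndarray, list[ContactRecord]]]:
    """Per-group residue × residue H-bond occupancy matrices.

    For each selected Rg group: a symmetric matrix whose (i, j) entry is the
    fraction of the group's frames in which residues i+1 and j+1 share at
    least one H-bond, plus the occupancy-ranked pair list. Self and
    adjacent-residue pairs (|i − j| < ``min_separation``) are excluded from
    the summary map.
    """
    if selected_labels is None:
        selected_labels = groups.labels
    topo = ensemble.topology
    nres = topo.n_residues
    out: dict[int, tuple[np.ndarray, list[ContactRecord]]] = {}
    for lab in selected_labels:
        if lab not in groups.members:
            raise KeyError(f"group {lab} not in partition (available: {groups.labels})")
        frames = groups.members[lab]
        counts = np.zeros((nres, nres))
        for fi in frames:
            seen = set()
            for donor, _h, acc in detect_hydrogen_bonds(
                    ensemble.coords[fi], topo, d_cutoff, angle_cutoff):
                i = int(topo.residue_index[donor]) - 1
                j = int(topo.residue_index[acc]) - 1
                if abs(i - j) < min_separation:
                    continue
                key = (min(i, j), max(i, j))
                if key not in seen:
                    seen.add(key)
                    counts[key[0], key[1]] += 1
        occ = counts / len(frames)
        occ = occ + occ.T
        records = [
            ContactRecord(i + 1, j + 1, occ[i, j])
            for i in range(nres) for j in range(i + 1, nres) if occ[i, j] > 0
        ]
        records.sort(key=lambda r: (-r.occupancy, r.donor_res, r.acceptor_res))
        out[lab] = (occ, records)
    return out


def residue_distance_map(ensemble: Ensemble, groups: RgGroupSet,
                         selected_labels: Optional[Sequence[int]] = None,
                         mode: str = "min-atom") -> dict[int, np.ndarray]:
    """Per-group mean residue–residue distance matrices (Å).

    ``mode='min-atom'`` uses the minimum heavy-atom distance per frame (the
    ``gmx pairdist`` default); ``'ca'`` uses Cα–Cα distances. Matrices are
    symmetric with a zero diagonal.
    """
    if mode not in ("min-atom", "ca"):
        raise ValueError("mode must be 'min-atom' or 'ca'")
    if selected_labels is None:
        selected_labels = groups.labels
    topo = ensemble.topology
    nres = topo.n_residues
    if mode == "ca":
        ca = topo.select_name("CA")
        if len(ca) != nres:
            raise ValueError("Cα mode needs one CA per residue")
    else:
        heavy = topo.heavy_atoms
        res_of = topo.residue_index[heavy] - 1
    out: dict[int, np.ndarray] = {}
    for lab in selected_labels:
        frames = groups.members[lab]
        acc = np.zeros((nres, nres))
        for fi in frames:
            X = ensemble.coords[fi]
            if mode == "ca":
                d = np.linalg.norm(X[ca][:, None] - X[ca][None, :], axis=-1)
            else:
                ha = X[heavy]
                dist = np.linalg.norm(ha[:, None] - ha[None, :], axis=-1)
                d = np.full((nres, nres), np.inf)
                for i in range(nres):
                    mi = res_of == i
                    for j in range(i, nres):
                        d[i, j] = d[j, i] = dist[np.ix_(mi, res_of == j)].min()
                np.fill_diagonal(d, 0.0)
            acc += d
        out[lab] = acc / len(frames)
    return out
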