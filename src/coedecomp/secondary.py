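"""Backbone dihedrals, Ramachandran region integration, and a reduced DSSP.

The Ramachandran analysis integrates the (φ, ψ) density over four fixed
windows — β-sheet, polyproline-II (PPII), α-helix and left-handed (LH)
helix — and reports the fraction of dihedral pairs falling in each. The
secondary-structure assignment is a reduced DSSP: Kabsch–Sander backbone
H-bond energies define n-turns, helices and bridges, a dihedral rule adds
the PPII class (absent from classic DSSP), and everything else is coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._geom import dihedral
from .ensemble_io import Ensemble, Topology
from .rg import RgGroupSet

__all__ = [
    "DihedralTable",
    "RamachandranRegions",
    "DEFAULT_REGIONS",
    "backbone_dihedrals",
    "ramachandran_histogram",
    "region_fractions",
    "kabsch_sander_energy",
    "kabsch_sander_bonds",
    "dssp_assign",
    "group_ss_fractions",
    "SS_LABELS",
]

SS_LABELS = ("H", "E", "T", "P", "C")


@dataclass
class DihedralTable:
    """Per-frame, per-residue (φ, ψ) in degrees; termini carry NaN.

    ``phi[:, 0]`` and ``psi[:, -1]`` are undefined by construction (no
    preceding C / following N); ``defined`` masks usable pairs.
    """

    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi shapes differ")
        for arr in (self.phi, self.psi):
            vals = arr[np.isfinite(arr)]
            if np.any(vals <= -180.0) or np.any(vals > 180.0):
                raise ValueError("angles must lie in (-180, 180]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.phi) & np.isfinite(self.psi)

    def defined_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of all defined (φ, ψ) pairs."""
        m = self.defined
        return self.phi[m], self.psi[m]


@dataclass(frozen=True)
class RamachandranRegions:
    """Named rectangular (φ, ψ) windows in degrees.

    ``regions`` maps name -> ((φ_lo, φ_hi), (ψ_lo, ψ_hi)). Membership is
    closed at the lower bound and open at the upper bound on each axis, so
    abutting windows never double-count a point.
    """

    regions: dict[str, tuple[tuple[float, float], tuple[float, float]]]

    def contains(self, name: str, phi, psi) -> np.ndarray:
        (plo, phi_hi), (slo, shi) = self.regions[name]
        phi = np.asarray(phi)
        psi = np.asarray(psi)
        return (phi >= plo) & (phi < phi_hi) & (psi >= slo) & (psi < shi)

    def names(self) -> list[str]:
        return list(self.regions)

    @classmethod
    def from_table(cls, path) -> "RamachandranRegions":
        """Read a region table: one row ``name phi_lo phi_hi psi_lo psi_hi``."""
        regions = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, plo, phi_hi, slo, shi = line.split()
                regions[name] = ((float(plo), float(phi_hi)), (float(slo), float(shi)))
        return cls(regions)

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# name phi_lo phi_hi psi_lo psi_hi\n")
            for name, ((plo, phi_hi), (slo, shi)) in self.regions.items():
                fh.write(f"{name} {plo:g} {phi_hi:g} {slo:g} {shi:g}\n")


#: The four secondary-structure windows used for Ramachandran integration.
DEFAULT_REGIONS = RamachandranRegions({
    "beta": ((-170.0, -120.0), (120.0, 180.0)),
    "ppii": ((-90.0, -40.0), (100.0, 180.0)),
    "alpha": ((-110.0, -40.0), (-50.0, 10.0)),
    "lh": ((30.0, 70.0), (10.0, 50.0)),
})


# ---------------------------------------------------------------------------
# Dihedrals


def backbone_dihedrals(ensemble: Ensemble) -> DihedralTable:
    """Compute φ/ψ for every frame and residue.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1); residues
    missing a backbone atom are masked undefined.
    """
    topo = ensemble.topology
    nres = topo.n_residues
    F = ensemble.n_frames
    idx = {
        name: [topo.atom_index(r + 1, name) for r in range(nres)]
        for name in ("N", "CA", "C")
    }
    phi = np.full((F, nres), np.nan)
    psi = np.full((F, nres), np.nan)
    X = ensemble.coords
    for r in range(nres):
        n_i, ca_i, c_i = idx["N"][r], idx["CA"][r], idx["C"][r]
        if None in (n_i, ca_i, c_i):
            continue
        if r > 0 and idx["C"][r - 1] is not None:
            phi[:, r] = dihedral(X[:, idx["C"][r - 1]], X[:, n_i], X[:, ca_i], X[:, c_i])
        if r < nres - 1 and idx["N"][r + 1] is not None:
            psi[:, r] = dihedral(X[:, n_i], X[:, ca_i], X[:, c_i], X[:, idx["N"][r + 1]])
    return DihedralTable(phi, psi)


def ramachandran_histogram(dihedrals: DihedralTable, bin_width: float = 2.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of defined (φ, ψ) pairs over [−180, 180]².

    Returns (counts, phi_edges, psi_edges); the grand total equals the number
    of defined pairs.
    """
    phi, psi = dihedrals.defined_pairs()
    if phi.size == 0:
        raise ValueError("no defined dihedral pairs")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, pe, se = np.histogram2d(phi, psi, bins=[edges, edges])
    return counts, pe, se


def region_fractions(dihedrals: DihedralTable,
                     regions: RamachandranRegions = DEFAULT_REGIONS) -> dict[str, float]:
    """Fraction of defined (φ, ψ) pairs inside each named window.

    Fractions need not sum to 1 — the windows do not tile the plane.
    """
    phi, psi = dihedrals.defined_pairs()
    total = phi.size
    if total == 0:
        return {name: 0.0 for name in regions.names()}
    return {
        name: float(np.count_nonzero(regions.contains(name, phi, psi))) / total
        for name in regions.names()
    }


# ---------------------------------------------------------------------------
# Kabsch–Sander hydrogen bonds and reduced DSSP


def _backbone_index(topo: Topology, name: str) -> list[Optional[int]]:
    return [topo.atom_index(r + 1, name) for r in range(topo.n_residues)]


def kabsch_sander_energy(frame: np.ndarray, topology: Topology,
                         donor_res: int, acceptor_res: int) -> float:
    """Electrostatic H-bond energy (kcal/mol) of N–H(donor) ··· O=C(acceptor).

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN); residues are
    1-based; identical or adjacent residues return +inf (no bond by
    definition).
    """
    if abs(donor_res - acceptor_res) < 2:
        return float("inf")
    n_i = topology.atom_index(donor_res, "N")
    h_i = topology.atom_index(donor_res, "H")
    c_j = topology.atom_index(acceptor_res, "C")
    o_j = topology.atom_index(acceptor_res, "O")
    if None in (n_i, h_i, c_j, o_j):
        raise ValueError("backbone N, H, C, O required for Kabsch-Sander energy")
    N, H, C, O = frame[n_i], frame[h_i], frame[c_j], frame[o_j]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    return float(0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def kabsch_sander_bonds(frame: np.ndarray, topology: Topology,
                        energy_cutoff: float = -0.5) -> np.ndarray:
    """Boolean matrix B[i, j]: CO of residue j+1 accepts the NH of residue i+1."""
    nres = topology.n_residues
    n_idx = _backbone_index(topology, "N")
    h_idx = _backbone_index(topology, "H")
    c_idx = _backbone_index(topology, "C")
    o_idx = _backbone_index(topology, "O")
    bonds = np.zeros((nres, nres), dtype=bool)
    for i in range(nres):
        if None in (n_idx[i], h_idx[i]):
            continue
        N, H = frame[n_idx[i]], frame[h_idx[i]]
        for j in range(nres):
            if abs(i - j) < 2 or None in (c_idx[j], o_idx[j]):
                continue
            C, O = frame[c_idx[j]], frame[o_idx[j]]
            r_on = np.linalg.norm(O - N)
            if r_on > 5.2:  # E cannot reach -0.5 kcal/mol beyond this
                continue
            e = 0.084 * 332.0 * (
                1.0 / r_on + 1.0 / np.linalg.norm(C - H)
                - 1.0 / np.linalg.norm(O - H) - 1.0 / np.linalg.norm(C - N)
            )
            bonds[i, j] = e < energy_cutoff
    return bonds


def _assign_frame(bonds: np.ndarray, phi: np.ndarray, psi: np.ndarray,
                  regions: RamachandranRegions) -> np.ndarray:
    """Reduced DSSP labels {H, E, T, P, C} for one frame."""
    nres = bonds.shape[0]
    # n-turn at i: CO(i) accepts NH(i+n) for n in 3,4,5
    turn = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(nres - n):
            if bonds[i + n, i]:
                turn[n][i] = True
    labels = np.full(nres, "C", dtype="U1")

    # helix: two consecutive 4-turns at i-1 and i label i..i+3
    helix = np.zeros(nres, dtype=bool)
    for i in range(1, nres - 4):
        if turn[4][i - 1] and turn[4][i]:
            helix[i:i + 4] = True

    # bridges: parallel / antiparallel ladder patterns
    bridge = np.zeros(nres, dtype=bool)
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            par = (bonds[j, i - 1] and bonds[i + 1, j]) or (bonds[i, j - 1] and bonds[j + 1, i])
            anti = (bonds[j, i] and bonds[i, j]) or (bonds[j + 1, i - 1] and bonds[i + 1, j - 1])
            if par or anti:
                bridge[i] = bridge[j] = True
    # require ladders of >=2 consecutive bridge residues
    strand = np.zeros(nres, dtype=bool)
    for i in range(nres - 1):
        if bridge[i] and bridge[i + 1]:
            strand[i] = strand[i + 1] = True

    # turns: interior residues of any n-turn
    in_turn = np.zeros(nres, dtype=bool)
    for n in (3, 4, 5):
        for i in np.nonzero(turn[n])[0]:
            in_turn[i + 1:i + n] = True

    # PPII: runs of >=2 residues inside the PPII dihedral window
    in_ppii_window = np.zeros(nres, dtype=bool)
    ok = np.isfinite(phi) & np.isfinite(psi)
    in_ppii_window[ok] = regions.contains("ppii", phi[ok], psi[ok])
    ppii = np.zeros(nres, dtype=bool)
    for i in range(nres - 1):
        if in_ppii_window[i] and in_ppii_window[i + 1]:
            ppii[i] = ppii[i + 1] = True

    labels[ppii] = "P"
    labels[in_turn & ~ppii] = "T"
    labels[in_turn & ppii] = "T"
    labels[strand] = "E"
    labels[helix] = "H"
    return labels


def dssp_assign(ensemble: Ensemble, frame_indices: Optional[Sequence[int]] = None,
                regions: RamachandranRegions = DEFAULT_REGIONS) -> np.ndarray:
    """Per-frame, per-residue reduced-DSSP labels (array of 'H','E','T','P','C').

    Priority H > E > T > P > C; PPII is dihedral-based (window membership in
    runs of ≥2 residues), the others come from Kabsch–Sander H-bond patterns.
    """
    if frame_indices is None:
        frame_indices = range(ensemble.n_frames)
    dih = backbone_dihedrals(ensemble)
    out = np.empty((len(list(frame_indices)), ensemble.topology.n_residues), dtype="U1")
    for k, fi in enumerate(frame_indices):
        bonds = kabsch_sander_bonds(ensemble.coords[fi], ensemble.topology)
        out[k] = _assign_frame(bonds, dih.phi[fi], dih.psi[fi], regions)
    return out


def group_ss_fractions(ensemble: Ensemble, groups: RgGroupSet,
                       selected_labels: Optional[Sequence[int]] = None,
                       regions: RamachandranRegions = DEFAULT_REGIONS) -> dict[int, dict[str, float]]:
    """Per-group fraction of residue-frames carrying each reduced-DSSP label.

    For every group the five fractions sum to 1.
    """
    if selected_labels is None:
        selected_labels = groups.labels
    result: dict[int, dict[str, float]] = {}
    for lab in selected_labels:
        if lab not in groups.members:
            raise KeyError(f"group {lab} not in partition (available: {groups.labels})")
        assign = dssp_assign(ensemble, groups.members[lab], regions)
        total = assign.size
        result[lab] = {s: float(np.count_nonzero(assign == s)) / total for s in SS_LABELS}
    return result
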