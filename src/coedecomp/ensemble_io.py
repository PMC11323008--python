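"""Reading and writing conformer ensembles and the associated flat-text formats.

Formats handled here:

* multi-MODEL PDB files (the ensemble container; all-atom or backbone-only),
* GROMACS-style ``.ndx`` frame-index files carrying an Rg-group partition,
* 2/3-column whitespace text for small-angle scattering curves.

Coordinates are Å everywhere inside the package (PDB native); frame indices
are 0-based in memory and 1-based in index files, following the GROMACS
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Ensemble",
    "ScatteringProfile",
    "FormatError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_saxs_curve",
    "write_saxs_curve",
    "read_group_index",
    "write_group_index",
    "ELEMENT_MASSES",
    "ELEMENT_VDW_RADII",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# Masses in amu; van der Waals radii in Å (Bondi).
ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
ELEMENT_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _element_from_name(name: str) -> str:
    """Infer the chemical element from a PDB atom name."""
    stripped = name.strip()
    if stripped[:2].upper() in ("SD", "SG"):  # Met/Cys sulfurs
        return "S"
    for ch in stripped:
        if ch.isalpha():
            el = ch.upper()
            break
    else:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if el not in ELEMENT_MASSES:
        raise FormatError(f"unsupported element {el!r} inferred from {name!r}")
    return el


@dataclass
class Topology:
    """Static chain description shared by every frame of an ensemble.

    ``residue_index`` is the 1-based residue ordinal of each atom and must be
    non-decreasing; ``residue_name`` has one 3-letter code per residue.
    Masses and radii are filled from the element tables when omitted.
    """

    atom_names: list[str]
    elements: list[str]
    residue_index: np.ndarray
    residue_name: list[str]
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]
    vdw_radius: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        for el in self.elements:
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unsupported element {el!r} (protein atoms are H/C/N/O/S)")
        if self.masses is None:
            self.masses = np.array([ELEMENT_MASSES[e] for e in self.elements])
        if self.vdw_radius is None:
            self.vdw_radius = np.array([ELEMENT_VDW_RADII[e] for e in self.elements])
        self.masses = np.asarray(self.masses, dtype=float)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if len(self.atom_names) != len(self.elements) or len(self.atom_names) != len(self.residue_index):
            raise ValueError("atom_names, elements and residue_index lengths differ")
        if self.residue_index[0] != 1 or np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must start at 1 and be non-decreasing")
        if self.residue_index[-1] != len(self.residue_name):
            raise ValueError("residue_name length does not match residue_index range")
        if np.any(self.masses <= 0) or np.any(self.vdw_radius <= 0):
            raise ValueError("masses and vdw radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_name)

    @property
    def residue_labels(self) -> list[str]:
        """1-letter code + 1-based position, e.g. ``D1``, ``Y24``."""
        return [
            THREE_TO_ONE.get(name, "X") + str(i + 1)
            for i, name in enumerate(self.residue_name)
        ]

    def atoms_of_residue(self, res_index: int) -> np.ndarray:
        """Atom indices of the 1-based residue ``res_index``."""
        return np.nonzero(self.residue_index == res_index)[0]

    def atom_index(self, res_index: int, name: str) -> Optional[int]:
        """Index of the atom called ``name`` in residue ``res_index`` (or None)."""
        for i in self.atoms_of_residue(res_index):
            if self.atom_names[i].strip() == name:
                return int(i)
        return None

    def select_name(self, name: str) -> np.ndarray:
        """Indices of all atoms with the given stripped PDB name."""
        return np.array(
            [i for i, n in enumerate(self.atom_names) if n.strip() == name], dtype=int
        )

    @property
    def heavy_atoms(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)


@dataclass
class Ensemble:
    """A conformer ensemble: F frames of A atoms in Å plus a topology.

    ``frame_stride`` is optional user metadata (time between saved frames,
    arbitrary units); ``hidden_states`` is filled by the synthetic generator
    when its two-state Markov chain is active.
    """

    coords: np.ndarray
    topology: Topology
    frame_stride: Optional[float] = None
    hidden_states: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, A, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class ScatteringProfile:
    """I(q) on a strictly increasing q grid (Å⁻¹), optional 1σ uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have the same length")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# PDB ensembles


def read_pdb_ensemble(path) -> Ensemble:
    """Read a multi-MODEL (or single-block) PDB file into an :class:`Ensemble`.

    Frames are ordered by MODEL number; every MODEL must carry the identical
    atom list. A missing element column is inferred from the atom name with a
    warning.
    """
    path = Path(path)
    frames: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    model_ids: list[str] = []
    inferred = False

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current:
                    frames.append(current)
                current = []
                in_model = True
                model_ids.append(line[6:].strip() or str(len(model_ids) + 1))
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                name = line[12:16]
                resname = line[17:20].strip()
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _element_from_name(name)
                    inferred = True
                current.append((name, resname, resseq, x, y, z, element.upper()))
    if current:
        frames.append(current)
        model_ids.append(str(len(model_ids) + 1))
    if not frames or not frames[0]:
        raise FormatError(f"{path}: no ATOM records found")
    if inferred:
        warnings.warn(f"{path}: element column missing; elements inferred from atom names")

    ref = [(a[0], a[1], a[2]) for a in frames[0]]
    for k, fr in enumerate(frames[1:], start=1):
        ident = [(a[0], a[1], a[2]) for a in fr]
        if ident != ref:
            model = model_ids[k] if k < len(model_ids) else str(k + 1)
            raise FormatError(f"{path}: MODEL {model} atom list differs from MODEL {model_ids[0]}")

    names = [a[0].strip() for a in frames[0]]
    elements = [a[6] for a in frames[0]]
    resseqs = np.array([a[2] for a in frames[0]])
    # renumber residues 1..R preserving order
    _, res_index = np.unique(resseqs, return_inverse=True)
    res_index = res_index + 1
    resnames: list[str] = []
    seen = set()
    for a in frames[0]:
        if a[2] not in seen:
            seen.add(a[2])
            resnames.append(a[1])
    topo = Topology(names, elements, res_index, resnames)
    coords = np.array([[(a[3], a[4], a[5]) for a in fr] for fr in frames])
    return Ensemble(coords, topo)


def write_pdb_ensemble(ensemble: Ensemble, path, frame_indices: Optional[Sequence[int]] = None) -> None:
    """Write the ensemble (or a frame subset) as a multi-MODEL PDB file."""
    if frame_indices is None:
        frame_indices = range(ensemble.n_frames)
    else:
        frame_indices = list(frame_indices)
        if len(frame_indices) == 0:
            raise ValueError("frame_indices must not be empty")
        for i in frame_indices:
            if not 0 <= i < ensemble.n_frames:
                raise IndexError(f"frame index {i} out of range [0, {ensemble.n_frames})")
    topo = ensemble.topology
    with open(path, "w") as fh:
        for model_no, fi in enumerate(frame_indices, start=1):
            fh.write(f"MODEL     {model_no:>4d}\n")
            for ai in range(topo.n_atoms):
                name = topo.atom_names[ai].strip()
                pdb_name = name if len(name) >= 4 else f" {name:<3s}"
                ri = int(topo.residue_index[ai])
                resname = topo.residue_name[ri - 1]
                x, y, z = ensemble.coords[fi, ai]
                fh.write(
                    f"ATOM  {ai + 1:>5d} {pdb_name:<4s} {resname:<3s} A{ri:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                    f"{topo.elements[ai]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# SAXS curves


def read_saxs_curve(path) -> ScatteringProfile:
    """Read a 2- or 3-column whitespace text curve (q, I, [σ]); '#' comments."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: expected at least 2 columns, got {len(parts)}")
            rows.append([float(p) for p in parts[:3]])
    if not rows:
        raise FormatError(f"{path}: empty curve")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows])
    q = data[:, 0]
    if np.any(np.diff(q) <= 0):
        raise FormatError(f"{path}: q values must be strictly increasing")
    sigma = data[:, 2] if ncol >= 3 else None
    return ScatteringProfile(q, data[:, 1], sigma)


def write_saxs_curve(profile: ScatteringProfile, path) -> None:
    """Write a curve in the same 2/3-column dialect read_saxs_curve accepts."""
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    np.savetxt(path, np.column_stack(cols), fmt="%.8e")


# ---------------------------------------------------------------------------
# GROMACS-style frame index files


def write_group_index(groups, path) -> None:
    """Write an Rg-group partition as a GROMACS ``.ndx``-dialect index file.

    One ``[ Rg_<label> ]`` section per group; 1-based frame numbers, at most
    15 numbers per line.
    """
    if not groups.labels:
        raise ValueError("group set is empty")
    with open(path, "w") as fh:
        for label in groups.labels:
            fh.write(f"[ Rg_{label} ]\n")
            members = [str(m + 1) for m in groups.members[label]]
            for i in range(0, len(members), 15):
                fh.write(" ".join(members[i:i + 15]) + "\n")


def read_group_index(path):
    """Read a ``.ndx`` frame-index file back into an :class:`~coedecomp.rg.RgGroupSet`.

    Sections must form a partition: a frame listed in two sections is an error.
    """
    from .rg import RgGroupSet  # deferred to avoid an import cycle

    path = Path(path)
    sections: dict[int, list[int]] = {}
    current_label: Optional[int] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith("["):
                name = line.strip("[] \t")
                if name.startswith("Rg_"):
                    name = name[3:]
                current_label = int(name)
                sections.setdefault(current_label, [])
            else:
                if current_label is None:
                    raise FormatError(f"{path}: frame numbers before any section header")
                sections[current_label].extend(int(tok) - 1 for tok in line.split())
    if not sections:
        raise FormatError(f"{path}: no sections found")
    seen: dict[int, int] = {}
    for label, members in sections.items():
        for m in members:
            if m in seen and seen[m] != label:
                raise FormatError(
                    f"{path}: frame {m + 1} assigned to both group {seen[m]} and {label}"
                )
            seen[m] = label
    members = {lab: np.array(sorted(v), dtype=int) for lab, v in sections.items()}
    return RgGroupSet(labels=sorted(sections), members=members, rg_per_frame=None)
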