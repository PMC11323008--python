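"""Synthetic Hst5-like backbone ensembles for exercising the full workflow.

Real inputs to the decomposition are multi-microsecond MD trajectories, which
are impractical to regenerate; this module emulates their statistical
features instead.  Frames are grown residue-by-residue with ideal peptide
geometry from (φ, ψ) pairs sampled out of the Ramachandran windows used
downstream, which gives

* a broad, smooth Rg distribution (compact helical/turn-rich frames through
  fully extended PPII/β frames),
* exact, generator-controlled region occupancies for parameter-recovery
  tests, and
* optional two-state Markov switching between a compact-biased and an
  extended-biased dihedral regime, producing the temporally correlated slow
  coordinate that the tICA stage is designed to find.

It does not emulate solvent, side-chain packing, or force-field energetics;
chains are backbone-only (N, H, CA, C, O) with optional Cβ pseudo-atoms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml
from scipy.spatial.distance import pdist

from ._geom import place_atom
from .ensemble_io import Ensemble, Topology, ONE_TO_THREE
from .secondary import DEFAULT_REGIONS, RamachandranRegions

__all__ = [
    "HISTATIN5",
    "GeneratorConfig",
    "net_charge",
    "sample_dihedrals",
    "build_backbone",
    "backbone_topology",
    "generate_ensemble",
    "COMPACT_WEIGHTS",
    "EXTENDED_WEIGHTS",
]

#: Histatin 5, the 24-residue cationic salivary IDP used as the model system.
HISTATIN5 = "DSHAKRHHGYKRKFHEKHHSHRGY"

# Ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0
OMEGA = 180.0

#: Dihedral regimes of the hidden two-state chain: the compact state favours
#: helix/turn-forming angles, the extended state PPII/β. Overridable per run.
COMPACT_WEIGHTS = {"beta": 0.0, "ppii": 0.0, "alpha": 0.55, "lh": 0.05, "coil": 0.40}
EXTENDED_WEIGHTS = {"beta": 0.30, "ppii": 0.50, "alpha": 0.0, "lh": 0.0, "coil": 0.20}

#: Default single-state occupancies: a disordered mix leaning extended,
#: in line with the β/PPII-dominated dihedral statistics of short cationic
#: IDPs, with a smaller helical and left-handed share.
DEFAULT_WEIGHTS = {"beta": 0.25, "ppii": 0.30, "alpha": 0.15, "lh": 0.03, "coil": 0.27}

REGION_NAMES = ("beta", "ppii", "alpha", "lh", "coil")


def net_charge(sequence: str = HISTATIN5, neutral_his: bool = True,
               charged_termini: bool = True) -> int:
    """Net charge (units of e) at neutral pH.

    Lys/Arg count +1, Asp/Glu −1; His is neutral by default (its pKa sits
    below 7); charged termini contribute +1 (N) and −1 (C), i.e. zero net.
    """
    charge = 0
    for aa in sequence.upper():
        if aa in "KR":
            charge += 1
        elif aa in "DE":
            charge -= 1
        elif aa == "H" and not neutral_his:
            charge += 1
    if charged_termini:
        charge += 1 - 1
    return charge


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-ensemble generator.

    ``region_weights`` are the single-state Ramachandran-region occupancies
    (must sum to 1); when ``switch_prob`` > 0 a hidden two-state Markov chain
    alternates between ``compact_weights`` and ``extended_weights`` instead,
    switching with the given per-frame probability.
    """

    sequence: str = HISTATIN5
    n_frames: int = 1000
    region_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    clash_cutoff: float = 2.0
    switch_prob: float = 0.0
    seed: int = 0
    with_cb: bool = False
    compact_weights: dict[str, float] = field(default_factory=lambda: dict(COMPACT_WEIGHTS))
    extended_weights: dict[str, float] = field(default_factory=lambda: dict(EXTENDED_WEIGHTS))

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.clash_cutoff <= 0:
            raise ValueError("clash_cutoff must be positive")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        for aa in self.sequence.upper():
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown residue letter {aa!r}")
        for w in (self.region_weights, self.compact_weights, self.extended_weights):
            _validate_weights(w)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _validate_weights(weights: dict[str, float]) -> None:
    unknown = set(weights) - set(REGION_NAMES)
    if unknown:
        raise ValueError(f"unknown region names {sorted(unknown)}; expected {REGION_NAMES}")
    vals = np.array([weights.get(n, 0.0) for n in REGION_NAMES])
    if np.any(vals < 0):
        raise ValueError("region weights must be non-negative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"region weights must sum to 1 (got {vals.sum()})")


def _sample_in_region(name: str, rng: np.random.Generator,
                      regions: RamachandranRegions) -> tuple[float, float]:
    if name == "coil":
        # uniform over the plane excluding the four named windows
        while True:
            phi = rng.uniform(-180.0, 180.0)
            psi = rng.uniform(-180.0, 180.0)
            if not any(regions.contains(r, phi, psi) for r in regions.names()):
                return phi, psi
    (plo, phi_hi), (slo, shi) = regions.regions[name]
    return rng.uniform(plo, phi_hi), rng.uniform(slo, shi)


def _sample_labels(nres: int, weights: dict[str, float],
                   rng: np.random.Generator) -> np.ndarray:
    probs = np.array([weights.get(n, 0.0) for n in REGION_NAMES])
    return rng.choice(len(REGION_NAMES), size=nres, p=probs / probs.sum())


def _angles_for_labels(labels: np.ndarray, rng: np.random.Generator,
                       regions: RamachandranRegions) -> tuple[np.ndarray, np.ndarray]:
    phi = np.empty(len(labels))
    psi = np.empty(len(labels))
    for r, c in enumerate(labels):
        phi[r], psi[r] = _sample_in_region(REGION_NAMES[c], rng, regions)
    return phi, psi


def sample_dihedrals(config: GeneratorConfig, rng: np.random.Generator,
                     weights: Optional[dict[str, float]] = None,
                     regions: RamachandranRegions = DEFAULT_REGIONS
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one frame's per-residue (φ, ψ) row in degrees.

    Each residue's region is drawn independently from ``weights`` (defaults
    to ``config.region_weights``) and its angles uniformly inside that
    region's window.
    """
    if weights is None:
        weights = config.region_weights
    labels = _sample_labels(len(config.sequence), weights, rng)
    return _angles_for_labels(labels, rng, regions)


def backbone_topology(sequence: str, with_cb: bool = False) -> Topology:
    """Topology of an ideal-geometry backbone chain (N, H, CA, C, O[, CB])."""
    names, elements, res_index, res_names = [], [], [], []
    for r, aa in enumerate(sequence.upper(), start=1):
        three = ONE_TO_THREE[aa]
        res_names.append(three)
        atoms = [("N", "N")]
        if three != "PRO":
            atoms.append(("H", "H"))
        atoms += [("CA", "C"), ("C", "C"), ("O", "O")]
        if with_cb and three != "GLY":
            atoms.append(("CB", "C"))
        for name, el in atoms:
            names.append(name)
            elements.append(el)
            res_index.append(r)
    return Topology(names, elements, np.array(res_index), res_names)


def build_backbone(sequence: str, dihedrals: tuple[np.ndarray, np.ndarray],
                   with_cb: bool = False) -> np.ndarray:
    """Grow one frame with ideal peptide geometry from per-residue (φ, ψ).

    ω is fixed at 180°; φ of the first and ψ of the last residue are taken
    from the supplied row (they steer only the terminal O/H placement).
    Returns coordinates matching :func:`backbone_topology` atom order.
    """
    phi, psi = (np.asarray(a, dtype=float) for a in dihedrals)
    nres = len(sequence)
    if phi.shape != (nres,) or psi.shape != (nres,):
        raise ValueError("need one (phi, psi) pair per residue")
    for aa in sequence.upper():
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {aa!r}")

    N = np.empty((nres, 3))
    CA = np.empty((nres, 3))
    C = np.empty((nres, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    th = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    for i in range(nres - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])

    coords = []
    for i, aa in enumerate(sequence.upper()):
        three = ONE_TO_THREE[aa]
        coords.append(N[i])
        if three != "PRO":
            if i == 0:
                h = place_atom(C[0], CA[0], N[0], BOND_N_H, 114.0, 180.0)
            else:
                # in the peptide plane, trans to the carbonyl O of residue i-1
                h = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_H, ANGLE_C_N_H, 0.0)
            coords.append(h)
        coords.append(CA[i])
        coords.append(C[i])
        # carbonyl O: trans to the next N about the CA-C axis
        coords.append(place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0))
        if with_cb and three != "GLY":
            coords.append(place_atom(N[i], C[i], CA[i], 1.530, 110.1, -122.6))
    return np.array(coords)


def _has_clash(frame: np.ndarray, topo: Topology, cutoff: float) -> bool:
    """True if any heavy-atom pair more than 2 residues apart is closer than cutoff."""
    heavy = topo.heavy_atoms
    res = topo.residue_index[heavy]
    d = pdist(frame[heavy])
    sep = pdist(res[:, None], metric="cityblock")
    return bool(np.any(d[sep > 2] < cutoff))


def generate_ensemble(config: GeneratorConfig,
                      regions: RamachandranRegions = DEFAULT_REGIONS) -> Ensemble:
    """Generate a synthetic ensemble under the configured study conditions.

    Each frame's region labels are drawn once; on a steric clash only the
    angles inside those fixed windows are redrawn (≤100 attempts, then the
    frame is accepted with a warning). Keeping the labels fixed during
    resampling leaves the region occupancies exactly multinomial in the
    configured weights — the clash filter cannot bias them. With
    ``switch_prob`` > 0 the hidden two-state Markov chain is recorded on the
    returned ensemble as ``hidden_states`` (0 = compact, 1 = extended).
    """
    rng = np.random.default_rng(config.seed)
    topo = backbone_topology(config.sequence, config.with_cb)
    two_state = config.switch_prob > 0
    state = int(rng.integers(2)) if two_state else None
    states = np.empty(config.n_frames, dtype=int) if two_state else None

    frames = np.empty((config.n_frames, topo.n_atoms, 3))
    n_forced = 0
    for f in range(config.n_frames):
        if two_state:
            if rng.random() < config.switch_prob:
                state = 1 - state
            states[f] = state
            weights = config.compact_weights if state == 0 else config.extended_weights
        else:
            weights = config.region_weights
        labels = _sample_labels(len(config.sequence), weights, rng)
        for attempt in range(100):
            row = _angles_for_labels(labels, rng, regions)
            frame = build_backbone(config.sequence, row, config.with_cb)
            if not _has_clash(frame, topo, config.clash_cutoff):
                break
        else:
            n_forced += 1
        frames[f] = frame
    if n_forced:
        warnings.warn(
            f"{n_forced} frame(s) kept with residual clashes after 100 resampling attempts"
        )
    return Ensemble(frames, topo, hidden_states=states)
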