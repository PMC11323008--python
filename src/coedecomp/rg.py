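"""Radius-of-gyration computation and decomposition of an ensemble into Rg groups.

The decomposition is the hinge of the whole workflow: every frame is assigned
to the integer-Å group nearest its mass-weighted Rg, and all downstream
analyses (scattering, SASA, H-bonds, RMSF, tICA, secondary structure) are run
per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ensemble_io import Ensemble

__all__ = ["RgGroupSet", "radius_of_gyration", "assign_rg_groups", "group_histogram"]


@dataclass
class RgGroupSet:
    """Partition of frame indices into integer-Å Rg groups.

    ``members`` maps each integer label to a sorted array of 0-based frame
    indices; the union over labels is exactly ``range(F)``. ``rg_per_frame``
    is retained for downstream statistics and is ``None`` only when the
    partition was read back from an index file.
    """

    labels: list[int]
    members: dict[int, np.ndarray]
    rg_per_frame: Optional[np.ndarray] = None
    low_sampling_fraction: float = 0.001

    def __post_init__(self) -> None:
        self.labels = sorted(int(l) for l in self.labels)
        if set(self.labels) != set(self.members):
            raise ValueError("labels and members keys differ")
        all_frames = np.concatenate([self.members[l] for l in self.labels]) if self.labels else np.array([], dtype=int)
        if len(np.unique(all_frames)) != len(all_frames):
            raise ValueError("groups overlap: not a partition")
        self.n_frames = len(all_frames)
        if self.rg_per_frame is not None:
            self.rg_per_frame = np.asarray(self.rg_per_frame, dtype=float)
            if len(self.rg_per_frame) != self.n_frames:
                raise ValueError("rg_per_frame length does not match partition size")

    def group_sizes(self) -> dict[int, int]:
        return {l: len(self.members[l]) for l in self.labels}

    def low_sampling_labels(self) -> list[int]:
        """Groups holding fewer than ``low_sampling_fraction`` of all frames.

        These are flagged (never dropped): sparsely populated extreme-Rg
        groups carry larger statistical errors in every per-group average.
        """
        cut = self.low_sampling_fraction * self.n_frames
        return [l for l in self.labels if len(self.members[l]) < cut]

    def top_k_labels(self, k: int) -> list[int]:
        """The k most populated group labels, in ascending label order."""
        ranked = sorted(self.labels, key=lambda l: (-len(self.members[l]), l))
        return sorted(ranked[:k])

    def mean_rg(self, label: int) -> float:
        if self.rg_per_frame is None:
            raise ValueError("rg_per_frame unavailable (partition read from file)")
        return float(np.mean(self.rg_per_frame[self.members[label]]))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float | np.ndarray:
    """Mass-weighted radius of gyration in Å.

    Rg = sqrt( Σ mᵢ ‖rᵢ − r_com‖² / Σ mᵢ ), the quantity ``gmx gyrate``
    reports (up to its nm unit). ``coords`` may be a single frame (A, 3) or a
    stack (F, A, 3); a stack returns one value per frame.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    com = np.einsum("fai,a->fi", coords, masses) / total
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(d2 @ masses / total)
    return float(rg[0]) if single else rg


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def assign_rg_groups(ensemble: Ensemble, low_sampling_fraction: float = 0.001) -> RgGroupSet:
    """Partition an ensemble's frames into integer-Å Rg groups.

    Each frame's label is its Rg rounded half-away-from-zero to the nearest
    integer Å; empty labels are omitted.
    """
    rg = radius_of_gyration(ensemble.coords, ensemble.topology.masses)
    rg = np.atleast_1d(rg)
    labels_per_frame = _round_half_away(rg).astype(int)
    members = {
        int(lab): np.nonzero(labels_per_frame == lab)[0]
        for lab in np.unique(labels_per_frame)
    }
    return RgGroupSet(
        labels=sorted(members),
        members=members,
        rg_per_frame=rg,
        low_sampling_fraction=low_sampling_fraction,
    )


def group_histogram(groups: RgGroupSet) -> dict[int, tuple[int, float]]:
    """Per-label (count, relative frequency); frequencies sum to 1."""
    total = groups.n_frames
    return {
        l: (len(groups.members[l]), len(groups.members[l]) / total)
        for l in groups.labels
    }
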