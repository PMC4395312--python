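"""Domain containers for serial-section trace data.

Coordinate convention (used throughout the package): X is medio-lateral
with lateral positive, Y is dorso-ventral with dorsal positive, the
origin is the central canal, and distances are in normalized hemicord
units (the baseline canal-to-lateral-edge distance is 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

POOL_LABELS = ("dorsal", "ventral")

GENOTYPES = ("wt", "mut")
HOUSINGS = ("NH", "EE_birth", "EE_4wk")
AGES_WEEKS = (4, 12)


def _as_points(a, n_expected=None, name="points"):
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1 and arr.size == 2:
        arr = arr.reshape(1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError(f"{name} must be an (n, 2) array, got shape {arr.shape}")
    if n_expected is not None and arr.shape[0] != n_expected:
        raise GeometryError(
            f"{name} must contain exactly {n_expected} points, got {arr.shape[0]}"
        )
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class SectionTrace:
    """One coronal section: traced neurons plus the landmark sets.

    ``lateral_edge`` holds exactly 5 points on the lateral edge of the
    grey matter, ordered dorsal to ventral; ``optical_refs`` the 4
    fiducial points used for rigid serial alignment; ``central_canal``
    and ``midsagittal_axis`` define the section's symmetry frame.
    """

    section_index: int
    z_um: float
    neurons: np.ndarray            # (n, 2)
    neuron_pools: np.ndarray       # (n,) of str in POOL_LABELS
    lateral_edge: np.ndarray       # (5, 2), ordered dorsal -> ventral
    central_canal: np.ndarray      # (2,)
    midsagittal_axis: np.ndarray   # (2,), unit norm
    optical_refs: np.ndarray       # (4, 2)

    def __post_init__(self):
        self.neurons = _as_points(self.neurons, name="neurons") if len(
            np.atleast_1d(self.neurons)
        ) else np.empty((0, 2))
        self.neuron_pools = np.asarray(self.neuron_pools, dtype=object)
        if self.neuron_pools.shape[0] != self.neurons.shape[0]:
            raise GeometryError("neuron_pools length must match neurons")
        unknown = set(self.neuron_pools) - set(POOL_LABELS)
        if unknown:
            raise GeometryError(f"unknown pool labels: {sorted(unknown)}")
        self.lateral_edge = _as_points(self.lateral_edge, 5, "lateral_edge")
        self.optical_refs = _as_points(self.optical_refs, 4, "optical_refs")
        self.central_canal = np.asarray(self.central_canal, dtype=float).reshape(2)
        axis = np.asarray(self.midsagittal_axis, dtype=float).reshape(2)
        nrm = np.linalg.norm(axis)
        if nrm == 0 or not np.isfinite(nrm):
            raise GeometryError("midsagittal_axis must be a nonzero finite vector")
        self.midsagittal_axis = axis / nrm

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SectionTrace":
        """Return a copy with the rigid map p -> R p + t applied to all geometry."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(2)
        return replace(
            self,
            neurons=self.neurons @ R.T + t,
            lateral_edge=self.lateral_edge @ R.T + t,
            central_canal=R @ self.central_canal + t,
            midsagittal_axis=R @ self.midsagittal_axis,
            optical_refs=self.optical_refs @ R.T + t,
        )

    def scaled_about_canal(self, factor: float) -> "SectionTrace":
        """Isotropic scaling of neurons and landmarks about the central canal.

        The optical reference points are fiducials of the imaging frame,
        not tissue, and are left untouched.
        """
        c = self.central_canal
        return replace(
            self,
            neurons=c + factor * (self.neurons - c),
            lateral_edge=c + factor * (self.lateral_edge - c),
        )


@dataclass
class SeriesTrace:
    """Ordered serial sections for one animal, anterior to posterior."""

    animal_id: str
    genotype: str
    housing: str
    age_weeks: int
    sections: list  # of SectionTrace
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise GeometryError(f"genotype must be one of {GENOTYPES}")
        if self.housing not in HOUSINGS:
            raise GeometryError(f"housing must be one of {HOUSINGS}")
        if len(self.sections) < 5:
            raise GeometryError("a series needs at least 5 sections")
        idx = [s.section_index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise GeometryError("section_index must be strictly increasing")

    def pool_points(self, pool_label: str) -> np.ndarray:
        pts = [
            s.neurons[s.neuron_pools == pool_label]
            for s in self.sections
            if s.neurons.shape[0]
        ]
        if not pts:
            return np.empty((0, 2))
        return np.vstack(pts)


@dataclass
class AlignedPool:
    """Pooled 2-D coordinates of one motor pool after alignment,
    normalization, and anterior-posterior projection."""

    pool_label: str
    points: np.ndarray  # (n, 2)
    n_neurons: int
    scale_factors: np.ndarray  # per-section isotropic factors applied

    def __post_init__(self):
        self.points = (
            _as_points(self.points, name="points")
            if np.size(self.points)
            else np.empty((0, 2))
        )
        if self.n_neurons != self.points.shape[0]:
            raise GeometryError("n_neurons must equal the number of pooled points")
        self.scale_factors = np.asarray(self.scale_factors, dtype=float)
        if self.scale_factors.size and np.any(self.scale_factors <= 0):
            raise GeometryError("scale factors must be positive")
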