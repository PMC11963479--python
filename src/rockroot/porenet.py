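"""Pore-space metrics on binary micro-CT volumes.

A pore network is extracted from a segmented (binary) voxel volume by
watershed partitioning of the Euclidean distance transform: each basin
is a pore, and two pores are connected when their basins share at least
one voxel face.  From the network the module computes air-filled
porosity, connectivity density ``(1 - (n - b)) / V`` (an Euler-number
based count of redundant connections per volume), the coordination
number (mean branches per pore), and the pore width (median diameter of
the maximal inscribed sphere per pore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import DomainError, MeasurementError

__all__ = [
    "PoreVolume",
    "PoreNetwork",
    "binarize",
    "image_porosity",
    "extract_network",
    "connectivity_density",
    "coordination_number",
    "pore_width",
]


@dataclass(frozen=True)
class PoreVolume:
    """Binary 3D pore-space volume (1 = pore, 0 = matrix)."""

    voxels: np.ndarray
    voxel_size: float = 0.9  # um

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DomainError(f"pore volume must be 3D, got {v.ndim}D")
        if self.voxel_size <= 0:
            raise DomainError("voxel_size must be > 0")
        vals = np.unique(v)
        if not np.isin(vals, (0, 1)).all():
            raise DomainError("pore volume must be binary (0/1)")
        object.__setattr__(self, "voxels", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_mm3(self) -> float:
        """Total analyzed volume in mm3."""
        return self.voxels.size * (self.voxel_size * 1e-3) ** 3


@dataclass(frozen=True)
class PoreNetwork:
    """Pores/connections graph extracted from a :class:`PoreVolume`.

    ``n`` pores, ``b`` distinct pore-to-pore connections, per-pore branch
    counts (``degrees``), per-pore maximal-inscribed-sphere diameters
    (mm), and the analyzed volume ``V`` (mm3).
    """

    n: int
    b: int
    degrees: tuple[int, ...]
    inscribed_diameters: tuple[float, ...]
    V: float
    labels: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.n < 0 or self.b < 0:
            raise MeasurementError("n and b must be non-negative")
        if len(self.degrees) != self.n:
            raise MeasurementError("degrees must have one entry per pore")
        if any(d <= 0 for d in self.inscribed_diameters):
            raise MeasurementError("inscribed diameters must be > 0")


def binarize(
    volume: np.ndarray, threshold: float, *, pore_below: bool = True, voxel_size: float = 0.9
) -> PoreVolume:
    """Global-threshold segmentation of a grayscale volume.

    With ``pore_below=True`` (air darker than matrix, the usual
    absorption-contrast convention) voxels with intensity <= threshold
    become pore.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise DomainError(f"expected a 3D grayscale volume, got {volume.ndim}D")
    lo, hi = float(volume.min()), float(volume.max())
    if not lo <= threshold <= hi:
        raise DomainError(
            f"threshold {threshold} outside intensity range [{lo}, {hi}]"
        )
    mask = volume <= threshold if pore_below else volume >= threshold
    return PoreVolume(mask.astype(np.uint8), voxel_size=voxel_size)


def image_porosity(pv: PoreVolume) -> float:
    """Air-filled porosity (%) = 100 * pore voxels / total voxels."""
    return 100.0 * float(pv.voxels.sum()) / pv.voxels.size


def extract_network(pv: PoreVolume, *, merge_tol: float = 1.0) -> PoreNetwork:
    """Partition the pore phase into pores and extract their connections.

    Pores are watershed basins of the Euclidean distance transform,
    seeded at its regional maxima; maxima whose prominence is below
    ``merge_tol`` voxels are merged into their parent (suppressing
    spurious seeds from voxelization ripple on ridges).  Connections are
    unordered basin pairs sharing at least one voxel face
    (6-connectivity); pore-phase components themselves are treated with
    full 26-connectivity inside the watershed.
    """
    pore = pv.voxels.astype(bool)
    if not pore.any():
        return PoreNetwork(n=0, b=0, degrees=(), inscribed_diameters=(), V=pv.volume_mm3)

    edt = ndimage.distance_transform_edt(pore)
    # prominence-filtered regional maxima; h_maxima handles plateaus that
    # drain toward a higher neighbour (e.g. along a connecting throat)
    seeds_mask = h_maxima(edt, merge_tol) & pore
    markers, _ = ndimage.label(seeds_mask, structure=np.ones((3, 3, 3), dtype=int))
    labels = watershed(-edt, markers=markers, mask=pore)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    n = ids.size
    relabel = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    relabel[ids] = np.arange(1, n + 1)
    labels = relabel[labels]

    pairs = set()
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)[:-1]
        b_ = np.moveaxis(labels, axis, 0)[1:]
        touching = (a > 0) & (b_ > 0) & (a != b_)
        if touching.any():
            lo = np.minimum(a[touching], b_[touching])
            hi = np.maximum(a[touching], b_[touching])
            pairs.update(zip(lo.tolist(), hi.tolist()))

    degrees = np.zeros(n, dtype=int)
    for i, j in pairs:
        degrees[i - 1] += 1
        degrees[j - 1] += 1

    # maximal inscribed sphere per pore: 2 * max EDT within the basin
    max_edt = ndimage.maximum(edt, labels=labels, index=np.arange(1, n + 1))
    diameters_mm = 2.0 * np.atleast_1d(max_edt) * pv.voxel_size * 1e-3

    return PoreNetwork(
        n=n,
        b=len(pairs),
        degrees=tuple(int(d) for d in degrees),
        inscribed_diameters=tuple(float(d) for d in diameters_mm),
        V=pv.volume_mm3,
        labels=labels,
    )


def connectivity_density(net: PoreNetwork) -> float:
    """Connectivity density (1 - (n - b)) / V in mm-3.

    Counts redundant (loop-forming) connections per unit volume via the
    Euler characteristic of the pore graph; negative for fragmented pore
    space (many isolated pores)."""
    if net.V <= 0:
        raise MeasurementError("network volume must be > 0")
    return (1.0 - (net.n - net.b)) / net.V


def coordination_number(net: PoreNetwork) -> float:
    """Mean number of branches spreading out of each pore."""
    if net.n == 0:
        raise MeasurementError("coordination number undefined for an empty network")
    return float(np.mean(net.degrees))


def pore_width(pv: PoreVolume, net: PoreNetwork) -> float:
    """Median maximal-inscribed-sphere diameter across pores (mm)."""
    if net.n == 0:
        raise MeasurementError("pore width undefined for an empty network")
    return float(np.median(net.inscribed_diameters))
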