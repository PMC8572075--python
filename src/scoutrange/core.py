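"""Core containers and conventions shared by every pipeline stage.

Coordinate convention (used everywhere, stated once):

* volumes are indexed ``(slice, row, col)``;
* slice index 0 is the most **superior** slice;
* the craniocaudal coordinate ``z`` is measured in millimetres at slice
  centres and **increases caudally** (toward the feet);
* rows run anterior -> posterior (AP axis), columns right -> left
  (lateral axis);
* scan ranges are inclusive limits at slice centres, so a valid range
  always has ``superior_z < inferior_z``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "CTVolume",
    "LungMask3D",
    "TCMProfile",
    "Projection2D",
    "Mask2D",
    "ScanRange",
    "OverscanReport",
    "stage_rng",
    "stage_seed",
]

HU_MIN = -1024.0
HU_MAX = 3071.0

View = Literal["AP", "LAT"]
Provenance = Literal["exact", "human", "DL_AP", "DL_Lat", "DL_Both"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a child seed < 2**31 for a named pipeline stage.

    All randomness in a run flows from one root seed; each stage mixes its
    name into the root via SHA-256 so stages are decorrelated but fully
    reproducible.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Seeded generator for one named stage (see :func:`stage_seed`)."""
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class TCMProfile:
    """Tube-current modulation: one mA value per slice, superior first."""

    ma_per_slice: np.ndarray
    pitch: float = 1.0

    def __post_init__(self) -> None:
        self.ma_per_slice = np.asarray(self.ma_per_slice, dtype=float)
        if self.ma_per_slice.ndim != 1:
            raise ValueError("TCM profile must be one mA value per slice")
        if np.any(self.ma_per_slice <= 0):
            raise ValueError("tube current must be positive for every slice")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    def __len__(self) -> int:
        return self.ma_per_slice.size

    def effective_mas(self, rotation_time_s: float = 0.5) -> float:
        """Effective tube-current--time product, mAs / pitch."""
        return float(self.ma_per_slice.mean() * rotation_time_s / self.pitch)


@dataclass
class CTVolume:
    """A chest CT volume in Hounsfield units with acquisition metadata.

    ``voxels`` has shape ``(n_slices, n_rows, n_cols)``; ``spacing`` is
    ``(row_mm, col_mm, slice_mm)``; ``z0`` is the z coordinate (mm) of the
    centre of slice 0 (the most superior slice).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    ctdi_vol: float = 0.0
    kvp: float = 120.0
    tcm: TCMProfile | None = None
    z0: float = 0.0
    patient_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (slice, row, col) grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN - 1e-6 or hi > HU_MAX + 1e-6:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]"
            )
        if self.tcm is not None and len(self.tcm) != self.n_slices:
            raise ValueError("TCM profile length must equal slice count")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_spacing(self) -> float:
        return self.spacing[2]

    def slice_z(self, index) -> np.ndarray | float:
        """z (mm) of a slice centre; increases caudally from slice 0."""
        return self.z0 + np.asarray(index) * self.slice_spacing


@dataclass
class LungMask3D:
    """Binary lung mask congruent with a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    z0: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D (slice, row, col) grid")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_spacing(self) -> float:
        return self.spacing[2]

    def occupied_slices(self) -> np.ndarray:
        return np.flatnonzero(self.voxels.any(axis=(1, 2)))


@dataclass
class Projection2D:
    """Scout-like 2D projection; rows are craniocaudal (superior first).

    ``z0``/``dz`` define the affine row -> z(mm) map at pixel centres:
    ``z(r) = z0 + r * dz``.
    """

    pixels: np.ndarray
    view: View
    z0: float
    dz: float
    normalization: dict | None = None
    provenance: Literal["summed", "scout"] = "summed"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection pixels must be finite")

    def row_to_z(self, row) -> np.ndarray | float:
        return self.z0 + np.asarray(row, dtype=float) * self.dz

    def z_to_row(self, z) -> np.ndarray | float:
        return (np.asarray(z, dtype=float) - self.z0) / self.dz


@dataclass
class Mask2D:
    """Binary 2D lung mask congruent with a :class:`Projection2D`."""

    pixels: np.ndarray
    view: View
    z0: float
    dz: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.dz <= 0:
            raise ValueError("dz must be positive")

    def row_to_z(self, row) -> np.ndarray | float:
        return self.z0 + np.asarray(row, dtype=float) * self.dz

    def occupied_rows(self) -> np.ndarray:
        return np.flatnonzero(self.pixels.any(axis=1))


@dataclass
class ScanRange:
    """Craniocaudal scan limits in patient millimetres (inclusive)."""

    superior_z: float
    inferior_z: float
    provenance: Provenance = "exact"

    def __post_init__(self) -> None:
        # equality is allowed: a single-slice range has zero length between
        # slice centres but still covers one slice (inclusive limits)
        if not self.superior_z <= self.inferior_z:
            raise ValueError(
                "superior limit must lie cranial to (smaller z than) the "
                f"inferior limit; got ({self.superior_z}, {self.inferior_z})"
            )

    @property
    def length_mm(self) -> float:
        return self.inferior_z - self.superior_z

    def with_provenance(self, provenance: Provenance) -> "ScanRange":
        return replace(self, provenance=provenance)


@dataclass
class OverscanReport:
    """Signed range-selection errors, positive = overscan, negative = missed lung."""

    superior_error_mm: float
    inferior_error_mm: float

    @property
    def overscan_superior(self) -> bool:
        return self.superior_error_mm > 0

    @property
    def overscan_inferior(self) -> bool:
        return self.inferior_error_mm > 0
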