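"""Scout-like 2D projections from 3D CT, with exact row -> z bookkeeping.

A localizer (scout) view is emulated by line-integrating the attenuation
``max(HU + 1000, 0)`` along the AP or lateral axis, so air contributes
nothing and pixel values are non-negative, as on a radiograph.  Lung masks
are projected with a logical OR along the same rays, which guarantees that
a slice contains lung voxels iff the corresponding projection row contains
mask pixels — the property scan-range conversion relies on.

Every projection carries an affine row -> z(mm) map that is updated through
resizing, so craniocaudal limits read off any processed image refer back to
the original patient coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import CTVolume, LungMask3D, Mask2D, Projection2D

__all__ = [
    "ScoutGeometry",
    "project_volume",
    "project_mask",
    "normalize_resize",
    "apply_magnification",
]


@dataclass
class ScoutGeometry:
    """Scout acquisition geometry for the magnification distortion model.

    ``table_height_offset`` is the object plane's offset (mm) from the
    isocenter along the beam axis, positive toward the source.
    """

    source_detector_distance: float = 1040.0
    source_isocenter_distance: float = 570.0
    table_height_offset: float = 0.0

    def validate(self) -> None:
        if not 0 < self.source_isocenter_distance < self.source_detector_distance:
            raise ValueError(
                "need 0 < source-isocenter distance < source-detector distance"
            )
        if self.table_height_offset >= self.source_isocenter_distance:
            raise ValueError("object plane lies at or beyond the source")

    @property
    def magnification(self) -> float:
        """Column scale factor M = SDD / (SDD - y) at the object plane."""
        return self.source_detector_distance / (
            self.source_detector_distance - self.table_height_offset
        )


def _ray_axis(view: str) -> tuple[int, int]:
    """(axis summed over, spacing index of that axis) for a view."""
    if view == "AP":
        return 1, 0  # integrate along rows (AP axis)
    if view == "LAT":
        return 2, 1  # integrate along columns (lateral axis)
    raise ValueError(f"view must be 'AP' or 'LAT', got {view!r}")


def project_volume(volume: CTVolume, view: str = "AP") -> Projection2D:
    """Sum-projection of attenuation along the AP or lateral axis.

    ``pixel(r, c) = sum_ray max(HU + 1000, 0) * step_mm``; row ``r``
    corresponds to slice ``r`` so ``dz`` equals the slice spacing.  No
    normalization is applied here.
    """
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    axis, sp_idx = _ray_axis(view)
    atten = np.clip(volume.voxels.astype(np.float64) + 1000.0, 0.0, None)
    pixels = atten.sum(axis=axis) * volume.spacing[sp_idx]
    return Projection2D(
        pixels,
        view=view,
        z0=volume.z0,
        dz=volume.slice_spacing,
        normalization=None,
        provenance="summed",
    )


def project_mask(mask: LungMask3D, view: str = "AP") -> Mask2D:
    """Project a 3D lung mask with a logical OR along the view's rays.

    The row set of the result equals the slice set of the 3D mask exactly.
    An empty 3D mask yields an empty 2D mask with a warning.
    """
    axis, _ = _ray_axis(view)
    pixels = mask.voxels.any(axis=axis)
    if not pixels.any():
        warnings.warn("projecting an empty lung mask", stacklevel=2)
    return Mask2D(pixels, view=view, z0=mask.z0, dz=mask.slice_spacing)


def normalize_resize(
    projection: Projection2D,
    mask: Mask2D | None = None,
    size: int = 256,
) -> tuple[Projection2D, Mask2D | None]:
    """Min-max normalize to [0, 1] and resample to ``size x size``.

    Intensity is resampled with a smooth (bilinear, anti-aliased)
    interpolant, masks with nearest-neighbour so they stay binary.  The
    row -> z affine is updated with the pixel-centre convention so any row of
    the resized image maps to the same patient z as the source grid.
    """
    if size < 32:
        raise ValueError("output size must be at least 32")
    rows = projection.pixels.shape[0]
    scale = rows / size
    resized = _sk_resize(
        projection.pixels.astype(np.float64),
        (size, size),
        order=1,
        anti_aliasing=scale > 1,
        preserve_range=True,
    )
    # normalize after resampling, so the output range is exactly [0, 1]
    lo, hi = float(resized.min()), float(resized.max())
    if hi - lo <= 0:
        warnings.warn(
            "constant-intensity projection: normalization degenerates to zeros",
            stacklevel=2,
        )
        resized = np.zeros_like(resized)
    else:
        resized = (resized - lo) / (hi - lo)
    new_z0 = projection.z0 + projection.dz * (scale - 1.0) / 2.0
    new_dz = projection.dz * scale
    out_p = Projection2D(
        resized,
        view=projection.view,
        z0=new_z0,
        dz=new_dz,
        normalization={"method": "minmax", "min": lo, "max": hi, "size": size},
        provenance=projection.provenance,
    )

    out_m = None
    if mask is not None:
        if mask.pixels.shape != projection.pixels.shape:
            raise ValueError("mask and projection shapes differ")
        m_resized = _sk_resize(
            mask.pixels.astype(float),
            (size, size),
            order=0,
            anti_aliasing=False,
            preserve_range=True,
        )
        out_m = Mask2D(m_resized > 0.5, view=mask.view, z0=new_z0, dz=new_dz)
    return out_p, out_m


def apply_magnification(
    projection: Projection2D,
    mask: Mask2D | None,
    geom: ScoutGeometry,
) -> tuple[Projection2D, Mask2D | None]:
    """Apply the scout magnification distortion to the transverse axis.

    Columns are scaled about the image centre by ``M = SDD / (SDD - y)``
    with ``y`` the object plane's offset from isocenter along the beam axis
    (``geom.table_height_offset``).  Rows (craniocaudal) are untouched
    because scout acquisition translates the table along z: the set of
    occupied mask rows is invariant under this distortion.

    Intensity is resampled smoothly (inverse mapping); the mask is forward
    mapped so thin structures never vanish.
    """
    geom.validate()
    m_factor = geom.magnification
    n_rows, n_cols = projection.pixels.shape
    centre = (n_cols - 1) / 2.0

    cols_out = np.arange(n_cols, dtype=float)
    src_cols = centre + (cols_out - centre) / m_factor
    row_idx = np.repeat(np.arange(n_rows, dtype=float)[:, None], n_cols, axis=1)
    col_idx = np.repeat(src_cols[None, :], n_rows, axis=0)
    warped = ndimage.map_coordinates(
        projection.pixels.astype(np.float64),
        [row_idx, col_idx],
        order=1,
        mode="constant",
        cval=0.0,
    )
    out_p = Projection2D(
        warped,
        view=projection.view,
        z0=projection.z0,
        dz=projection.dz,
        normalization=projection.normalization,
        provenance="scout",
    )

    out_m = None
    if mask is not None:
        rr, cc = np.nonzero(mask.pixels)
        new_pixels = np.zeros_like(mask.pixels)
        if rr.size:
            new_cc = np.round(centre + (cc - centre) * m_factor).astype(int)
            keep = (new_cc >= 0) & (new_cc < n_cols)
            # Forward splat; clamp one pixel per row inside the frame so a
            # row never loses all of its (possibly single) lung pixels.
            if not np.all(keep):
                new_cc = np.clip(new_cc, 0, n_cols - 1)
            new_pixels[rr, new_cc] = True
        out_m = Mask2D(new_pixels, view=mask.view, z0=mask.z0, dz=mask.dz)
    return out_p, out_m
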