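"""Mask -> scan-range conversion, view combination, overscan accounting.

The scan range of a 2D lung mask is the z of its first occupied row
(superior limit) to the z of its last occupied row (inferior limit), with a
safety margin of one voxel in each direction by default.  Errors follow the
overscan sign convention: positive means coverage beyond the lung
(overscanning), negative means lung slices were excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.measure import label

from .core import Mask2D, OverscanReport, ScanRange

__all__ = [
    "postprocess_mask",
    "mask_to_range",
    "combine_ranges",
    "overscan_error",
    "summarize_cohort",
]

_VIEW_PROVENANCE = {"AP": "DL_AP", "LAT": "DL_Lat"}


def postprocess_mask(mask: Mask2D, min_pixels: int = 50) -> Mask2D:
    """Drop spurious small components, always keeping the largest one.

    Removes connected components smaller than ``min_pixels``; the largest
    component survives even if it is below the cutoff.  Idempotent.
    """
    lab = label(mask.pixels)
    if lab.max() == 0:
        warnings.warn("post-processing an empty mask", stacklevel=2)
        return Mask2D(mask.pixels.copy(), view=mask.view, z0=mask.z0, dz=mask.dz)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= min_pixels)
    largest = sizes.argmax()
    if largest not in keep:
        keep = np.append(keep, largest)
    out = np.isin(lab, keep)
    return Mask2D(out, view=mask.view, z0=mask.z0, dz=mask.dz)


def mask_to_range(
    mask: Mask2D,
    margin_voxels: int = 1,
    provenance: str | None = None,
) -> ScanRange:
    """Craniocaudal scan range of a 2D mask via its row -> z affine.

    The superior limit is the z of the first occupied row minus
    ``margin_voxels`` rows, the inferior limit the z of the last occupied
    row plus the margin, both clipped to the image extent.
    """
    occ = mask.occupied_rows()
    if occ.size == 0:
        raise ValueError("no lung found")
    n_rows = mask.pixels.shape[0]
    first = max(int(occ[0]) - margin_voxels, 0)
    last = min(int(occ[-1]) + margin_voxels, n_rows - 1)
    if provenance is None:
        provenance = _VIEW_PROVENANCE.get(mask.view, "exact")
    return ScanRange(
        float(mask.row_to_z(first)), float(mask.row_to_z(last)),
        provenance=provenance,
    )


def combine_ranges(
    ap: ScanRange, lat: ScanRange, rule: str = "average"
) -> ScanRange:
    """Combine AP- and lateral-view ranges into one (provenance DL_Both).

    ``average`` takes the mean of the two views' limits; ``union`` the most
    superior top and most inferior bottom; ``intersection`` the opposite.
    """
    if rule == "average":
        sup = (ap.superior_z + lat.superior_z) / 2.0
        inf = (ap.inferior_z + lat.inferior_z) / 2.0
    elif rule == "union":
        sup = min(ap.superior_z, lat.superior_z)
        inf = max(ap.inferior_z, lat.inferior_z)
    elif rule == "intersection":
        sup = max(ap.superior_z, lat.superior_z)
        inf = min(ap.inferior_z, lat.inferior_z)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return ScanRange(sup, inf, provenance="DL_Both")


def overscan_error(selected: ScanRange, truth: ScanRange) -> OverscanReport:
    """Signed superior/inferior errors of a selected range vs the truth.

    Positive superior error: the selected range extends cranially beyond
    the lung.  Positive inferior error: it extends caudally beyond the
    lung.  Negative values mean lung was excluded.
    """
    return OverscanReport(
        superior_error_mm=truth.superior_z - selected.superior_z,
        inferior_error_mm=selected.inferior_z - truth.inferior_z,
    )


def summarize_cohort(reports) -> pd.DataFrame:
    """Per-direction summary: mean, SD, min, Q1, Q3, max, overscan fraction."""
    reports = list(reports)
    if not reports:
        raise ValueError("empty report list")
    data = {
        "superior": np.array([r.superior_error_mm for r in reports], dtype=float),
        "inferior": np.array([r.inferior_error_mm for r in reports], dtype=float),
    }
    rows = []
    for direction, err in data.items():
        rows.append(
            {
                "direction": direction,
                "n": err.size,
                "mean": err.mean(),
                "sd": err.std(ddof=1) if err.size > 1 else 0.0,
                "min": err.min(),
                "q1": np.quantile(err, 0.25),
                "q3": np.quantile(err, 0.75),
                "max": err.max(),
                "overscan_fraction": float((err > 0).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("direction")
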