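"""Dendritic cell counting and density estimation.

Cell counts come from connected components of the class channels of a
one-hot segmentation mask (8-connectivity, minimum component area 10 px by
default so single-pixel noise never counts). Densities follow the
per-participant convention: the average per-image count divided by the
analyzed image area, separately per morphology class, with the total
density the exact sum of the two class densities.

Known limitation, shared with manual grading of crowded images: touching
cells of the same class merge into a single component and are counted once.
Components touching the image border are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import CellClass, MaskKind, SegmentationMask
from .units import cells_per_image

__all__ = ["DCCounts", "DCDensities", "count_components", "count_image",
           "densities_participant", "cells_per_image"]

_EIGHT = np.ones((3, 3), dtype=int)

_CLASS_CHANNEL = {
    CellClass.WITH_DENDRITES: 1,
    CellClass.WITHOUT_DENDRITES: 2,
}


@dataclass(frozen=True)
class DCCounts:
    """Per-image dendritic cell counts by morphology class."""

    image_id: str
    n_with: int
    n_without: int

    def __post_init__(self) -> None:
        if self.n_with < 0 or self.n_without < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DCDensities:
    """Per-participant densities (cells/mm^2) for both classes and total."""

    subject_id: str
    density_with: float
    density_without: float
    density_total: float
    area_mm2: float


def count_components(
    mask: SegmentationMask | np.ndarray,
    cell_class: CellClass | str,
    min_area_px: int = 10,
) -> int:
    """Number of 8-connected components of one class channel.

    Components smaller than ``min_area_px`` pixels are ignored.
    """
    cell_class = CellClass(cell_class)
    if isinstance(mask, SegmentationMask):
        if mask.kind is not MaskKind.DC_ONEHOT:
            raise ValueError("count_components requires a dc_onehot mask")
        channel = mask.data[_CLASS_CHANNEL[cell_class]]
    else:
        channel = np.asarray(mask)
    labels, n = ndimage.label(channel.astype(bool), structure=_EIGHT)
    if n == 0 or min_area_px <= 1:
        return int(n)
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_area_px))


def count_image(mask: SegmentationMask, image_id: str = "",
                min_area_px: int = 10) -> DCCounts:
    """Counts of both cell classes for one image."""
    return DCCounts(
        image_id=image_id,
        n_with=count_components(mask, CellClass.WITH_DENDRITES, min_area_px),
        n_without=count_components(mask, CellClass.WITHOUT_DENDRITES, min_area_px),
    )


def densities_participant(
    counts: Sequence[DCCounts],
    area_mm2: float = 0.16,
    subject_id: str = "",
) -> DCDensities:
    """Participant DC densities: mean per-image count / image area, per class.

    The total density is the exact sum of the two class densities.
    """
    if not counts:
        raise ValueError("participant has no usable images")
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    mean_with = sum(c.n_with for c in counts) / len(counts)
    mean_without = sum(c.n_without for c in counts) / len(counts)
    d_with = mean_with / area_mm2
    d_without = mean_without / area_mm2
    return DCDensities(
        subject_id=subject_id,
        density_with=d_with,
        density_without=d_without,
        density_total=d_with + d_without,
        area_mm2=area_mm2,
    )
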