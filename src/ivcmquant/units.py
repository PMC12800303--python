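"""Unit conventions used throughout the package.

All conversions between pixels, micrometres and millimetres live here so the
rest of the code can stay unit-honest: curve lengths are reported in mm,
densities in mm/mm**2 (nerves) or cells/mm**2 (dendritic cells), and the pixel
pitch in micrometres per pixel.

The imaging geometry follows the Heidelberg HRT3-RCM convention for corneal
confocal images: a 384 x 384 pixel frame covering a 400 x 400 um field, i.e.
a pixel pitch of 400/384 um/px and an image area of 0.16 mm**2.
"""

from __future__ import annotations

DEFAULT_IMAGE_SIZE_PX: int = 384
FIELD_OF_VIEW_UM: float = 400.0

#: micrometres per pixel for the standard 384 px / 400 um field
DEFAULT_PIXEL_PITCH_UM: float = FIELD_OF_VIEW_UM / DEFAULT_IMAGE_SIZE_PX


def px_to_mm(length_px: float, pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM) -> float:
    """Convert a length in pixels to millimetres."""
    return length_px * pixel_pitch_um / 1000.0


def image_area_mm2(
    image_shape: tuple[int, int] = (DEFAULT_IMAGE_SIZE_PX, DEFAULT_IMAGE_SIZE_PX),
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> float:
    """Physical area of an image in mm**2 (0.16 for the default geometry)."""
    h, w = image_shape
    return (h * pixel_pitch_um / 1000.0) * (w * pixel_pitch_um / 1000.0)


def cells_per_image(density_cells_per_mm2: float, area_mm2: float = 0.16) -> float:
    """Convert a cell density (cells/mm**2) to an expected per-image count.

    One image covers ``area_mm2`` (0.16 mm**2 by default), so a density of
    6.25 cells/mm**2 corresponds to exactly one cell per image.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    return density_cells_per_mm2 * area_mm2
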