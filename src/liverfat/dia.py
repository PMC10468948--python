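"""Digital image analysis of H&E biopsy sections.

Steatosis appears as unstained (white) fat vacuoles on a stained-tissue
background.  The quantification is deliberately simple and fully automatic:

1. the biopsy outline is found as the connected components brighter than a
   background threshold (fragmented biopsies yield several masks);
2. the area fat fraction DIAFF is the count of pixels at or above a *fixed*
   white threshold inside the biopsy mask, divided by the mask area;
3. the 2-D area fraction is converted to a 3-D volume fraction with a
   geometric factor for spherical inclusions (default 2/3, the
   sphere-in-cube vs circle-in-square packing ratio; 4/3 selectable);
4. the volume fraction becomes a tissue mass fat fraction via the fat and
   water mass densities: ``TMFF = D_F v / (D_F v + D_W (1 − v))``, which
   reduces to multiplication by the density ratio 0.9 at small v.

Intensities are on [0, 1] grayscale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .constants import ModelConstants

__all__ = ["DiaResult", "segment_biopsy", "compute_diaff",
           "area_to_volume_fraction", "volume_to_mass_fraction",
           "analyze_image", "WHITE_THRESHOLD", "BACKGROUND_THRESHOLD",
           "MIN_FRAGMENT_PX"]

#: Fixed white-pixel threshold for steatosis, [0, 1] grayscale.
WHITE_THRESHOLD = 0.85
#: Pixels above this are tissue (or vacuole), below is background slide.
BACKGROUND_THRESHOLD = 0.15
#: Connected components smaller than this are speckle, not biopsy fragments.
MIN_FRAGMENT_PX = 200


@dataclass(frozen=True)
class DiaResult:
    """Area, volume and mass fat fractions for one biopsy image."""

    diaff_area: float
    volume_fraction: float
    tmff_dia: float
    biopsy_pixels: int
    white_pixels: int

    def __post_init__(self) -> None:
        for name in ("diaff_area", "volume_fraction", "tmff_dia"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.white_pixels > self.biopsy_pixels:
            raise ValueError("white_pixels cannot exceed biopsy_pixels")


def segment_biopsy(pixels: np.ndarray,
                   background_threshold: float = BACKGROUND_THRESHOLD,
                   min_fragment_px: int = MIN_FRAGMENT_PX,
                   ) -> list[np.ndarray]:
    """Find biopsy fragment masks as large bright connected components.

    Returns one boolean mask per retained fragment (largest first); their
    union is the biopsy region.  Raises ``ValueError`` when no component
    reaches ``min_fragment_px``.
    """
    img = np.asarray(pixels, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    labels = measure.label(img > background_threshold, connectivity=2)
    masks = []
    for region in measure.regionprops(labels):
        if region.area >= min_fragment_px:
            masks.append(labels == region.label)
    if not masks:
        raise ValueError("no biopsy found: no component above "
                         f"{min_fragment_px} px")
    masks.sort(key=lambda m: int(m.sum()), reverse=True)
    return masks


def compute_diaff(pixels: np.ndarray, masks: list[np.ndarray],
                  white_threshold: float = WHITE_THRESHOLD,
                  constants: ModelConstants | None = None) -> DiaResult:
    """White-pixel area fraction within the union of biopsy masks.

    The threshold is a fixed configuration constant, not adaptive.  The
    area→volume→mass conversions are filled in from ``constants`` (defaults
    if omitted).
    """
    img = np.asarray(pixels, dtype=float)
    if not masks:
        raise ValueError("empty mask list")
    union = np.zeros(img.shape, dtype=bool)
    for m in masks:
        if m.shape != img.shape:
            raise ValueError("mask shape does not match image")
        union |= m
    biopsy_px = int(union.sum())
    if biopsy_px == 0:
        raise ValueError("empty biopsy mask")
    white_px = int(np.count_nonzero(img[union] >= white_threshold))
    diaff = white_px / biopsy_px
    constants = constants or ModelConstants()
    vol = area_to_volume_fraction(diaff, constants.area_to_volume_factor)
    tmff = volume_to_mass_fraction(vol, constants)
    return DiaResult(diaff_area=diaff, volume_fraction=vol, tmff_dia=tmff,
                     biopsy_pixels=biopsy_px, white_pixels=white_px)


def area_to_volume_fraction(area_fraction: float, factor: float) -> float:
    """Geometric area→volume conversion for spherical inclusions.

    The 2/3 factor is the inscribed-shape packing ratio (sphere-in-cube π/6
    over circle-in-square π/4); the literal circle/square-to-sphere/cube
    expression ratio gives 4/3.  Result is clipped to [0, 1].
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must be in [0, 1]")
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return float(np.clip(area_fraction * factor, 0.0, 1.0))


def volume_to_mass_fraction(volume_fraction: float,
                            constants: ModelConstants | None = None) -> float:
    """Two-component volume→mass fat fraction using the mass densities.

    ``D_F v / (D_F v + D_W (1 − v))`` — a proper mass fraction that reduces
    to multiplication by the density ratio (0.9) at small volume fractions.
    """
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError("volume_fraction must be in [0, 1]")
    c = constants or ModelConstants()
    fat = c.D_F * volume_fraction
    water = c.D_W * (1.0 - volume_fraction)
    return fat / (fat + water)


def analyze_image(pixels: np.ndarray,
                  background_threshold: float = BACKGROUND_THRESHOLD,
                  white_threshold: float = WHITE_THRESHOLD,
                  min_fragment_px: int = MIN_FRAGMENT_PX,
                  constants: ModelConstants | None = None) -> DiaResult:
    """Full DIA chain: segment fragments, then quantify steatosis."""
    masks = segment_biopsy(pixels, background_threshold, min_fragment_px)
    return compute_diaff(pixels, masks, white_threshold, constants)
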