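"""Classical red-lesion detector for rendered synthetic fundus images.

This is a deliberately simple, fully specified stand-in for the trained
deep-learning segmenters used by production DR screening systems: a
background-subtraction blob detector on the green channel (the channel with
the strongest red-lesion contrast), followed by a size rule separating
microaneurysms from hemorrhages.  It is designed to recover ground truth on
the schematic renders of :mod:`drquad.simulate`; it makes no claim of
robustness on real fundus photographs.

Pipeline: take the chosen channel, estimate the slowly varying background by
a wide Gaussian, form the darkness contrast ``background - image``, mask the
optic-disc neighbourhood (the disc is bright and lesion-free), threshold,
and measure each connected component (centroid, equivalent-circle diameter,
mean contrast).  Everything is deterministic for a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import FundusFrame
from .lesions import LesionMark, LesionType

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the stand-in detector.

    ``response_threshold`` is the minimum normalized darkness contrast (on a
    [0, 1] intensity scale) for a pixel to join a blob.  ``min_blob_um`` and
    ``max_blob_um`` gate candidate equivalent diameters; candidates at or
    below ``ma_max_diameter_um`` (default 125 um, the conventional clinical
    upper size of a microaneurysm) are classified MA, larger ones HEM.
    ``background_sigma_um`` sets the Gaussian background estimate and must
    comfortably exceed the largest lesion radius.
    """

    min_blob_um: float = 20.0
    ma_max_diameter_um: float = 125.0
    max_blob_um: float = 1500.0
    response_threshold: float = 0.08
    channel: str = "green"
    background_sigma_um: float = 1000.0
    disc_mask_radius_um: float = 1400.0

    def __post_init__(self) -> None:
        if not 0 < self.min_blob_um < self.ma_max_diameter_um < self.max_blob_um:
            raise ValueError(
                "size gates must satisfy 0 < min_blob_um < ma_max_diameter_um < max_blob_um"
            )
        if self.response_threshold <= 0:
            raise ValueError("response_threshold must be positive")
        if self.channel not in _CHANNEL_INDEX:
            raise ValueError(f"channel must be one of {sorted(_CHANNEL_INDEX)}")


@dataclass(frozen=True)
class Blob:
    """One dark-blob candidate (image coordinates, px; contrast in [0, 1])."""

    x_px: float
    y_px: float
    equivalent_diameter_px: float
    contrast: float


def _as_channel(image: np.ndarray, channel: str) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., _CHANNEL_INDEX[channel]]
    elif img.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got shape {img.shape}")
    img = img.astype(np.float64)
    if img.max() > 1.0:  # 8/16-bit integers -> [0, 1]
        img = img / (255.0 if img.max() <= 255 else 65535.0)
    return img


def detect_candidates(
    image: np.ndarray,
    params: DetectionParams,
    um_per_px: float,
    exclusion_mask: np.ndarray | None = None,
) -> list[Blob]:
    """Dark-blob candidates within the size gates, sorted by position.

    ``exclusion_mask`` (optional, boolean, True = ignore) removes regions
    such as the optic disc before thresholding.  A flat or empty image
    yields an empty list.  Raising ``response_threshold`` can only shrink
    the thresholded set, so the candidate list never grows with it.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    chan = _as_channel(image, params.channel)
    if chan.size == 0:
        return []
    sigma_px = params.background_sigma_um / um_per_px
    background = ndimage.gaussian_filter(chan, sigma=sigma_px, mode="nearest")
    contrast = background - chan  # positive where darker than surroundings
    if exclusion_mask is not None:
        contrast = np.where(exclusion_mask, 0.0, contrast)
    binary = contrast > params.response_threshold
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    blobs: list[Blob] = []
    for region in measure.regionprops(labels, intensity_image=contrast):
        d_um = region.equivalent_diameter_area * um_per_px
        if not params.min_blob_um <= d_um <= params.max_blob_um:
            continue
        cy, cx = region.centroid
        blobs.append(
            Blob(
                x_px=float(cx),
                y_px=float(cy),
                equivalent_diameter_px=float(region.equivalent_diameter_area),
                contrast=float(region.intensity_mean),
            )
        )
    blobs.sort(key=lambda b: (b.y_px, b.x_px))
    return blobs


def classify_lesion(
    blob: Blob, params: DetectionParams, um_per_px: float
) -> LesionType | None:
    """Size rule: MA up to ``ma_max_diameter_um``, HEM above it; out-of-gate
    candidates are rejected (``None``)."""
    d_um = blob.equivalent_diameter_px * um_per_px
    if not params.min_blob_um <= d_um <= params.max_blob_um:
        return None
    return LesionType.MA if d_um <= params.ma_max_diameter_um else LesionType.HEM


def disc_mask(frame: FundusFrame, radius_um: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the optic-disc keep-out disc (True = excluded)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r_px = radius_um / frame.um_per_px
    return (xx - frame.disc_x) ** 2 + (yy - frame.disc_y) ** 2 < r_px**2


def detect_lesions(
    image: np.ndarray,
    frame: FundusFrame,
    params: DetectionParams = DetectionParams(),
) -> list[LesionMark]:
    """Detect and type red lesions in one rendered fundus image.

    Composition of :func:`detect_candidates` (with the optic-disc
    neighbourhood masked out) and :func:`classify_lesion`.  The image must
    match the frame's dimensions.
    """
    img = np.asarray(image)
    shape = img.shape[:2]
    if shape != (frame.height_px, frame.width_px):
        raise ValueError(
            f"image shape {shape} does not match frame {frame.height_px}x{frame.width_px}"
        )
    mask = disc_mask(frame, params.disc_mask_radius_um, shape)
    marks: list[LesionMark] = []
    for blob in detect_candidates(img, params, frame.um_per_px, exclusion_mask=mask):
        lesion = classify_lesion(blob, params, frame.um_per_px)
        if lesion is None:
            continue
        marks.append(
            LesionMark(
                lesion_type=lesion,
                x_px=blob.x_px,
                y_px=blob.y_px,
                diameter_um=blob.equivalent_diameter_px * frame.um_per_px,
                mean_intensity=min(1.0, blob.contrast),
            )
        )
    return marks
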