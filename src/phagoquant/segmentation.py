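"""Nucleus detection and perinuclear-zone assignment.

Implements the rule-based segmentation used by high-content phagocytosis
assays: a global fluorescence threshold separates Hoechst-stained nuclei from
background, holes are filled, objects are smoothed by shrinking and growing
(morphological opening, 2 px by default), and candidates are accepted as
nuclei only if their area lies within configured bounds and their elliptical
fit exceeds a gate (0.8 by default).  Accepted nuclei are then expanded by a
fixed radius (50 px by default) into disjoint perinuclear assignment zones
within which particles and puncta are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Parameters of the nucleus-detection ruleset.

    ``smoothing_radius`` (2 px), ``elliptical_fit_threshold`` (0.8) and
    ``zone_radius`` (50 px) are assay-protocol constants; ``area_bounds``
    excludes debris and clumps and must be tuned to the magnification.
    """

    threshold_method: str = "otsu"  # "otsu" or "fixed"
    threshold_value: float | None = None  # used when threshold_method == "fixed"
    smoothing_radius: int = 2
    area_bounds: tuple[float, float] = (50.0, 2000.0)
    elliptical_fit_threshold: float = 0.8
    zone_radius: float = 50.0
    connectivity: int = 8
    exclude_border_objects: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.elliptical_fit_threshold < 1.0):
            raise ValueError("elliptical_fit_threshold must be in (0, 1)")
        if not self.area_bounds[0] < self.area_bounds[1]:
            raise ValueError("area_bounds must satisfy min < max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")


@dataclass
class NucleusObject:
    """A detected nucleus candidate with its acceptance decision."""

    label: int
    mask: np.ndarray  # boolean, full-field shape
    centroid: tuple[float, float]  # (row, col)
    area: int
    elliptical_fit: float
    accepted: bool
    touches_border: bool = False


@dataclass
class CellZone:
    """Perinuclear assignment zone of one accepted nucleus."""

    nucleus_label: int
    mask: np.ndarray
    radius: float


def elliptical_fit(mask: np.ndarray) -> float:
    """Shape score in [0, 1]: Jaccard overlap of a mask with its
    moment-equivalent equal-area ellipse.

    The ellipse shares the mask's centroid and orientation (from second
    central moments); its axes are rescaled so the continuous ellipse area
    equals the pixel count of the mask.  A perfect ellipse scores ~1 (up to
    rasterization); elongated crosses and stars score well below 0.8.

    A single-pixel mask scores 1.0 by convention (the equivalent ellipse
    degenerates to the pixel itself).
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("elliptical_fit is undefined for an empty mask")
    if area == 1:
        return 1.0

    props = regionprops(mask.astype(np.uint8))[0]
    cr, cc = props.centroid
    # semi-axes of the normalized second-central-moment ellipse
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    # degenerate (collinear) masks: clamp so the equal-area ellipse exists
    a = max(a, 0.5)
    b = max(b, 0.5)
    scale = np.sqrt(area / (np.pi * a * b))
    a *= scale
    b *= scale
    theta = props.orientation  # angle of major axis vs row axis (skimage)

    rows, cols = np.nonzero(mask)
    pad = int(np.ceil(a)) + 1
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, mask.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, mask.shape[1])

    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    # major-axis unit vector is (cos theta, sin theta) in (row, col)
    v = dr * np.cos(theta) + dc * np.sin(theta)  # along major
    u = -dr * np.sin(theta) + dc * np.cos(theta)  # along minor
    inside = (v / a) ** 2 + (u / b) ** 2 <= 1.0

    sub = mask[r0:r1, c0:c1]
    inter = np.logical_and(sub, inside).sum()
    union = np.logical_or(sub, inside).sum()
    # ellipse clipped at field border can only shrink the union
    return float(inter) / float(union)


def _threshold(image: np.ndarray, config: SegmentationConfig) -> float | None:
    if config.threshold_method == "fixed":
        return float(config.threshold_value)
    if np.ptp(image) == 0:
        return None
    return float(threshold_otsu(image))


def detect_nuclei(
    nuclear_channel: np.ndarray, config: SegmentationConfig | None = None
) -> list[NucleusObject]:
    """Detect nucleus candidates and flag which ones pass the size and
    elliptical-fit gates.

    Pipeline: global threshold -> connected components -> per-object hole
    filling -> morphological opening (shrink/grow by ``smoothing_radius``,
    keeping the largest fragment if an object splits) -> classification by
    area bounds and elliptical fit.  Border-touching objects are scored and
    flagged; they are excluded only if the config says so.
    """
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(nuclear_channel, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")

    thr = _threshold(image, config)
    if thr is None:
        logger.warning("constant image: no foreground under Otsu; returning no nuclei")
        return []
    binary = image > thr
    if not binary.any():
        logger.warning("threshold left no foreground pixels; returning no nuclei")
        return []

    structure = (
        np.ones((3, 3), dtype=bool)
        if config.connectivity == 8
        else ndi.generate_binary_structure(2, 1)
    )
    labels, n = ndi.label(binary, structure=structure)
    selem = disk(config.smoothing_radius) if config.smoothing_radius > 0 else None

    out: list[NucleusObject] = []
    next_label = 1
    slices = ndi.find_objects(labels)
    for lab, sl in zip(range(1, n + 1), slices, strict=True):
        if sl is None:
            continue
        # pad the crop so opening near the crop edge behaves like the full field
        pad = config.smoothing_radius + 1
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, image.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, image.shape[1])
        crop = labels[r0:r1, c0:c1] == lab
        crop = ndi.binary_fill_holes(crop)
        if selem is not None:
            opened = ndi.binary_erosion(crop, structure=selem)
            if not opened.any():
                continue  # object thinner than the smoothing radius: debris
            frag, nf = ndi.label(opened, structure=structure)
            if nf > 1:
                sizes = ndi.sum_labels(opened, frag, index=np.arange(1, nf + 1))
                opened = frag == (1 + int(np.argmax(sizes)))
            crop = ndi.binary_dilation(opened, structure=selem)

        full = np.zeros(image.shape, dtype=bool)
        full[r0:r1, c0:c1] = crop
        area = int(full.sum())
        rows, cols = np.nonzero(full)
        centroid = (float(rows.mean()), float(cols.mean()))
        touches = bool(
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == image.shape[0] - 1
            or cols.max() == image.shape[1] - 1
        )
        if touches and config.exclude_border_objects:
            continue
        fit = elliptical_fit(full)
        accepted = (
            config.area_bounds[0] <= area <= config.area_bounds[1]
            and fit > config.elliptical_fit_threshold
        )
        out.append(
            NucleusObject(
                label=next_label,
                mask=full,
                centroid=centroid,
                area=area,
                elliptical_fit=fit,
                accepted=accepted,
                touches_border=touches,
            )
        )
        next_label += 1
    return out


def expand_zones(
    nuclei: list[NucleusObject],
    field_shape: tuple[int, int],
    config: SegmentationConfig | None = None,
) -> list[CellZone]:
    """Expand accepted nuclei into disjoint perinuclear zones.

    Every pixel within ``zone_radius`` (Euclidean distance to the nearest
    nucleus mask) is assigned to exactly one nucleus — the nearest; ties go
    to the lower label.  Zones are clipped at field borders and contain
    their nucleus.
    """
    if config is None:
        config = SegmentationConfig()
    accepted = [n for n in nuclei if n.accepted]
    if not accepted:
        return []
    label_map = zone_label_map(accepted, field_shape, config.zone_radius)
    return [
        CellZone(nucleus_label=n.label, mask=label_map == n.label, radius=config.zone_radius)
        for n in accepted
    ]


def zone_label_map(
    nuclei: list[NucleusObject], field_shape: tuple[int, int], radius: float
) -> np.ndarray:
    """Integer map of zone ownership (0 = unassigned background).

    Computed from per-nucleus Euclidean distance transforms; argmin over
    nuclei in ascending label order makes the tie-break (lower label wins)
    explicit.
    """
    order = sorted(nuclei, key=lambda n: n.label)
    dmin = np.full(field_shape, np.inf)
    winner = np.zeros(field_shape, dtype=np.int32)
    for nuc in order:
        d = ndi.distance_transform_edt(~nuc.mask)
        better = d < dmin  # strict comparison: ties stay with the lower label
        dmin[better] = d[better]
        winner[better] = nuc.label
    label_map = np.zeros(field_shape, dtype=np.int32)
    within = dmin <= radius
    label_map[within] = winner[within]
    return label_map
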