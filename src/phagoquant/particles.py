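"""pHrodo particle detection, the >2-fold brightness filter, and the
beads/cell phagocytic index.

Particles are detected only inside the perinuclear zones (the 50-px
expansions of accepted nuclei): a white top-hat removes the smooth
background and cell-body signal, candidates above a noise-scaled contrast
threshold are extracted as connected components and smoothed by shrinking
and growing 2 px, and each object is kept only if its mean intensity
exceeds twice the background estimate — objects not significantly brighter
than background are discarded.  The per-field phagocytic index is the
retained-spot count divided by the nucleus count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import disk, white_tophat

from .segmentation import CellZone

logger = logging.getLogger(__name__)


@dataclass
class ParticleConfig:
    tophat_radius: int = 6  # >= largest expected particle radius
    contrast_sigma: float = 3.0  # threshold = contrast_sigma * sd(background top-hat)
    smoothing_radius: int = 2  # shrink/grow of detected objects
    fold_threshold: float = 2.0  # retained iff mean/background > this (strict)
    background_method: str = "outside_zones"  # or "annulus"
    annulus_width: int = 10
    connectivity: int = 8
    min_area: int = 2  # sub-pixel specks are noise


@dataclass
class ParticleObject:
    label: int
    mask: np.ndarray
    centroid: tuple[float, float]
    area: int
    mean_intensity: float
    background_fold: float
    owner_nucleus: int
    retained: bool


@dataclass
class UptakeRecord:
    """Per-field summary feeding the uptake time course."""

    genotype: str
    condition: str
    timepoint: float
    n_nuclei: int
    n_spots: int

    @property
    def beads_per_cell(self) -> float:
        return self.n_spots / self.n_nuclei


def _zone_union_and_labels(zones: list[CellZone], shape) -> tuple[np.ndarray, np.ndarray]:
    union = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    for z in zones:
        union |= z.mask
        labels[z.mask] = z.nucleus_label
    return union, labels


def estimate_background(
    phrodo_channel: np.ndarray,
    zones: list[CellZone],
    config: ParticleConfig | None = None,
) -> float:
    """Background level for the fold filter: median intensity of pixels
    outside all zones (falls back to the global median when the zones tile
    the whole field).  Strictly positive — floored at the smallest positive
    observed value so folds stay finite."""
    if config is None:
        config = ParticleConfig()
    image = np.asarray(phrodo_channel, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if zones:
        union, _ = _zone_union_and_labels(zones, image.shape)
        outside = image[~union]
    else:
        outside = image.ravel()
    if outside.size == 0:
        logger.warning("all pixels lie inside zones; using global median background")
        outside = image.ravel()
    bg = float(np.median(outside))
    if bg <= 0:
        positive = image[image > 0]
        bg = float(positive.min()) if positive.size else 1.0
    return bg


def detect_particles(
    phrodo_channel: np.ndarray,
    zones: list[CellZone],
    config: ParticleConfig | None = None,
) -> list[ParticleObject]:
    if config is None:
        config = ParticleConfig()
    image = np.asarray(phrodo_channel, dtype=float)
    if not zones:
        logger.warning("no zones supplied; no particles can be reported")
        return []
    union, zone_labels = _zone_union_and_labels(zones, image.shape)

    tophat = white_tophat(image, footprint=disk(config.tophat_radius))
    outside_vals = tophat[~union]
    # the top-hat of pure noise has a positive mean; threshold above it
    if outside_vals.size:
        center = float(outside_vals.mean())
        sigma = float(outside_vals.std())
    else:
        center = sigma = 0.0
    threshold = center + config.contrast_sigma * sigma
    candidates = (tophat > threshold) & union

    structure = (
        np.ones((3, 3), dtype=bool)
        if config.connectivity == 8
        else ndi.generate_binary_structure(2, 1)
    )
    labels, n = ndi.label(candidates, structure=structure)
    background = estimate_background(image, zones, config)
    selem = disk(config.smoothing_radius) if config.smoothing_radius > 0 else None

    out: list[ParticleObject] = []
    next_label = 1
    for lab, sl in zip(range(1, n + 1), ndi.find_objects(labels), strict=True):
        if sl is None:
            continue
        pad = config.smoothing_radius + 1
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, image.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, image.shape[1])
        crop = labels[r0:r1, c0:c1] == lab
        if selem is not None:
            eroded = ndi.binary_erosion(crop, structure=selem)
            if not eroded.any():
                continue  # smaller than the smoothing scale: not a particle
            crop = ndi.binary_dilation(eroded, structure=selem)
        mask = np.zeros(image.shape, dtype=bool)
        mask[r0:r1, c0:c1] = crop
        area = int(mask.sum())
        if area < config.min_area:
            continue
        rows, cols = np.nonzero(mask)
        centroid = (float(rows.mean()), float(cols.mean()))
        # owner = zone holding the centroid; majority vote if the rounded
        # centroid falls on a zone-free pixel (concave overlap)
        owner = int(zone_labels[int(round(centroid[0])), int(round(centroid[1]))])
        if owner == 0:
            in_zone = zone_labels[mask]
            in_zone = in_zone[in_zone > 0]
            if in_zone.size == 0:
                continue  # entirely outside all zones: never reported
            owner = int(np.bincount(in_zone).argmax())
        mean_intensity = float(image[mask].mean())
        fold = mean_intensity / background
        out.append(
            ParticleObject(
                label=next_label,
                mask=mask,
                centroid=centroid,
                area=area,
                mean_intensity=mean_intensity,
                background_fold=fold,
                owner_nucleus=owner,
                retained=fold > config.fold_threshold,
            )
        )
        next_label += 1
    return out


def phagocytic_index(n_nuclei: int, n_retained_spots: int) -> float:
    """beads/cell: total retained spots normalized by total nuclei."""
    if n_nuclei <= 0:
        raise ValueError("phagocytic index undefined for a field with no nuclei")
    return n_retained_spots / n_nuclei


def particles_frame(particles: list[ParticleObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": p.label,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "area": p.area,
                "mean_intensity": p.mean_intensity,
                "background_fold": p.background_fold,
                "owner_nucleus": p.owner_nucleus,
                "retained": p.retained,
            }
            for p in particles
        ],
        columns=[
            "label",
            "centroid_row",
            "centroid_col",
            "area",
            "mean_intensity",
            "background_fold",
            "owner_nucleus",
            "retained",
        ],
    )


def assemble_uptake_curves(records: pd.DataFrame | list[UptakeRecord]) -> pd.DataFrame:
    """Per-(genotype, timepoint) mean and SEM of beads/cell across fields.

    SEM is sd/sqrt(n) with ddof=1; a single replicate yields SEM 0 with
    ``n = 1`` flagged in the output.  Missing timepoints are preserved as
    gaps, never interpolated.
    """
    if isinstance(records, list):
        records = pd.DataFrame(
            [
                {
                    "genotype": r.genotype,
                    "condition": r.condition,
                    "timepoint": r.timepoint,
                    "n_nuclei": r.n_nuclei,
                    "n_spots": r.n_spots,
                    "beads_per_cell": r.beads_per_cell,
                }
                for r in records
            ]
        )
    if records.empty:
        raise ValueError("no uptake records supplied")

    def _sem(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))

    out = (
        records.groupby(["genotype", "timepoint"], sort=True)["beads_per_cell"]
        .agg(mean="mean", sem=_sem, n="size")
        .reset_index()
        .sort_values(["genotype", "timepoint"], kind="stable")
        .reset_index(drop=True)
    )
    return out
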