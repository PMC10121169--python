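"""Puncta counting, tandem-reporter flux classification, and NF-kB nuclear
localization.

Three readouts share the nucleus/zone segmentation:

* ``count_puncta`` — small bright objects (p62/LC3 puncta) per cell, via
  white top-hat + contrast threshold inside each perinuclear zone, filtered
  to a puncta area range.
* ``classify_flux`` — tandem mCherry-GFP reporter puncta are classified as
  autophagosomes (bright in both channels) or autolysosomes (mCherry only,
  the GFP moiety quenched in the acidic lysosome) by greedy nearest-pair
  matching of GFP to mCherry puncta.
* ``nuclear_localization`` — NF-kB translocation, reported both as the
  count of NF-kB-positive pixels colocalized with the nucleus mask and as
  the fraction of NF-kB intensity falling inside the nucleus.  The imaging
  here is single-plane, so "voxels" are pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat

from .segmentation import CellZone, NucleusObject

logger = logging.getLogger(__name__)


@dataclass
class PunctaConfig:
    tophat_radius: int = 4
    contrast_sigma: float = 3.0
    smoothing_radius: int = 1  # shrink/grow; kills isolated noise specks
    # minimum mean top-hat response (a.u.) of a punctum; rejects the faint
    # rim residuals a dim diffuse cell body leaves in the top-hat image
    min_response: float = 20.0
    area_bounds: tuple[int, int] = (2, 80)  # pixels^2
    connectivity: int = 8
    match_radius: float = 3.0  # GFP-to-mCherry pairing distance
    nfkb_threshold_method: str = "otsu"  # or "fixed"
    nfkb_threshold_value: float | None = None


@dataclass
class FluxResult:
    cell_id: int
    n_autophagosome: int
    n_autolysosome: int
    n_unmatched_gfp: int

    @property
    def ratio_al_ap(self) -> float | None:
        if self.n_autophagosome == 0:
            return None
        return self.n_autolysosome / self.n_autophagosome


@dataclass
class NuclearLocResult:
    cell_id: int
    colocalized_pixels: int
    nuclear_signal_fraction: float


def _structure(connectivity: int) -> np.ndarray:
    return (
        np.ones((3, 3), dtype=bool) if connectivity == 8 else ndi.generate_binary_structure(2, 1)
    )


def count_puncta(
    channel: np.ndarray,
    zones: list[CellZone],
    config: PunctaConfig | None = None,
) -> tuple[dict[int, int], pd.DataFrame]:
    """Count small bright puncta per cell.

    Returns ``(counts, table)`` where counts maps every zone's nucleus label
    to its punctum count (zero included) and the table lists one row per
    punctum (owner_cell, centroid, area, mean_intensity).
    """
    if config is None:
        config = PunctaConfig()
    image = np.asarray(channel, dtype=float)
    counts: dict[int, int] = {z.nucleus_label: 0 for z in zones}
    rows: list[dict] = []
    if not zones:
        return counts, pd.DataFrame(
            columns=["owner_cell", "centroid_row", "centroid_col", "area", "mean_intensity"]
        )

    union = np.zeros(image.shape, dtype=bool)
    zone_labels = np.zeros(image.shape, dtype=np.int32)
    for z in zones:
        union |= z.mask
        zone_labels[z.mask] = z.nucleus_label

    tophat = white_tophat(image, footprint=disk(config.tophat_radius))
    outside = tophat[~union]
    # the top-hat of pure noise has a positive mean; threshold above it
    if outside.size:
        threshold = float(outside.mean()) + config.contrast_sigma * float(outside.std())
    else:
        threshold = 0.0
    candidates = (tophat > threshold) & union
    if config.smoothing_radius > 0:
        selem = disk(config.smoothing_radius)
        candidates = ndi.binary_dilation(
            ndi.binary_erosion(candidates, structure=selem), structure=selem
        )

    labels, n = ndi.label(candidates, structure=_structure(config.connectivity))
    for lab, sl in zip(range(1, n + 1), ndi.find_objects(labels), strict=True):
        if sl is None:
            continue
        mask = labels[sl] == lab
        area = int(mask.sum())
        if not (config.area_bounds[0] <= area <= config.area_bounds[1]):
            continue
        if float(tophat[sl][mask].mean()) < config.min_response:
            continue
        rr, cc = np.nonzero(mask)
        cr = float(rr.mean() + sl[0].start)
        ccol = float(cc.mean() + sl[1].start)
        owner = int(zone_labels[int(round(cr)), int(round(ccol))])
        if owner == 0:
            in_zone = zone_labels[sl][mask]
            in_zone = in_zone[in_zone > 0]
            if in_zone.size == 0:
                continue
            owner = int(np.bincount(in_zone).argmax())
        counts[owner] = counts.get(owner, 0) + 1
        rows.append(
            {
                "owner_cell": owner,
                "centroid_row": cr,
                "centroid_col": ccol,
                "area": area,
                "mean_intensity": float(image[sl][mask].mean()),
            }
        )
    table = pd.DataFrame(
        rows, columns=["owner_cell", "centroid_row", "centroid_col", "area", "mean_intensity"]
    )
    return counts, table


def classify_flux(
    gfp_puncta: pd.DataFrame,
    mcherry_puncta: pd.DataFrame,
    match_radius: float = 3.0,
) -> list[FluxResult]:
    """Classify tandem-reporter puncta per cell.

    GFP puncta are greedily matched to mCherry puncta of the same cell in
    order of increasing pair distance, each punctum used at most once and
    only within ``match_radius``.  Matched pairs are autophagosomes;
    unmatched mCherry puncta are autolysosomes; unmatched GFP puncta are
    reported as anomalies (a GFP-only punctum has no place in the reporter's
    chemistry).  Expects the tables emitted by :func:`count_puncta`.
    """
    cells = sorted(
        set(gfp_puncta["owner_cell"].tolist()) | set(mcherry_puncta["owner_cell"].tolist())
    )
    out: list[FluxResult] = []
    for cell in cells:
        g = gfp_puncta[gfp_puncta["owner_cell"] == cell]
        m = mcherry_puncta[mcherry_puncta["owner_cell"] == cell]
        gxy = g[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        mxy = m[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        matched_g: set[int] = set()
        matched_m: set[int] = set()
        if len(gxy) and len(mxy):
            d = cdist(gxy, mxy)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            for gi, mi in order:
                if d[gi, mi] > match_radius:
                    break
                if gi in matched_g or mi in matched_m:
                    continue
                matched_g.add(int(gi))
                matched_m.add(int(mi))
        n_ap = len(matched_m)
        n_al = len(mxy) - n_ap
        n_anom = len(gxy) - len(matched_g)
        out.append(
            FluxResult(
                cell_id=int(cell),
                n_autophagosome=n_ap,
                n_autolysosome=n_al,
                n_unmatched_gfp=n_anom,
            )
        )
    return out


def flux_frame(results: list[FluxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "n_autophagosome": r.n_autophagosome,
                "n_autolysosome": r.n_autolysosome,
                "n_unmatched_gfp": r.n_unmatched_gfp,
                "ratio_al_ap": np.nan if r.ratio_al_ap is None else r.ratio_al_ap,
            }
            for r in results
        ]
    )


def nuclear_localization(
    nfkb_channel: np.ndarray,
    nuclei: list[NucleusObject],
    zones: list[CellZone],
    config: PunctaConfig | None = None,
) -> list[NuclearLocResult]:
    """Quantify NF-kB nuclear translocation per cell.

    ``colocalized_pixels`` counts NF-kB-positive pixels (above an Otsu or
    fixed threshold on the NF-kB channel) inside the nucleus mask — the
    colocalization readout.  ``nuclear_signal_fraction`` is the fraction of
    NF-kB intensity inside the nucleus relative to the whole cell
    (nucleus + cytoplasmic zone) — a continuous alternative.
    """
    if config is None:
        config = PunctaConfig()
    image = np.asarray(nfkb_channel, dtype=float)
    if config.nfkb_threshold_method == "fixed":
        thr = float(config.nfkb_threshold_value)
    elif np.ptp(image) == 0:
        thr = np.inf  # constant channel: nothing is positive
    else:
        thr = float(threshold_otsu(image))
    positive = image > thr

    zone_by_label = {z.nucleus_label: z for z in zones}
    out: list[NuclearLocResult] = []
    for nuc in nuclei:
        if not nuc.accepted:
            continue
        zone = zone_by_label.get(nuc.label)
        if zone is None:
            logger.warning("nucleus %d has no zone; cell skipped", nuc.label)
            continue
        coloc = int(np.logical_and(positive, nuc.mask).sum())
        cell_mask = np.logical_or(zone.mask, nuc.mask)
        total = float(image[cell_mask].sum())
        nuclear = float(image[nuc.mask].sum())
        frac = nuclear / total if total > 0 else 0.0
        out.append(
            NuclearLocResult(
                cell_id=nuc.label,
                colocalized_pixels=coloc,
                nuclear_signal_fraction=min(max(frac, 0.0), 1.0),
            )
        )
    return out


def nuclear_loc_frame(results: list[NuclearLocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "colocalized_pixels": r.colocalized_pixels,
                "nuclear_signal_fraction": r.nuclear_signal_fraction,
            }
            for r in results
        ]
    )
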