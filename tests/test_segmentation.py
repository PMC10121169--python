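"""Nucleus detection, the elliptical-fit shape gate, and zone expansion."""

import dataclasses

import numpy as np
import pytest
import scipy.ndimage as ndi

from phagoquant import synthgen
from phagoquant.segmentation import (
    SegmentationConfig,
    detect_nuclei,
    elliptical_fit,
    expand_zones,
    zone_label_map,
)

from conftest import cross_mask, rasterize_ellipse


def oracle_elliptical_fit(mask: np.ndarray) -> float:
    """Independent brute-force oracle: moments by direct summation, axes by
    eigendecomposition, overlap by per-pixel rasterization."""
    ys, xs = np.nonzero(mask)
    n = len(ys)
    if n == 1:
        return 1.0
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    cov = np.array(
        [[np.mean(dy * dy), np.mean(dy * dx)], [np.mean(dy * dx), np.mean(dx * dx)]]
    )
    evals, evecs = np.linalg.eigh(cov)
    b0 = max(2.0 * np.sqrt(max(evals[0], 0.0)), 0.5)
    a0 = max(2.0 * np.sqrt(max(evals[1], 0.0)), 0.5)
    s = np.sqrt(n / (np.pi * a0 * b0))
    a, b = a0 * s, b0 * s
    vmaj = evecs[:, 1]
    vmin = evecs[:, 0]
    pad = int(np.ceil(a)) + 2
    inter = union = 0
    for y in range(max(ys.min() - pad, 0), min(ys.max() + pad + 1, mask.shape[0])):
        for x in range(max(xs.min() - pad, 0), min(xs.max() + pad + 1, mask.shape[1])):
            p = np.array([y - cy, x - cx])
            inside = (p @ vmaj / a) ** 2 + (p @ vmin / b) ** 2 <= 1.0
            in_mask = mask[y, x]
            if inside and in_mask:
                inter += 1
            if inside or in_mask:
                union += 1
    return inter / union


def shape_fixtures():
    shapes = []
    for a, b, th in [(20, 10, 0.0), (15, 8, 0.6), (12, 12, 0.0), (18, 6, -0.9)]:
        shapes.append(("ellipse", rasterize_ellipse((64, 64), (32, 32), a, b, th)))
    sq = np.zeros((64, 64), dtype=bool)
    sq[20:41, 20:41] = True
    shapes.append(("square", sq))
    shapes.append(("cross", cross_mask()))
    shapes.append(("cross", cross_mask(size=61, arm=4, length=48)))
    notched = rasterize_ellipse((64, 64), (32, 32), 16, 9, 0.3)
    notched[28:37, 40:] = False
    shapes.append(("notched", notched))
    return shapes


class TestEllipticalFit:
    @pytest.mark.parametrize("name,mask", shape_fixtures())
    def test_matches_brute_force_oracle(self, name, mask):
        assert elliptical_fit(mask) == pytest.approx(oracle_elliptical_fit(mask), abs=1e-9)

    def test_solid_ellipse_scores_near_one(self):
        mask = rasterize_ellipse((64, 64), (32, 32), 20, 10, 0.0)
        assert elliptical_fit(mask) >= 0.95

    def test_cross_fails_gate(self):
        assert elliptical_fit(cross_mask()) <= 0.8

    def test_single_pixel_convention(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert elliptical_fit(mask) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            elliptical_fit(np.zeros((5, 5), dtype=bool))

    def test_rotation_invariance(self):
        fits = [
            elliptical_fit(rasterize_ellipse((80, 80), (40, 40), 18, 9, th))
            for th in (0.0, 0.5, 1.0, 1.5)
        ]
        assert max(fits) - min(fits) < 0.03


class TestDetectNuclei:
    def test_recovers_well_separated_ellipses(self):
        image = np.full((200, 200), 50.0)
        centers = [(40, 40), (40, 150), (100, 100), (160, 40), (160, 150)]
        for r, c in centers:
            image[rasterize_ellipse(image.shape, (r, c), 11, 7, 0.4)] = 500.0
        nuclei = detect_nuclei(image)
        assert sum(n.accepted for n in nuclei) == 5

    def test_cross_shape_rejected_by_fit_gate(self):
        image = np.full((100, 100), 10.0)
        image[10:91, 10:91][cross_mask()] = 400.0
        nuclei = detect_nuclei(image, SegmentationConfig(area_bounds=(50, 5000)))
        assert len(nuclei) == 1
        assert not nuclei[0].accepted
        assert nuclei[0].elliptical_fit <= 0.8

    def test_holes_are_filled(self):
        image = np.full((80, 80), 10.0)
        ell = rasterize_ellipse(image.shape, (40, 40), 14, 9, 0.0)
        image[ell] = 300.0
        image[38:43, 38:43] = 10.0  # punch a hole
        nuclei = detect_nuclei(image)
        filled_area = int(ndi.binary_fill_holes(ell).sum())
        # smoothing may trim boundary pixels but the hole must be gone
        assert nuclei[0].area >= filled_area - 40
        hole = np.zeros_like(ell)
        hole[38:43, 38:43] = True
        assert np.logical_and(nuclei[0].mask, hole).sum() == hole.sum()

    def test_constant_image_returns_empty(self, caplog):
        assert detect_nuclei(np.full((50, 50), 7.0)) == []

    def test_idempotent_on_own_masks(self, noise_free_field):
        image, _ = noise_free_field
        nuclei = detect_nuclei(image.channels["nuclear"])
        binary = np.zeros(image.shape)
        for n in nuclei:
            if n.accepted:
                binary[n.mask] = 1.0
        again = detect_nuclei(binary)
        assert len(again) == sum(n.accepted for n in nuclei)
        masks1 = sorted(
            (n.mask for n in nuclei if n.accepted), key=lambda m: tuple(np.argwhere(m)[0])
        )
        masks2 = sorted((n.mask for n in again), key=lambda m: tuple(np.argwhere(m)[0]))
        for m1, m2 in zip(masks1, masks2):
            assert np.array_equal(m1, m2)

    def test_translation_equivariance(self):
        image = np.full((120, 120), 20.0)
        image[rasterize_ellipse(image.shape, (50, 50), 11, 7, 0.8)] = 400.0
        shifted = np.roll(image, (13, -9), axis=(0, 1))
        n1 = detect_nuclei(image)[0]
        n2 = detect_nuclei(shifted)[0]
        assert n2.centroid[0] == pytest.approx(n1.centroid[0] + 13, abs=1e-9)
        assert n2.centroid[1] == pytest.approx(n1.centroid[1] - 9, abs=1e-9)
        assert np.array_equal(np.roll(n1.mask, (13, -9), axis=(0, 1)), n2.mask)

    def test_recall_precision_on_synthetic_field(self, small_config):
        image, truth = synthgen.simulate_field(small_config, "isogenic", 60.0)
        nuclei = [n for n in detect_nuclei(image.channels["nuclear"]) if n.accepted]
        hits = 0
        for _, row in truth.nuclei.iterrows():
            for n in nuclei:
                dr = n.centroid[0] - row["row"]
                dc = n.centroid[1] - row["col"]
                if dr * dr + dc * dc <= row["semi_minor"] ** 2:
                    hits += 1
                    break
        assert hits / len(truth.nuclei) >= 0.95
        assert hits / max(len(nuclei), 1) >= 0.95


class TestExpandZones:
    def _nucleus(self, shape, center, label=1):
        image = np.full(shape, 10.0)
        image[rasterize_ellipse(shape, center, 10, 7, 0.0)] = 300.0
        nuclei = detect_nuclei(image)
        for i, n in enumerate(nuclei):
            n.label = label + i
        return nuclei

    def test_single_nucleus_zone_is_dilation(self):
        nuclei = self._nucleus((300, 300), (150, 150))
        zones = expand_zones(nuclei, (300, 300))
        dist = ndi.distance_transform_edt(~nuclei[0].mask)
        assert np.array_equal(zones[0].mask, dist <= 50)

    def test_two_nuclei_split_on_bisector(self):
        image = np.full((300, 300), 10.0)
        image[rasterize_ellipse(image.shape, (150, 120), 8, 8, 0.0)] = 300.0
        image[rasterize_ellipse(image.shape, (150, 180), 8, 8, 0.0)] = 300.0
        nuclei = detect_nuclei(image)
        zones = expand_zones(nuclei, image.shape)
        z1 = zones[0].mask
        z2 = zones[1].mask
        assert not np.logical_and(z1, z2).any()
        # columns < 150 belong to nucleus 1, > 150 to nucleus 2
        assert not z1[:, 151:].any()
        assert not z2[:, :150].any()

    def test_tie_goes_to_lower_label(self):
        # two identical discs; the equidistant midline must carry label 1
        image = np.full((120, 240), 10.0)
        image[rasterize_ellipse(image.shape, (60, 80), 8, 8, 0.0)] = 300.0
        image[rasterize_ellipse(image.shape, (60, 160), 8, 8, 0.0)] = 300.0
        nuclei = detect_nuclei(image)
        labels = zone_label_map(nuclei, image.shape, 50.0)
        assert labels[60, 120] == nuclei[0].label

    def test_zone_invariants(self, noise_free_field):
        image, _ = noise_free_field
        nuclei = detect_nuclei(image.channels["nuclear"])
        zones = expand_zones(nuclei, image.shape)
        total = np.zeros(image.shape, dtype=int)
        for z in zones:
            total += z.mask.astype(int)
            nucleus = next(n for n in nuclei if n.label == z.nucleus_label)
            assert z.mask[nucleus.mask].all(), "zone must contain its nucleus"
            dist = ndi.distance_transform_edt(~nucleus.mask)
            assert dist[z.mask].max() <= z.radius
        assert total.max() <= 1, "zones must be disjoint"
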