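"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately written as plain per-pixel / per-pair
python scans, independent of the vectorized implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from trophoquant.quantification import StainMask
from trophoquant.segmentation import NucleusRecord, SegmentationConfig, label_nuclei


@pytest.fixture
def stain_cfg() -> SegmentationConfig:
    """Stain-channel binarization used for synthetic fields: a global
    threshold between background (8) and the dimmest population (50)."""
    return SegmentationConfig(method="global", threshold=25.0)


def oracle_nearest_stain(
    nuclei: list[NucleusRecord],
    stain: StainMask,
    fallback_value: float,
) -> list[tuple[float, bool, float, float]]:
    """Exhaustive per-pixel distance scan for nearest-stain assignment.

    For each nucleus, walks every stain-positive pixel and every
    DAPI-positive pixel of other nuclei in raster order, tracking the
    nearest; applies the fallback rule (no stain, or stain farther than the
    nearest other-nucleus pixel; ties keep the stain).
    """
    results = []
    for rec in nuclei:
        cr, cc = rec.centroid
        d_stain = math.inf
        nearest_label = 0
        h, w = stain.labels.shape
        for r in range(h):
            for c in range(w):
                lab = stain.labels[r, c]
                if lab > 0:
                    d = math.sqrt((r - cr) ** 2 + (c - cc) ** 2)
                    if d < d_stain:
                        d_stain = d
                        nearest_label = lab
        d_other = math.inf
        for other in nuclei:
            if other.label == rec.label:
                continue
            for r, c in other.coords:
                d = math.sqrt((r - cr) ** 2 + (c - cc) ** 2)
                if d < d_other:
                    d_other = d
        if math.isinf(d_stain) or d_stain > d_other:
            results.append((fallback_value, True, d_stain, d_other))
        else:
            results.append(
                (stain.component_means[int(nearest_label)], False, d_stain, d_other)
            )
    return results


def random_assignment_scene(rng: np.random.Generator, size: int = 48):
    """A random small field for oracle-equivalence checks: a few nucleus
    disks and scattered stain blobs with random intensities."""
    dapi = np.zeros((size, size), dtype=bool)
    n_nuclei = int(rng.integers(1, 6))
    for _ in range(n_nuclei):
        r0, c0 = rng.integers(4, size - 4, size=2)
        rad = int(rng.integers(2, 5))
        rr, cc = np.ogrid[:size, :size]
        dapi |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    nuclei = label_nuclei(dapi)

    raster = rng.uniform(0, 255, size=(size, size))
    stain_mask = rng.random((size, size)) < rng.uniform(0.0, 0.05)
    stain_records = label_nuclei(stain_mask)
    labels = np.zeros((size, size), dtype=int)
    means = {}
    for rec in stain_records:
        labels[tuple(rec.coords.T)] = rec.label
        means[rec.label] = float(raster[tuple(rec.coords.T)].mean())
    stain = StainMask(
        channel="green", mask=labels > 0, labels=labels,
        component_means=means, threshold=None,
    )
    return nuclei, stain


def oracle_flood_fill(mask: np.ndarray) -> list[tuple[int, set, tuple, int]]:
    """Brute-force 8-connected labeling by BFS flood fill, components
    numbered in raster-scan order of their first pixel."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    out = []
    label = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            label += 1
            queue = [(r0, c0)]
            seen[r0, c0] = True
            pixels = set()
            while queue:
                r, c = queue.pop()
                pixels.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            centroid = (sum(rows) / len(pixels), sum(cols) / len(pixels))
            out.append((label, pixels, centroid, len(pixels)))
    return out
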