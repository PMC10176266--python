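"""Spatial classification, quartile stratification and the syncytial fusion index.

Colony vs. single-cell classification follows the neighbor rule used for
day-6 EVT heterogeneity: a cell with no neighboring cell centroid within a
50 μm radius is a single cell; a cell with at least one neighbor within that
radius belongs to a colony. The boundary is inclusive (a neighbor at exactly
the radius counts), and classification is computed within each field.

Quartile stratification orders cells by a primary marker (e.g. HLA-G) after
excluding cells negative for both the primary and a secondary marker (e.g.
Notch1); the bottom and top groups each contain floor(n/4) cells, so the two
extracted groups are equal-sized by construction.

The fusion index of a membrane-stained field is (N − S)/T, with N the number
of nuclei inside syncytia, S the number of syncytia (regions holding ≥ 2
nuclei) and T the total nuclei counted. Manually counted (N, S, T) tables
are the reference input path; ``syncytium_counts_from_labels`` is the
automated stand-in that assigns nuclei to membrane-bounded regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .quantification import CellMeasurement
from .segmentation import NucleusRecord
from . import stats as tq_stats

__all__ = [
    "SpatialConfig",
    "SyncytiumCounts",
    "classify_colony_single",
    "classify_points",
    "quartile_stratify",
    "fusion_index",
    "syncytium_counts_from_labels",
    "membrane_region_labels",
    "fusion_index_summary",
]


@dataclass(frozen=True)
class SpatialConfig:
    """Neighbor radius for single/colony classification (default 50 μm)."""

    neighbor_radius_um: float = 50.0
    um_per_px: float = 0.62

    def __post_init__(self) -> None:
        if self.neighbor_radius_um <= 0 or self.um_per_px <= 0:
            raise ValueError("radius and pixel size must be positive")

    @property
    def radius_px(self) -> float:
        return self.neighbor_radius_um / self.um_per_px


@dataclass(frozen=True)
class SyncytiumCounts:
    """Counts entering the fusion index: N nuclei in syncytia, S syncytia,
    T total nuclei."""

    N: int
    S: int
    T: int

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 <= self.N <= self.T:
            raise ValueError("need 0 <= N <= T")
        if (self.S == 0) != (self.N == 0):
            raise ValueError("S = 0 exactly when N = 0")
        if self.S > 0 and self.N < 2 * self.S:
            raise ValueError("each syncytium holds >= 2 nuclei, so N >= 2S")


def classify_points(centroids_px: np.ndarray, radius_px: float) -> list[str]:
    """Label each point ``single`` iff no other point lies within
    ``radius_px`` (inclusive), else ``colony``."""
    pts = np.asarray(centroids_px, dtype=float)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return ["single"]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    has_neighbor = (d2 <= radius_px**2).any(axis=1)
    return ["colony" if h else "single" for h in has_neighbor]


def classify_colony_single(
    cells: Sequence[CellMeasurement], config: SpatialConfig
) -> list[str]:
    """Classify cells as single/colony within each field independently and
    write the label onto each measurement."""
    if not cells:
        return []
    labels: dict[int, str] = {}
    by_field: dict[str, list[int]] = {}
    for i, cell in enumerate(cells):
        by_field.setdefault(cell.field_id, []).append(i)
    for idxs in by_field.values():
        pts = np.asarray([cells[i].centroid for i in idxs])
        for i, lab in zip(idxs, classify_points(pts, config.radius_px)):
            labels[i] = lab
    out = [labels[i] for i in range(len(cells))]
    for cell, lab in zip(cells, out):
        cell.spatial_class = lab
    return out


def quartile_stratify(
    cells: Sequence[CellMeasurement],
    primary_channel: str,
    secondary_channel: str,
    *,
    negativity_rule: str = "fallback",
    negative_threshold: float | None = None,
) -> tuple[list[str], list[CellMeasurement], list[CellMeasurement]]:
    """Stratify cells by primary-marker intensity into quartiles.

    Cells negative for BOTH channels are labeled ``excluded`` and dropped
    before ranking. Negativity defaults to the fallback flag (equivalently a
    normalized intensity of exactly 1.0); ``negativity_rule="threshold"``
    instead calls a cell negative when its normalized intensity is at or
    below ``negative_threshold``. The remaining n cells are sorted ascending
    by primary intensity (ties broken by cell identity for determinism); the
    bottom and top extracted groups each hold floor(n/4) cells.

    Returns (per-cell labels, bottom group, top group). Labels are Q1..Q4
    (Q1 = bottom floor(n/4), Q4 = top floor(n/4), the middle split evenly
    into Q2/Q3) or ``excluded``.
    """

    def is_negative(cell: CellMeasurement, ch: str) -> bool:
        if negativity_rule == "fallback":
            return bool(cell.fallback[ch])
        if negativity_rule == "threshold":
            if negative_threshold is None:
                raise ValueError("threshold rule requires negative_threshold")
            return cell.normalized[ch] <= negative_threshold
        raise ValueError(f"unknown negativity_rule {negativity_rule!r}")

    labels = ["excluded"] * len(cells)
    included = [
        i
        for i, cell in enumerate(cells)
        if not (is_negative(cell, primary_channel) and is_negative(cell, secondary_channel))
    ]
    n = len(included)
    if n < 4:
        raise ValueError(f"only {n} cells after double-negative exclusion; quartiles undefined")

    order = sorted(
        included,
        key=lambda i: (cells[i].normalized[primary_channel], cells[i].field_id, cells[i].cell_id),
    )
    q = n // 4
    mid = order[q : n - q]
    half = len(mid) // 2
    for rank, i in enumerate(order):
        if rank < q:
            labels[i] = "Q1"
        elif rank >= n - q:
            labels[i] = "Q4"
        elif rank - q < half:
            labels[i] = "Q2"
        else:
            labels[i] = "Q3"
    for i, lab in zip(range(len(cells)), labels):
        cells[i].quartile_label = lab
    bottom = [cells[i] for i in order[:q]]
    top = [cells[i] for i in order[n - q :]]
    return labels, bottom, top


def fusion_index(counts: SyncytiumCounts) -> float:
    """(N − S)/T: 0 for an unfused field, approaching 1 as all nuclei share
    one syncytium."""
    return (counts.N - counts.S) / counts.T


def membrane_region_labels(
    membrane_channel: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Partition a membrane-stained image into closed regions.

    Pixels above the membrane threshold (Otsu when not given) form the
    boundaries; 4-connected components of the remaining pixels are the
    candidate cell/syncytium regions, labeled 1..R.
    """
    from .segmentation import binarize_channel

    if threshold is None:
        boundary, _ = binarize_channel(membrane_channel, "otsu")
    else:
        boundary, _ = binarize_channel(membrane_channel, "global", threshold)
    labels, _ = ndi.label(~boundary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return labels


def syncytium_counts_from_labels(
    nuclei: Sequence[NucleusRecord], region_labels: np.ndarray
) -> SyncytiumCounts:
    """Assign each nucleus to the region containing its centroid and count.

    A centroid falling on a boundary/background pixel is assigned to the
    nearest region. Regions holding ≥ 2 nuclei are syncytia.
    """
    if not nuclei:
        raise ValueError("no nuclei to count")
    region_labels = np.asarray(region_labels)
    fg = np.argwhere(region_labels > 0)
    assignments: list[int] = []
    for rec in nuclei:
        r = int(round(rec.centroid[0]))
        c = int(round(rec.centroid[1]))
        r = min(max(r, 0), region_labels.shape[0] - 1)
        c = min(max(c, 0), region_labels.shape[1] - 1)
        lab = int(region_labels[r, c])
        if lab == 0:  # on the membrane line: take the nearest region pixel
            d2 = ((fg - (r, c)) ** 2).sum(axis=1)
            lab = int(region_labels[tuple(fg[int(d2.argmin())])])
        assignments.append(lab)
    counts = pd.Series(assignments).value_counts()
    syncytia = counts[counts >= 2]
    return SyncytiumCounts(N=int(syncytia.sum()), S=int(len(syncytia)), T=len(nuclei))


def fusion_index_summary(
    groups: Mapping[str, Sequence[SyncytiumCounts]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition fusion-index mean ± SD plus pairwise t-tests.

    Returns (summary, pairwise) DataFrames; SD follows the fusion-index
    convention (sample SD across measurements), and pairwise comparisons use
    the variance-gated two-tailed t-test.
    """
    rows = []
    fi: dict[str, np.ndarray] = {}
    for cond, counts in groups.items():
        vals = np.asarray([fusion_index(c) for c in counts], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 measurements for SD")
        fi[cond] = vals
        rows.append(
            {
                "condition": cond,
                "n": len(vals),
                "mean_fusion_index": float(vals.mean()),
                "sd_fusion_index": float(vals.std(ddof=1)),
            }
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    conds = list(groups)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            res = tq_stats.variance_gated_t_test(fi[conds[i]], fi[conds[j]])
            pair_rows.append(
                {
                    "condition_a": conds[i],
                    "condition_b": conds[j],
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significance": tq_stats.significance_marker(res.p_value),
                }
            )
    return summary, pd.DataFrame(pair_rows)
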