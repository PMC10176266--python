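"""Per-cell marker-intensity assignment with isotype fallback and normalization.

For each detected nucleus the pipeline assigns a raw marker intensity per
stain channel in one of two modes:

``nearest-stain``
    The stain channel is binarized and cleaned with the same operator family
    as DAPI; the cell receives the mean ORIGINAL intensity of the connected
    stain component containing the stain pixel nearest its nucleus centroid.
    If the nearest stain pixel is farther than the nearest DAPI pixel
    belonging to a DIFFERENT nucleus — i.e. the signal more plausibly belongs
    to a neighbor — or if no stain pixels exist, the cell instead receives
    the isotype-control reference value (fallback). Ties resolve to no
    fallback. A ``fallback_rule`` switch selects the literal "any blue pixel"
    reading, under which a cell's own nucleus (distance ≈ 0) competes too;
    that reading is degenerate and kept only for sensitivity analysis.

``nuclear``
    The cell receives the mean of the channel's ORIGINAL values over its own
    nucleus pixels (used for nuclear factors such as HIF1α/HIF2α).

Raw values are normalized by the average isotype-control intensity for the
channel (pooled across 1–3 isotype fields), so a fallback cell normalizes to
exactly 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .segmentation import (
    Field,
    NucleusRecord,
    SegmentationConfig,
    binarize_channel,
    clean_mask,
    label_nuclei,
    segment_nuclei,
)

__all__ = [
    "StainMask",
    "StainAssignment",
    "IsotypeReference",
    "CellMeasurement",
    "build_stain_mask",
    "assign_nearest_stain",
    "nuclear_intensity",
    "isotype_reference",
    "quantify_isotype_field",
    "quantify_field",
]


@dataclass
class StainMask:
    """A binarized stain channel with labeled components and their mean raw
    intensities (means are over the original, pre-binarization values)."""

    channel: str
    mask: np.ndarray
    labels: np.ndarray  # 2-D int component labels, 0 = background
    component_means: dict[int, float]
    threshold: float | None


@dataclass(frozen=True)
class StainAssignment:
    """Outcome of nearest-stain assignment for one nucleus."""

    raw: float
    fallback: bool
    d_stain: float  # px, inf if no stain pixels
    d_other_nucleus: float  # px, inf if the field has a single nucleus


@dataclass(frozen=True)
class IsotypeReference:
    """Pooled isotype-control mean for one channel, with provenance."""

    value: float
    n: int
    per_field_means: tuple[float, ...]
    per_field_n: tuple[int, ...]


@dataclass
class CellMeasurement:
    """Per-cell marker values for every quantified channel."""

    field_id: str
    group_id: str
    cell_id: int
    centroid: tuple[float, float]
    raw: dict[str, float]
    fallback: dict[str, bool]
    normalized: dict[str, float]
    mode: dict[str, str]
    spatial_class: str = "unset"
    quartile_label: str = "unset"


def build_stain_mask(
    field: Field, channel: str, config: SegmentationConfig | None = None
) -> StainMask:
    """Binarize + clean a stain channel and attach component mean intensities."""
    if channel not in field.channels:
        raise ValueError(f"field {field.field_id!r} has no channel {channel!r}")
    config = config or SegmentationConfig()
    raster = field.channels[channel]
    mask, thr = binarize_channel(raster, config.method, config.threshold)
    mask = clean_mask(
        mask,
        min_area_px=config.min_area_px,
        fill_holes=config.fill_holes,
        split_touching=False,
    )
    records = label_nuclei(mask)
    labels = np.zeros(mask.shape, dtype=int)
    means: dict[int, float] = {}
    for rec in records:
        labels[tuple(rec.coords.T)] = rec.label
        means[rec.label] = float(raster[tuple(rec.coords.T)].mean())
    return StainMask(
        channel=channel, mask=labels > 0, labels=labels, component_means=means, threshold=thr
    )


def assign_nearest_stain(
    nuclei: Sequence[NucleusRecord],
    stain: StainMask,
    fallback_value: float,
    *,
    fallback_rule: str = "other_nucleus",
) -> list[StainAssignment]:
    """Assign each nucleus the mean intensity of its nearest stain component,
    falling back to ``fallback_value`` when the stain is not plausibly its own.

    ``d_stain`` is the Euclidean pixel distance from the nucleus centroid to
    the nearest stain-positive pixel; ``d_other_nucleus`` the distance to the
    nearest DAPI-positive pixel of a different nucleus. Fallback triggers
    when no stain pixels exist or ``d_stain > d_other_nucleus`` (strict:
    ties keep the stain).
    """
    if fallback_value < 0:
        raise ValueError("fallback_value must be nonnegative")
    if fallback_rule not in ("other_nucleus", "any_blue"):
        raise ValueError(f"unknown fallback_rule {fallback_rule!r}")
    if not nuclei:
        return []

    # stain pixels in raster-scan order; nearest-pixel ties resolve to the
    # earliest pixel in that order
    stain_coords = np.argwhere(stain.labels > 0)
    has_stain = len(stain_coords) > 0
    if has_stain:
        stain_pixel_labels = stain.labels[tuple(stain_coords.T)]

    all_coords = np.concatenate([rec.coords for rec in nuclei])
    all_labels = np.concatenate(
        [np.full(rec.area_px, rec.label) for rec in nuclei]
    )

    out: list[StainAssignment] = []
    for rec in nuclei:
        centroid = np.asarray(rec.centroid)
        if fallback_rule == "other_nucleus":
            other = all_labels != rec.label
            if other.any():
                diffs = all_coords[other] - centroid
                d_other = float(np.sqrt((diffs**2).sum(axis=1).min()))
            else:
                d_other = math.inf
        else:  # any_blue: a cell's own nucleus pixels compete as well
            diffs = all_coords - centroid
            d_other = float(np.sqrt((diffs**2).sum(axis=1).min()))

        if not has_stain:
            out.append(StainAssignment(fallback_value, True, math.inf, d_other))
            continue
        sdiffs = stain_coords - centroid
        sdist = np.sqrt((sdiffs**2).sum(axis=1))
        idx = int(sdist.argmin())
        d_stain = float(sdist[idx])
        if d_stain > d_other:
            out.append(StainAssignment(fallback_value, True, d_stain, d_other))
        else:
            comp = int(stain_pixel_labels[idx])
            out.append(
                StainAssignment(stain.component_means[comp], False, d_stain, d_other)
            )
    return out


def nuclear_intensity(
    nuclei: Sequence[NucleusRecord],
    field: Field,
    channel: str,
    fallback_value: float,
) -> list[StainAssignment]:
    """Mean channel intensity over each nucleus's own pixels (nuclear mode).

    Distance-based fallback does not apply — the nucleus is its own region —
    so the flag is set only for an (invariant-impossible) empty pixel set.
    """
    if channel not in field.channels:
        raise ValueError(f"field {field.field_id!r} has no channel {channel!r}")
    raster = field.channels[channel]
    out = []
    for rec in nuclei:
        if rec.area_px == 0:
            out.append(StainAssignment(fallback_value, True, math.nan, math.nan))
        else:
            val = float(raster[tuple(rec.coords.T)].mean())
            out.append(StainAssignment(val, False, 0.0, math.nan))
    return out


def isotype_reference(
    per_field_values: Sequence[Sequence[float]], *, pooling: str = "pooled"
) -> IsotypeReference:
    """Average isotype-control expression intensity for one channel.

    ``pooled`` (default) averages per-cell values pooled across the isotype
    fields (weighted by cell count); ``per_field`` averages the per-field
    means instead.
    """
    per_field_values = [np.asarray(v, dtype=float) for v in per_field_values]
    ns = [len(v) for v in per_field_values]
    if sum(ns) == 0:
        raise ValueError("no isotype cells: normalization undefined")
    means = tuple(float(v.mean()) if len(v) else math.nan for v in per_field_values)
    if pooling == "pooled":
        value = float(np.concatenate(per_field_values).mean())
    elif pooling == "per_field":
        value = float(np.nanmean(means))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return IsotypeReference(value=value, n=sum(ns), per_field_means=means, per_field_n=tuple(ns))


def _resolve_modes(
    channels: Sequence[str], mode: str | Mapping[str, str]
) -> dict[str, str]:
    if isinstance(mode, str):
        modes = {ch: mode for ch in channels}
    else:
        modes = {ch: mode.get(ch, "nearest-stain") for ch in channels}
    for ch, m in modes.items():
        if m not in ("nearest-stain", "nuclear"):
            raise ValueError(f"unknown mode {m!r} for channel {ch}")
    return modes


def quantify_isotype_field(
    field: Field,
    channels: Sequence[str],
    mode: str | Mapping[str, str] = "nearest-stain",
    config: SegmentationConfig | None = None,
    *,
    stain_config: SegmentationConfig | None = None,
) -> dict[str, list[float]]:
    """Per-cell raw intensities of an isotype-control field, per channel.

    Isotype fields are processed with the same mode as the experimental
    fields. In nearest-stain mode no reference exists yet, so a cell that
    falls back receives the field's mean channel intensity — the nonspecific
    background estimate the isotype image exists to measure.
    """
    config = config or SegmentationConfig()
    stain_config = stain_config or config
    nuclei, _, _ = segment_nuclei(field, config)
    modes = _resolve_modes(channels, mode)
    out: dict[str, list[float]] = {}
    for ch in channels:
        background = float(field.channels[ch].mean())
        if modes[ch] == "nuclear":
            assigns = nuclear_intensity(nuclei, field, ch, background)
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant isotype channel is expected
                stain = build_stain_mask(field, ch, stain_config)
            assigns = assign_nearest_stain(nuclei, stain, background)
        out[ch] = [a.raw for a in assigns]
    return out


def quantify_field(
    field: Field,
    references: Mapping[str, IsotypeReference | float],
    mode: str | Mapping[str, str] = "nearest-stain",
    config: SegmentationConfig | None = None,
    *,
    channels: Sequence[str] | None = None,
    fallback_rule: str = "other_nucleus",
    stain_config: SegmentationConfig | None = None,
) -> tuple[list[CellMeasurement], dict]:
    """Segment a field and produce one CellMeasurement per detected nucleus.

    ``references`` maps each quantified channel to its isotype reference
    (the fallback value and the normalization denominator). ``stain_config``
    overrides the binarization used for stain channels (default: the DAPI
    config); a fixed global threshold is preferable when dim and bright
    marker populations coexist, where Otsu can swallow the dim one into
    background. Returns the measurements plus a details dict (thresholds,
    fallback rates) for the run manifest.
    """
    config = config or SegmentationConfig()
    stain_config = stain_config or config
    if channels is None:
        channels = sorted(references)
    ref_values: dict[str, float] = {}
    for ch in channels:
        if ch not in references:
            raise ValueError(f"no isotype reference for channel {ch!r}")
        ref = references[ch]
        val = ref.value if isinstance(ref, IsotypeReference) else float(ref)
        if val <= 0:
            raise ValueError(f"isotype reference for {ch!r} must be positive, got {val}")
        ref_values[ch] = val

    modes = _resolve_modes(channels, mode)
    nuclei, _, dapi_thr = segment_nuclei(field, config)
    details: dict = {
        "field_id": field.field_id,
        "dapi_threshold": dapi_thr,
        "n_cells": len(nuclei),
        "stain_thresholds": {},
        "fallback_rate": {},
    }

    per_channel: dict[str, list[StainAssignment]] = {}
    for ch in channels:
        if modes[ch] == "nuclear":
            assigns = nuclear_intensity(nuclei, field, ch, ref_values[ch])
            details["stain_thresholds"][ch] = None
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stain = build_stain_mask(field, ch, stain_config)
            assigns = assign_nearest_stain(
                nuclei, stain, ref_values[ch], fallback_rule=fallback_rule
            )
            details["stain_thresholds"][ch] = stain.threshold
        per_channel[ch] = assigns
        if nuclei:
            details["fallback_rate"][ch] = sum(a.fallback for a in assigns) / len(nuclei)

    measurements = []
    for i, rec in enumerate(nuclei):
        raw = {ch: per_channel[ch][i].raw for ch in channels}
        fb = {ch: per_channel[ch][i].fallback for ch in channels}
        norm = {ch: raw[ch] / ref_values[ch] for ch in channels}
        measurements.append(
            CellMeasurement(
                field_id=field.field_id,
                group_id=field.group_id,
                cell_id=rec.label,
                centroid=rec.centroid,
                raw=raw,
                fallback=fb,
                normalized=norm,
                mode=dict(modes),
            )
        )
    return measurements, details
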