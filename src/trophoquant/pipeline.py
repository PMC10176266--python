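"""End-to-end orchestration: fields → per-cell table → comparisons → stats.

A run is described by a :class:`RunConfig`; ``run_quantification`` executes
segmentation, isotype-reference estimation and per-field quantification, and
returns a tidy per-cell table plus a JSON-serializable manifest (software
version, config hash, per-field thresholds, isotype references, fallback
rates) sufficient to re-execute the run exactly. Fallback frequency is
logged per field because a silently high fallback rate is the pipeline's
main failure mode.

``run_comparison`` produces per-contrast group sizes, means, medians,
Mann-Whitney p-values and significance markers, mirroring the violin-plot
groupings of the differentiation experiments. ``make_fixtures`` writes the
canonical synthetic fixture suite (counting fields, fallback fields,
two-population fields, membrane fields at fusion indices 0/0.4/0.9, Ct
tables) with ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .quantification import (
    CellMeasurement,
    isotype_reference,
    quantify_field,
    quantify_isotype_field,
)
from .segmentation import Field, SegmentationConfig
from .spatial import SpatialConfig, classify_points
from .stats import mann_whitney_large_sample, significance_marker

__all__ = [
    "RunConfig",
    "run_quantification",
    "run_comparison",
    "classify_dataframe",
    "measurements_to_dataframe",
    "dataframe_to_measurements",
    "make_fixtures",
    "plot_comparison",
]


@dataclass
class RunConfig:
    """Configuration of a quantification run.

    ``channels`` are the stain channels to quantify; ``mode`` is a single
    mode or per-channel mapping (``nearest-stain`` for membrane/surface
    markers, ``nuclear`` for nuclear factors). Experimental groups must be
    backed by at least one isotype field per quantified channel.
    """

    channels: tuple[str, ...] = ("green", "red")
    mode: str | Mapping[str, str] = "nearest-stain"
    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    # stain channels binarize at a fixed global threshold by default: with a
    # dim and a bright marker population over a dominant dark background,
    # Otsu merges the dim population into background. 25 sits between the
    # synthetic background (8) and the dimmest population (50).
    stain_segmentation: SegmentationConfig = dc_field(
        default_factory=lambda: SegmentationConfig(method="global", threshold=25.0)
    )
    fallback_rule: str = "other_nucleus"
    isotype_pooling: str = "pooled"
    neighbor_radius_um: float = 50.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mode"] = dict(self.mode) if not isinstance(self.mode, str) else self.mode
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_fields(fields: Sequence[Field | str | Path]) -> list[Field]:
    from .synthgen import load_field_tiff

    out = []
    for f in fields:
        out.append(f if isinstance(f, Field) else load_field_tiff(f))
    return out


def measurements_to_dataframe(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        row: dict = {
            "field_id": m.field_id,
            "group_id": m.group_id,
            "cell_id": m.cell_id,
            "centroid_row": m.centroid[0],
            "centroid_col": m.centroid[1],
            "spatial_class": m.spatial_class,
            "quartile_label": m.quartile_label,
        }
        for ch in sorted(m.raw):
            row[f"raw_{ch}"] = m.raw[ch]
            row[f"normalized_{ch}"] = m.normalized[ch]
            row[f"fallback_{ch}"] = m.fallback[ch]
            row[f"mode_{ch}"] = m.mode[ch]
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_measurements(df: pd.DataFrame) -> list[CellMeasurement]:
    """Inverse of :func:`measurements_to_dataframe` (e.g. after reading a
    per-cell CSV back for stratification)."""
    channels = sorted(c[len("raw_") :] for c in df.columns if c.startswith("raw_"))
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            CellMeasurement(
                field_id=d["field_id"],
                group_id=d["group_id"],
                cell_id=int(d["cell_id"]),
                centroid=(float(d["centroid_row"]), float(d["centroid_col"])),
                raw={ch: float(d[f"raw_{ch}"]) for ch in channels},
                fallback={ch: bool(d[f"fallback_{ch}"]) for ch in channels},
                normalized={ch: float(d[f"normalized_{ch}"]) for ch in channels},
                mode={ch: d[f"mode_{ch}"] for ch in channels},
                spatial_class=d.get("spatial_class", "unset"),
                quartile_label=d.get("quartile_label", "unset"),
            )
        )
    return out


def run_quantification(
    config: RunConfig,
    experimental_fields: Sequence[Field | str | Path],
    isotype_fields: Sequence[Field | str | Path],
    *,
    output_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Quantify all experimental fields against pooled isotype references.

    Mirrors the layout of 1–3 isotype-control images backing a set of
    experimental images (e.g. seven per biological replicate), but accepts
    any grouping. Returns (per-cell DataFrame, manifest); with
    ``output_dir`` set, writes ``cells.csv`` and ``manifest.json``.
    """
    experimental = _load_fields(experimental_fields)
    isotype = _load_fields(isotype_fields)
    if not isotype:
        raise ValueError("at least one isotype-control field is required")
    if not experimental:
        raise ValueError("no experimental fields")

    per_field_values: dict[str, list[list[float]]] = {ch: [] for ch in config.channels}
    for fld in isotype:
        vals = quantify_isotype_field(
            fld,
            config.channels,
            config.mode,
            config.segmentation,
            stain_config=config.stain_segmentation,
        )
        for ch in config.channels:
            per_field_values[ch].append(vals[ch])
    references = {
        ch: isotype_reference(per_field_values[ch], pooling=config.isotype_pooling)
        for ch in config.channels
    }

    all_measurements: list[CellMeasurement] = []
    field_details = []
    for fld in experimental:
        measurements, details = quantify_field(
            fld,
            references,
            config.mode,
            config.segmentation,
            channels=config.channels,
            fallback_rule=config.fallback_rule,
            stain_config=config.stain_segmentation,
        )
        all_measurements.extend(measurements)
        field_details.append(details)

    df = measurements_to_dataframe(all_measurements)
    manifest = {
        "software": {"name": "trophoquant", "version": __version__},
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "isotype_references": {
            ch: {
                "value": ref.value,
                "n": ref.n,
                "per_field_means": list(ref.per_field_means),
                "per_field_n": list(ref.per_field_n),
            }
            for ch, ref in references.items()
        },
        "fields": field_details,
        "n_cells_total": len(df),
    }
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(output_dir / "cells.csv", index=False)
        with open(output_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return df, manifest


def classify_dataframe(
    df: pd.DataFrame, neighbor_radius_um: float = 50.0, um_per_px: float = 0.62
) -> pd.DataFrame:
    """Add single/colony spatial classes to a per-cell table, per field."""
    cfg = SpatialConfig(neighbor_radius_um=neighbor_radius_um, um_per_px=um_per_px)
    df = df.copy()
    for _, idx in df.groupby("field_id", sort=False).groups.items():
        pts = df.loc[idx, ["centroid_row", "centroid_col"]].to_numpy()
        df.loc[idx, "spatial_class"] = classify_points(pts, cfg.radius_px)
    return df


def run_comparison(
    cells: pd.DataFrame,
    contrasts: Sequence[Mapping[str, str]],
    *,
    group_column: str = "group_id",
) -> pd.DataFrame:
    """Pairwise group comparisons of normalized intensities.

    Each contrast is a mapping with ``group_a``, ``group_b`` and ``channel``
    keys; values are taken from the ``normalized_<channel>`` column. Output
    rows carry group n, mean, median, the large-sample Mann-Whitney p and
    the ns/*/**/*** significance marker.
    """
    known = set(cells[group_column].unique())
    rows = []
    for contrast in contrasts:
        ga, gb, ch = contrast["group_a"], contrast["group_b"], contrast["channel"]
        for g in (ga, gb):
            if g not in known:
                raise ValueError(f"contrast references unknown group {g!r}")
        col = f"normalized_{ch}"
        if col not in cells.columns:
            raise ValueError(f"no column {col!r} in per-cell table")
        a = cells.loc[cells[group_column] == ga, col].to_numpy()
        b = cells.loc[cells[group_column] == gb, col].to_numpy()
        res = mann_whitney_large_sample(a, b)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "channel": ch,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "U": res.statistic,
                "p_value": res.p_value,
                "significance": significance_marker(res.p_value),
            }
        )
    return pd.DataFrame(rows)


def plot_comparison(
    cells: pd.DataFrame,
    channel: str,
    *,
    group_column: str = "group_id",
    path: str | Path | None = None,
):
    """Diagnostic violin plot of normalized intensity per group, with the
    mean as a white circle and the median as a black bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = f"normalized_{channel}"
    groups = list(cells[group_column].unique())
    data = [cells.loc[cells[group_column] == g, col].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.5 * len(groups) + 2, 4))
    ax.violinplot(data, showextrema=False)
    for i, vals in enumerate(data, start=1):
        ax.hlines(np.median(vals), i - 0.15, i + 0.15, colors="black", lw=3)
        ax.plot(i, np.mean(vals), "o", color="white", mec="black", ms=8, zorder=3)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(f"normalized {channel} intensity (fold over isotype)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical synthetic fixture suite with ground truth.

    Produces counting fields (1/5/50 nuclei), a stain-offset field that
    deliberately triggers the isotype fallback, a two-population
    experimental + isotype field pair, membrane fields at fusion indices
    {0, 0.4, 0.9}, and a Ct table with known log2 fold changes; all
    regenerated bit-identically from the seed.
    """
    from . import synthgen as sg

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fields": []}

    def emit(name: str, field: Field, gt: sg.GroundTruth, spec: sg.FieldSpec) -> None:
        sg.save_field_tiff(field, out_dir / f"{name}.tiff")
        sg.save_field_png(field, out_dir / f"{name}.png")
        sg.save_ground_truth_csv(gt, out_dir / f"{name}_truth.csv")
        sg.save_field_spec(spec, out_dir / f"{name}_spec.yaml")
        manifest["fields"].append({"name": name, "n_cells": gt.n_cells})

    for k in (1, 5, 50):
        spec = sg.FieldSpec(
            n_colonies=0,
            n_single_cells=k,
            colony_radius_um=12.0,
            noise_sd=0.0,
            seed=seed + k,
        )
        field, gt = sg.generate_field(spec, field_id=f"count{k}")
        emit(f"count{k}", field, gt, spec)

    offset_spec = sg.FieldSpec(
        n_colonies=2, cells_per_colony=(4, 6), n_single_cells=2,
        stain_offset_px=40.0, seed=seed + 101,
    )
    field, gt = sg.generate_field(offset_spec, field_id="offset")
    emit("offset", field, gt, offset_spec)

    twopop_spec = sg.FieldSpec(n_colonies=2, cells_per_colony=(5, 8), n_single_cells=5, seed=seed + 202)
    field, gt = sg.generate_field(twopop_spec, field_id="twopop")
    emit("twopop", field, gt, twopop_spec)
    iso_field, iso_gt = sg.generate_isotype_field(twopop_spec, field_id="twopop_isotype")
    emit("twopop_isotype", iso_field, iso_gt, twopop_spec)

    for target in (0.0, 0.4, 0.9):
        spec = sg.FieldSpec(n_colonies=0, n_single_cells=20, seed=seed + int(target * 10))
        field, gt = sg.generate_membrane_field(spec, target, field_id=f"membrane{target}")
        emit(f"membrane_fi{target}", field, gt, spec)
        manifest["fields"][-1]["true_fusion_index"] = gt.true_fusion_index()

    ct = sg.generate_ct_table(
        genes=["CYP19A1", "ERVW1", "TP63"],
        conditions=["day0", "day4", "day6"],
        replicates=3,
        true_log2fc={
            "CYP19A1": {"day4": 2.0, "day6": 3.0},
            "ERVW1": {"day4": 1.0, "day6": 2.5},
            "TP63": {"day4": -1.5, "day6": -3.0},
        },
        ct_noise_sd=0.0,
        seed=seed + 303,
    )
    ct.to_csv(out_dir / "ct_table.csv", index=False)
    manifest["ct_table"] = "ct_table.csv"

    with open(out_dir / "fixtures_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
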