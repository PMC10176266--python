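"""Ground-truthed synthetic fluorescence fields and qPCR tables.

Every downstream stage of the pipeline (nucleus detection, per-cell marker
assignment, spatial classification, fusion index, ΔΔCT) is exercised against
fields generated here, for which the complete ground truth — cell positions,
per-cell marker intensities, population labels, syncytium membership — is
known by construction.

Coordinate convention, used throughout the package: arrays are indexed
``(row, col)``, 0-based, with pixel centers at integer coordinates. Distances
in pixels are Euclidean on these coordinates; physical distances are obtained
via ``um_per_px``.

Intensities are stored as floating point on a [0, 255] scale mirroring 8-bit
RGB exports. Quantization to integers is optional and off by default so that
intensity-recovery tests can assert exact equality on noise-free fields.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import Field

MAX_INTENSITY = 255.0

__all__ = [
    "MAX_INTENSITY",
    "Population",
    "FieldSpec",
    "GroundTruth",
    "PackingError",
    "generate_field",
    "generate_isotype_field",
    "generate_membrane_field",
    "generate_ct_table",
    "save_field_tiff",
    "load_field_tiff",
    "save_field_png",
    "save_ground_truth_csv",
    "load_ground_truth_csv",
    "save_field_spec",
    "load_field_spec",
]


class PackingError(RuntimeError):
    """Raised when a field spec cannot be realized (infeasible nucleus packing)."""


@dataclass(frozen=True)
class Population:
    """A cell population with per-channel intensity distributions.

    ``channel_means`` maps a stain channel name (``"green"``/``"red"``) to a
    ``(mean, sd)`` pair on the [0, 255] intensity scale. Draws are truncated
    to [0, MAX_INTENSITY]. ``weight`` is the relative abundance.
    """

    name: str
    weight: float
    channel_means: Mapping[str, tuple[float, float]]


#: Default two-population model: anti-correlated HLA-G(green)/Notch1(red)
#: intensities — an HLA-G-high/Notch1-low population and its mirror image —
#: emulating the heterogeneous mixture of mature single-cell EVTs and
#: column-stage colony EVTs.
DEFAULT_POPULATIONS: tuple[Population, ...] = (
    Population("HLAG-high_Notch1-low", 0.5, {"green": (200.0, 0.0), "red": (50.0, 0.0)}),
    Population("HLAG-low_Notch1-high", 0.5, {"green": (50.0, 0.0), "red": (200.0, 0.0)}),
)


@dataclass
class FieldSpec:
    """Parameters of one synthetic imaging field.

    Attributes
    ----------
    image_height_px, image_width_px:
        Raster size in pixels.
    um_per_px:
        Physical pixel size (μm/pixel). Default 0.62 μm/px, a declared
        assumption standing in for unreported confocal magnification.
    n_colonies, cells_per_colony:
        Number of colonies and the inclusive range of cells per colony.
        Colony members are placed within ``colony_radius_um / 2`` of their
        colony center, which guarantees each has at least one neighbor
        within ``colony_radius_um``.
    n_single_cells:
        Isolated cells with no other nucleus centroid within
        ``colony_radius_um``.
    colony_radius_um:
        The neighbor radius defining single vs. colony ground truth (μm).
    colony_spacing_um:
        Minimum distance between colony centers, and from a colony center to
        any single cell (μm).
    nucleus_radius_px:
        Inclusive range of nucleus disk radii in pixels.
    populations:
        Cell populations with per-channel intensity models.
    stain_radius_px:
        Radius of the stain blob rendered for each cell.
    stain_offset_px:
        Distance of the stain blob center from the nucleus centroid
        (direction drawn uniformly). Default 0 (stain over nucleus); a
        positive offset deliberately triggers the isotype-fallback rule.
    touching_pairs:
        Number of nucleus pairs placed at sub-diameter spacing to exercise
        watershed splitting (0 by default: nuclei are non-touching).
    dapi_intensity, background_level, noise_sd:
        Nucleus disk intensity, additive background, and Gaussian noise SD,
        all on the [0, 255] scale.
    quantize:
        Round rendered channels to integers (off by default).
    seed:
        RNG seed; equal seeds give bit-identical fields.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    um_per_px: float = 0.62
    n_colonies: int = 2
    cells_per_colony: tuple[int, int] = (4, 8)
    n_single_cells: int = 6
    colony_radius_um: float = 50.0
    colony_spacing_um: float = 130.0
    nucleus_radius_px: tuple[int, int] = (6, 9)
    populations: Sequence[Population] = DEFAULT_POPULATIONS
    stain_radius_px: int = 6
    stain_offset_px: float = 0.0
    touching_pairs: int = 0
    dapi_intensity: float = 200.0
    background_level: float = 8.0
    noise_sd: float = 0.0
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.n_colonies < 0 or self.n_single_cells < 0:
            raise ValueError("cell counts must be nonnegative")
        lo, hi = self.nucleus_radius_px
        if lo < 1 or hi < lo:
            raise ValueError("invalid nucleus_radius_px range")
        if self.n_colonies > 0 and self.cells_per_colony[0] < 2:
            raise ValueError("colonies need >= 2 cells for the neighbor invariant")


@dataclass
class GroundTruth:
    """Per-cell truth for one synthetic field, one row per generated nucleus."""

    table: pd.DataFrame  # columns: cell_id, row, col, radius_px, population,
    #          true_<channel> per stain channel, spatial_class, syncytium_id

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def true_fusion_index(self) -> float:
        """Recompute (N − S)/T from the syncytium assignments."""
        t = self.n_cells
        if t == 0:
            raise ValueError("no cells")
        syn = self.table["syncytium_id"].dropna()
        sizes = syn.value_counts()
        sizes = sizes[sizes >= 2]
        n = int(sizes.sum())
        s = int(len(sizes))
        return (n - s) / t


# ---------------------------------------------------------------------------
# nucleus placement


def _min_sep_px(spec: FieldSpec) -> float:
    # non-overlap by construction: center distance > 2 x max radius
    return 2.0 * spec.nucleus_radius_px[1] + 1.0


def _in_bounds(spec: FieldSpec, r: float, c: float, rad: int) -> bool:
    return (
        r - rad >= 0
        and c - rad >= 0
        and r + rad <= spec.image_height_px - 1
        and c + rad <= spec.image_width_px - 1
    )


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Place nucleus centers satisfying the spacing/isolation invariants.

    Returns (centers (k,2) float array, radii (k,) int array,
    spatial_class list, colony_ids list). Raises PackingError when a
    constraint cannot be met after bounded retries.
    """
    h, w = spec.image_height_px, spec.image_width_px
    radius_lo, radius_hi = spec.nucleus_radius_px
    colony_r_px = spec.colony_radius_um / spec.um_per_px
    spacing_px = spec.colony_spacing_um / spec.um_per_px
    min_sep = _min_sep_px(spec)
    max_attempts = 20000

    centers: list[tuple[float, float]] = []
    radii: list[int] = []
    classes: list[str] = []
    colony_ids: list[int] = []

    def far_from_all(r, c, d):
        for rr, cc in centers:
            if (rr - r) ** 2 + (cc - c) ** 2 <= d * d:
                return False
        return True

    # colony centers
    colony_centers: list[tuple[float, float]] = []
    for _ in range(spec.n_colonies):
        placed = False
        for _ in range(max_attempts):
            r = rng.uniform(colony_r_px / 2 + radius_hi, h - 1 - colony_r_px / 2 - radius_hi)
            c = rng.uniform(colony_r_px / 2 + radius_hi, w - 1 - colony_r_px / 2 - radius_hi)
            if all((rr - r) ** 2 + (cc - c) ** 2 > spacing_px**2 for rr, cc in colony_centers):
                colony_centers.append((r, c))
                placed = True
                break
        if not placed:
            raise PackingError(
                "could not place colony centers at spacing "
                f"{spec.colony_spacing_um} um in a {h}x{w} image"
            )

    # colony members: within colony_radius/2 of their center so that any two
    # members of the same colony are within colony_radius of each other
    for cid, (cr, cc) in enumerate(colony_centers):
        n_cells = int(rng.integers(spec.cells_per_colony[0], spec.cells_per_colony[1] + 1))
        for _ in range(n_cells):
            placed = False
            for _ in range(max_attempts):
                ang = rng.uniform(0, 2 * math.pi)
                dist = (colony_r_px / 2) * math.sqrt(rng.uniform())
                r = cr + dist * math.sin(ang)
                c = cc + dist * math.cos(ang)
                rad = int(rng.integers(radius_lo, radius_hi + 1))
                if _in_bounds(spec, r, c, rad) and far_from_all(r, c, min_sep):
                    centers.append((r, c))
                    radii.append(rad)
                    classes.append("colony")
                    colony_ids.append(cid)
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not pack {n_cells} non-overlapping nuclei within "
                    f"colony radius {spec.colony_radius_um} um"
                )

    # single cells: no other nucleus centroid within colony_radius
    iso = max(colony_r_px, min_sep)
    for _ in range(spec.n_single_cells):
        placed = False
        for _ in range(max_attempts):
            r = rng.uniform(radius_hi, h - 1 - radius_hi)
            c = rng.uniform(radius_hi, w - 1 - radius_hi)
            rad = int(rng.integers(radius_lo, radius_hi + 1))
            if _in_bounds(spec, r, c, rad) and far_from_all(r, c, iso):
                centers.append((r, c))
                radii.append(rad)
                classes.append("single")
                colony_ids.append(-1)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place {spec.n_single_cells} isolated cells at "
                f"isolation radius {spec.colony_radius_um} um in a {h}x{w} image"
            )

    # optional touching pairs (sub-diameter spacing) for watershed tests;
    # labeled "colony" since the pair members are mutual neighbors
    for _ in range(spec.touching_pairs):
        placed = False
        for _ in range(max_attempts):
            rad = int(rng.integers(radius_lo, radius_hi + 1))
            gap = 1.5 * rad  # overlapping: spacing 1.5 x radius < 2 x radius
            ang = rng.uniform(0, 2 * math.pi)
            r0 = rng.uniform(2 * rad, h - 1 - 2 * rad)
            c0 = rng.uniform(2 * rad, w - 1 - 2 * rad)
            r1 = r0 + gap * math.sin(ang)
            c1 = c0 + gap * math.cos(ang)
            ok = (
                _in_bounds(spec, r0, c0, rad)
                and _in_bounds(spec, r1, c1, rad)
                and far_from_all(r0, c0, 4 * rad)
                and far_from_all(r1, c1, 4 * rad)
            )
            if ok:
                for r, c in ((r0, c0), (r1, c1)):
                    centers.append((r, c))
                    radii.append(rad)
                    classes.append("colony")
                    colony_ids.append(-2)
                placed = True
                break
        if not placed:
            raise PackingError("could not place touching nucleus pairs")

    if not centers:
        raise PackingError("spec requests zero cells")
    return np.asarray(centers, dtype=float), np.asarray(radii), classes, colony_ids


def _disk_coords(center: tuple[float, float], radius: float, shape: tuple[int, int]):
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def _finish(spec: FieldSpec, channels: dict[str, np.ndarray], rng: np.random.Generator):
    for name, img in channels.items():
        # background fills unsignaled pixels only, so a rendered blob's mean
        # equals the cell's true intensity exactly at zero noise
        img[img == 0.0] = spec.background_level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        np.clip(img, 0.0, MAX_INTENSITY, out=img)
        if spec.quantize:
            np.rint(img, out=img)
        channels[name] = img


# ---------------------------------------------------------------------------
# public generators


def generate_field(
    spec: FieldSpec, *, field_id: str = "field", group_id: str = "group"
) -> tuple[Field, GroundTruth]:
    """Render a 3-channel experimental field plus its ground truth.

    Each nucleus is a filled disk of DAPI intensity in the blue channel; each
    cell's stain signal is a disk of its true per-channel intensity placed at
    ``stain_offset_px`` from the nucleus centroid; background and Gaussian
    noise are added and the result clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii, classes, _colony_ids = _place_nuclei(spec, rng)
    shape = (spec.image_height_px, spec.image_width_px)

    stain_channels = sorted({ch for p in spec.populations for ch in p.channel_means})
    weights = np.asarray([p.weight for p in spec.populations], dtype=float)
    weights = weights / weights.sum()
    pop_idx = rng.choice(len(spec.populations), size=len(centers), p=weights)

    true_int = {ch: np.zeros(len(centers)) for ch in stain_channels}
    for i, pi in enumerate(pop_idx):
        pop = spec.populations[pi]
        for ch in stain_channels:
            mean, sd = pop.channel_means.get(ch, (0.0, 0.0))
            val = rng.normal(mean, sd) if sd > 0 else mean
            true_int[ch][i] = float(np.clip(val, 0.0, MAX_INTENSITY))

    blue = np.zeros(shape)
    for (r, c), rad in zip(centers, radii):
        blue[_disk_coords((r, c), rad, shape)] = spec.dapi_intensity

    channels: dict[str, np.ndarray] = {"blue": blue}
    for ch in stain_channels:
        img = np.zeros(shape)
        for i, (r, c) in enumerate(centers):
            if spec.stain_offset_px > 0:
                ang = rng.uniform(0, 2 * math.pi)
                r = r + spec.stain_offset_px * math.sin(ang)
                c = c + spec.stain_offset_px * math.cos(ang)
            img[_disk_coords((r, c), spec.stain_radius_px, shape)] = true_int[ch][i]
        channels[ch] = img

    _finish(spec, channels, rng)

    gt = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius_px": radii,
            "population": [spec.populations[i].name for i in pop_idx],
            "spatial_class": classes,
            "syncytium_id": pd.array([pd.NA] * len(centers), dtype="Int64"),
        }
    )
    for ch in stain_channels:
        gt[f"true_{ch}"] = true_int[ch]

    field = Field(
        channels=channels,
        um_per_px=spec.um_per_px,
        field_id=field_id,
        group_id=group_id,
        is_isotype=False,
    )
    return field, GroundTruth(gt)


def generate_isotype_field(
    spec: FieldSpec, *, field_id: str = "isotype", group_id: str = "group"
) -> tuple[Field, GroundTruth]:
    """Render an isotype-control field: nuclei as usual, stain channels
    containing only background + noise (no cell-associated signal)."""
    stainless = dataclasses.replace(
        spec,
        populations=[
            Population(p.name, p.weight, {ch: (0.0, 0.0) for ch in p.channel_means})
            for p in spec.populations
        ],
    )
    field, gt = generate_field(stainless, field_id=field_id, group_id=group_id)
    for ch in field.channels:
        if ch != "blue":
            gt.table[f"true_{ch}"] = spec.background_level
    field.is_isotype = True
    return field, gt


def generate_membrane_field(
    spec: FieldSpec,
    target_fusion_index: float,
    *,
    field_id: str = "membrane",
    group_id: str = "group",
    membrane_intensity: float = 180.0,
) -> tuple[Field, GroundTruth]:
    """Render a membrane-stained field with a known fusion index.

    The membrane channel partitions the image into closed rectangular
    regions. With T total nuclei and target f, k = round(f·T) nuclei beyond
    one are grouped into a single syncytial region (N = k + 1 nuclei,
    S = 1), so (N − S)/T = k/T is within 1/T of the target; the remaining
    nuclei occupy one region each. A target of 0 yields only singly-occupied
    regions (S = 0).
    """
    if not 0.0 <= target_fusion_index < 1.0:
        raise ValueError("target fusion index must be in [0, 1)")
    t_total = spec.n_single_cells + spec.n_colonies * spec.cells_per_colony[0]
    # membrane fields use a simple count: all requested cells, colony layout ignored
    t_total = spec.n_single_cells if spec.n_colonies == 0 else t_total
    if t_total < 1:
        raise ValueError("membrane field needs >= 1 nucleus")
    k = int(round(target_fusion_index * t_total))
    if k > 0 and k + 1 > t_total:
        raise PackingError(
            f"fusion target {target_fusion_index} unreachable with T={t_total}"
        )

    region_sizes = ([k + 1] if k > 0 else []) + [1] * (t_total - (k + 1 if k > 0 else 0))
    n_regions = len(region_sizes)

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    shape = (h, w)
    radius_lo, radius_hi = spec.nucleus_radius_px

    # grid of region boxes; the syncytium gets a whole grid row if it needs room
    g = max(1, math.ceil(math.sqrt(n_regions)))
    rows = math.ceil(n_regions / g)
    box_h, box_w = h // rows, w // g
    need = (2 * radius_hi + 4) ** 2 * max(region_sizes)
    if box_h * box_w < need:
        raise PackingError(
            f"image {h}x{w} too small for {n_regions} membrane regions holding "
            f"up to {max(region_sizes)} nuclei"
        )

    membrane = np.zeros(shape)
    membrane[0, :] = membrane_intensity
    membrane[-1, :] = membrane_intensity
    membrane[:, 0] = membrane_intensity
    membrane[:, -1] = membrane_intensity
    for i in range(1, rows):
        membrane[i * box_h, :] = membrane_intensity
    for j in range(1, g):
        membrane[:, j * box_w] = membrane_intensity

    order = rng.permutation(n_regions)
    centers: list[tuple[float, float]] = []
    radii: list[int] = []
    syncytium_ids: list[object] = []
    min_sep = 2 * radius_hi + 2
    syn_counter = 0
    for size, slot in zip(region_sizes, order):
        br, bc = divmod(int(slot), g)
        r0, r1 = br * box_h + radius_hi + 2, min((br + 1) * box_h, h) - radius_hi - 2
        c0, c1 = bc * box_w + radius_hi + 2, min((bc + 1) * box_w, w) - radius_hi - 2
        syn_id: object = pd.NA
        if size >= 2:
            syn_id = syn_counter
            syn_counter += 1
        placed_pts: list[tuple[float, float]] = []
        for _ in range(size):
            ok = False
            for _ in range(20000):
                r = rng.uniform(r0, r1)
                c = rng.uniform(c0, c1)
                if all((pr - r) ** 2 + (pc - c) ** 2 > min_sep**2 for pr, pc in placed_pts):
                    ok = True
                    break
            if not ok:
                raise PackingError(
                    f"could not pack {size} nuclei inside a {box_h}x{box_w} membrane region"
                )
            placed_pts.append((r, c))
            centers.append((r, c))
            radii.append(int(rng.integers(radius_lo, radius_hi + 1)))
            syncytium_ids.append(syn_id)

    blue = np.zeros(shape)
    for (r, c), rad in zip(centers, radii):
        blue[_disk_coords((r, c), rad, shape)] = spec.dapi_intensity
    channels = {"blue": blue, "membrane": membrane}
    _finish(spec, channels, rng)

    arr = np.asarray(centers)
    gt = pd.DataFrame(
        {
            "cell_id": np.arange(t_total),
            "row": arr[:, 0],
            "col": arr[:, 1],
            "radius_px": radii,
            "population": "membrane",
            "spatial_class": "unset",
            "syncytium_id": pd.array(syncytium_ids, dtype="Int64"),
        }
    )
    field = Field(
        channels=channels,
        um_per_px=spec.um_per_px,
        field_id=field_id,
        group_id=group_id,
        is_isotype=False,
    )
    return field, GroundTruth(gt)


def generate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    replicates: int,
    true_log2fc: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    *,
    housekeeping: Sequence[str] = ("GAPDH", "ACTB"),
    reference: str = "day0",
) -> pd.DataFrame:
    """Construct a qPCR Ct table whose ΔΔCT analysis recovers ``true_log2fc``.

    Housekeeping Cts are constant across conditions (up to noise); a target
    gene's Ct in a condition is its base Ct minus the true log2 fold change,
    so at ``ct_noise_sd = 0`` the ΔΔCT pipeline recovers the truth exactly.

    Returns a tidy DataFrame with columns gene, condition, replicate, ct,
    role (``target``/``housekeeping``) plus a ``reference_condition`` column.
    """
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not in conditions")
    for hk in housekeeping:
        fc = true_log2fc.get(hk, {})
        if any(abs(v) > 1e-12 for v in fc.values()):
            raise ValueError(f"housekeeping gene {hk} must have true_log2fc = 0")

    rng = np.random.default_rng(seed)
    hk_base = {hk: 15.0 + 2.0 * i for i, hk in enumerate(housekeeping)}
    rows = []
    all_genes = list(dict.fromkeys(list(housekeeping) + list(genes)))
    for gi, gene in enumerate(all_genes):
        is_hk = gene in hk_base
        base = hk_base.get(gene, 20.0 + (gi % 7))
        for cond in conditions:
            l2fc = 0.0 if is_hk else float(true_log2fc.get(gene, {}).get(cond, 0.0))
            for rep in range(1, replicates + 1):
                ct = base - l2fc
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": ct,
                        "role": "housekeeping" if is_hk else "target",
                        "reference_condition": reference,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: TIFF / PNG / CSV / YAML round-trips


def save_field_tiff(field: Field, path: str | Path) -> None:
    """Write a field as a multi-page float32 TIFF (one page per channel),
    channel names and metadata in the TIFF description."""
    path = Path(path)
    names = sorted(field.channels)
    stack = np.stack([field.channels[n].astype(np.float32) for n in names])
    meta = {
        "channels": names,
        "um_per_px": field.um_per_px,
        "field_id": field.field_id,
        "group_id": field.group_id,
        "is_isotype": field.is_isotype,
    }
    tifffile.imwrite(
        path, stack, description=json.dumps(meta), photometric="minisblack"
    )


def load_field_tiff(path: str | Path) -> Field:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    return Field(
        channels=channels,
        um_per_px=float(meta["um_per_px"]),
        field_id=meta["field_id"],
        group_id=meta["group_id"],
        is_isotype=bool(meta["is_isotype"]),
    )


def save_field_png(field: Field, path: str | Path) -> None:
    """Write an 8-bit RGB PNG (red/green/blue channels; missing → zeros)."""
    h, w = next(iter(field.channels.values())).shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for i, ch in enumerate(("red", "green", "blue")):
        if ch in field.channels:
            rgb[..., i] = np.clip(np.rint(field.channels[ch]), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), rgb)


def save_ground_truth_csv(gt: GroundTruth, path: str | Path) -> None:
    gt.table.to_csv(Path(path), index=False)


def load_ground_truth_csv(path: str | Path) -> GroundTruth:
    table = pd.read_csv(Path(path))
    table["syncytium_id"] = pd.array(table["syncytium_id"], dtype="Int64")
    return GroundTruth(table)


def save_field_spec(spec: FieldSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d["populations"] = [
        {"name": p.name, "weight": p.weight, "channel_means": {k: list(v) for k, v in p.channel_means.items()}}
        for p in spec.populations
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_field_spec(path: str | Path) -> FieldSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["populations"] = tuple(
        Population(p["name"], p["weight"], {k: tuple(v) for k, v in p["channel_means"].items()})
        for p in d["populations"]
    )
    for key in ("cells_per_colony", "nucleus_radius_px"):
        d[key] = tuple(d[key])
    return FieldSpec(**d)
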