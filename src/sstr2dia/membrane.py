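"""Digital image analysis of membranous DAB immunostaining.

The pipeline mirrors the contract of commercial membrane-quantification
software for brightfield IHC:

1. unmix the RGB image into hematoxylin and DAB optical-density (OD) maps
   (Ruifrok–Johnston color deconvolution with a fixed stain matrix);
2. segment nuclei on the hematoxylin map and expand each nucleus to a cell
   territory;
3. measure, per cell, the mean DAB OD on the membrane ring and the membrane
   *completeness* — the fraction of angular sectors around the nucleus whose
   ring pixels reach the OD positivity threshold;
4. classify cells positive when completeness strictly exceeds the
   minimum-completeness parameter (default 0%, i.e. any supra-threshold
   membrane signal counts);
5. select the hot spot — the sliding window holding 1000–2000 cells with the
   highest composite score — and report
   ``%positive × mean positive membrane OD × mean positive completeness``.

A note on step 1: projecting the pixel OD vector onto the DAB vector alone
would leave severe cross-talk (the unit hematoxylin and DAB OD vectors have
a dot product of ~0.8), so the full 3x3 stain-matrix inversion is used; a
purely hematoxylin-stained pixel then unmixes to DAB OD ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, erosion
from skimage.segmentation import watershed, expand_labels

__all__ = [
    "DAB_OD_RGB",
    "HEMATOXYLIN_OD_RGB",
    "StainVector",
    "CellMeasurement",
    "DIAResult",
    "HotSpot",
    "Segmentation",
    "rgb_to_od",
    "stain_matrix",
    "unmix_stains",
    "deconvolve_dab",
    "deconvolve_hematoxylin",
    "segment_cells",
    "measure_membrane",
    "classify_positive",
    "select_hotspot",
    "composite_score",
    "quantify_image",
]

#: DAB reaction-product OD vector used for SSTR2 membrane scoring (RGB order).
DAB_OD_RGB = (0.268, 0.570, 0.776)
#: Standard hematoxylin counterstain OD vector (RGB order).
HEMATOXYLIN_OD_RGB = (0.650, 0.704, 0.286)

#: Additive constant (intensity units) preventing log(0) in the OD transform.
OD_EPSILON = 1.0


@dataclass(frozen=True)
class StainVector:
    """Unit-norm per-channel optical density vector of one chromogen."""

    od_rgb: tuple[float, float, float]

    def __post_init__(self):
        v = np.asarray(self.od_rgb, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("stain vector must be nonzero")
        object.__setattr__(self, "od_rgb", tuple(v / n))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.od_rgb, dtype=float)


DAB = StainVector(DAB_OD_RGB)
HEMATOXYLIN = StainVector(HEMATOXYLIN_OD_RGB)


@dataclass
class CellMeasurement:
    """Schema of one row of the per-cell measurement table."""

    cell_id: int
    centroid_row: float
    centroid_col: float
    nucleus_area: float
    nucleus_roundness: float
    membrane_mean_od: float
    membrane_completeness: float
    is_positive: bool
    ring_clipped: bool = False


@dataclass
class DIAResult:
    """Hot-spot level quantification of membranous immunoreactivity."""

    pct_positive_cells: float
    avg_positive_membrane_od: float
    avg_positive_completeness: float
    composite_score: float
    n_cells: int

    @property
    def table_value(self) -> int:
        """Composite rounded down to an integer, as reported in case tables."""
        return int(np.floor(self.composite_score))


@dataclass
class HotSpot:
    """Window selected for quantification and the cells it contains."""

    origin: tuple[int, int]  # (row, col), 0-based
    size: tuple[int, int]  # (height, width)
    cell_ids: list[int] = field(default_factory=list)
    n_cells: int = 0
    degraded: bool = False  # True when no window reached the minimum cell count


@dataclass
class Segmentation:
    """Labeled nuclei, expanded cell territories, and per-cell geometry."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cells: pd.DataFrame  # cell_id, centroid_row, centroid_col, nucleus_area, nucleus_roundness

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _check_rgb(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return img.astype(float)


def rgb_to_od(image, eps: float = OD_EPSILON) -> np.ndarray:
    """Per-channel optical density, OD = −log10((I+ε)/255), clamped at 0."""
    img = _check_rgb(image)
    od = -np.log10((img + eps) / 255.0)
    return np.clip(od, 0.0, None)


def stain_matrix(hematoxylin: StainVector = HEMATOXYLIN,
                 dab: StainVector = DAB) -> np.ndarray:
    """3×3 stain matrix (rows: hematoxylin, DAB, residual).

    The residual vector is the normalized cross product of the two stains,
    completing the basis so the matrix can be inverted.
    """
    h, d = hematoxylin.array, dab.array
    r = np.cross(h, d)
    nr = np.linalg.norm(r)
    if nr < 1e-6:
        raise ValueError("stain vectors are collinear; cannot unmix")
    return np.vstack([h, d, r / nr])


def unmix_stains(image, hematoxylin: StainVector = HEMATOXYLIN,
                 dab: StainVector = DAB) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel hematoxylin and DAB OD concentration maps (clamped ≥ 0)."""
    od = rgb_to_od(image)
    m = stain_matrix(hematoxylin, dab)
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    conc = conc.reshape(od.shape)
    hema = np.clip(conc[..., 0], 0.0, None)
    dab_map = np.clip(conc[..., 1], 0.0, None)
    return hema, dab_map


def deconvolve_dab(image, hematoxylin: StainVector = HEMATOXYLIN,
                   dab: StainVector = DAB) -> np.ndarray:
    """DAB OD map from stain unmixing (see module docstring)."""
    return unmix_stains(image, hematoxylin, dab)[1]


def deconvolve_hematoxylin(image, hematoxylin: StainVector = HEMATOXYLIN,
                           dab: StainVector = DAB) -> np.ndarray:
    """Hematoxylin OD map from stain unmixing."""
    return unmix_stains(image, hematoxylin, dab)[0]


def segment_cells(
    image,
    *,
    nucleus_od_threshold: float = 0.15,
    min_distance: int = 10,
    min_nucleus_area: float = 20.0,
    max_nucleus_area: float = 500.0,
    min_roundness: float = 0.4,
    expand_radius: int = 5,
    hematoxylin: StainVector = HEMATOXYLIN,
    dab: StainVector = DAB,
) -> Segmentation:
    """Detect nuclei on the hematoxylin channel and grow cell territories.

    Nuclei are supra-threshold hematoxylin regions split by a watershed on
    the distance transform (markers = distance peaks at least ``min_distance``
    apart — nuclei closer than that merge, deterministically). Candidates
    outside the nuclear size or roundness bounds (roundness = 4πA/P², capped
    at 1) are discarded. Each surviving nucleus is expanded by
    ``expand_radius`` pixels into a territory bounded by its neighbors.

    An image with no nuclei yields an empty segmentation, not an error.
    """
    hema, _ = unmix_stains(image, hematoxylin, dab)
    mask = hema >= nucleus_od_threshold
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        empty = np.zeros(mask.shape, dtype=np.int32)
        cells = pd.DataFrame(columns=["cell_id", "centroid_row", "centroid_col",
                                      "nucleus_area", "nucleus_roundness"])
        return Segmentation(empty, empty, cells)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(distance, min_distance=min_distance,
                           labels=sk_label(mask), exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    nucleus_labels = watershed(-distance, markers, mask=mask)

    rows = []
    keep = np.zeros(nucleus_labels.max() + 1, dtype=bool)
    for prop in regionprops(nucleus_labels):
        area = prop.area
        perim = prop.perimeter
        roundness = min(1.0, 4 * np.pi * area / perim**2) if perim > 0 else 0.0
        if not (min_nucleus_area <= area <= max_nucleus_area):
            continue
        if roundness < min_roundness:
            continue
        keep[prop.label] = True
        rows.append((prop.label, prop.centroid[0], prop.centroid[1], float(area), roundness))

    filtered = np.where(keep[nucleus_labels], nucleus_labels, 0).astype(np.int32)
    # relabel sequentially, ordered by original label for determinism
    old_ids = sorted(r[0] for r in rows)
    remap = {old: new for new, old in enumerate(old_ids, start=1)}
    relabeled = np.zeros_like(filtered)
    for old, new in remap.items():
        relabeled[filtered == old] = new
    cells = pd.DataFrame(
        [(remap[cid], cr, cc, a, rd) for cid, cr, cc, a, rd in rows],
        columns=["cell_id", "centroid_row", "centroid_col",
                 "nucleus_area", "nucleus_roundness"],
    ).sort_values("cell_id", ignore_index=True)
    cell_labels = expand_labels(relabeled, distance=expand_radius)
    return Segmentation(relabeled, cell_labels, cells)


def measure_membrane(
    segmentation: Segmentation,
    dab_od: np.ndarray,
    *,
    od_threshold: float = 0.15,
    ring_width: int = 3,
    n_sectors: int = 36,
) -> pd.DataFrame:
    """Per-cell membrane OD and completeness (columns of CellMeasurement).

    The membrane ring is the outer band of the cell territory, ``ring_width``
    pixels deep. Completeness is the percentage of the ``n_sectors`` angular
    sectors about the nucleus centroid containing at least one ring pixel
    with DAB OD ≥ ``od_threshold``; the mean OD is taken over supra-threshold
    ring pixels only (0 when there are none). Cells whose territory touches
    the image border have their ring clipped and are flagged.
    """
    labels = segmentation.cell_labels
    h, w = labels.shape
    footprint = disk(ring_width)
    out = []
    sector_width = 2 * np.pi / n_sectors
    for rec in segmentation.cells.itertuples(index=False):
        cid = int(rec.cell_id)
        region = labels == cid
        rr, cc = np.nonzero(region)
        if rr.size == 0:
            continue
        clipped = bool(rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1)
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        pad = ring_width + 1
        sub = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=bool)
        sub[pad:-pad, pad:-pad] = region[r0:r1, c0:c1]
        ring_sub = sub & ~erosion(sub, footprint)
        ring_r, ring_c = np.nonzero(ring_sub)
        ring_r = ring_r - pad + r0
        ring_c = ring_c - pad + c0
        inside = (ring_r >= 0) & (ring_r < h) & (ring_c >= 0) & (ring_c < w)
        ring_r, ring_c = ring_r[inside], ring_c[inside]
        od_vals = dab_od[ring_r, ring_c]
        supra = od_vals >= od_threshold
        if supra.any():
            mean_od = float(od_vals[supra].mean())
            theta = np.arctan2(ring_r[supra] - rec.centroid_row,
                               ring_c[supra] - rec.centroid_col)
            sectors = np.floor((theta + np.pi) / sector_width).astype(int)
            sectors = np.clip(sectors, 0, n_sectors - 1)
            completeness = 100.0 * np.unique(sectors).size / n_sectors
        else:
            mean_od = 0.0
            completeness = 0.0
        out.append(CellMeasurement(
            cell_id=cid,
            centroid_row=float(rec.centroid_row),
            centroid_col=float(rec.centroid_col),
            nucleus_area=float(rec.nucleus_area),
            nucleus_roundness=float(rec.nucleus_roundness),
            membrane_mean_od=mean_od,
            membrane_completeness=completeness,
            is_positive=completeness > 0.0,
            ring_clipped=clipped,
        ))
    return pd.DataFrame([m.__dict__ for m in out])


def classify_positive(measurements: pd.DataFrame, min_completeness: float = 0.0) -> pd.DataFrame:
    """Set the positivity flag: positive ⇔ completeness strictly exceeds
    ``min_completeness`` (so at the default 0%, any membrane signal counts,
    and at 50%, cells at exactly 50% completeness are excluded)."""
    if not 0.0 <= min_completeness <= 100.0:
        raise ValueError("min_completeness must be in [0, 100]")
    df = measurements.copy()
    df["is_positive"] = df["membrane_completeness"] > min_completeness
    return df


def composite_score(measurements: pd.DataFrame) -> DIAResult:
    """Composite membrane score over a set of cells.

    composite = %positive cells × mean positive membrane OD × mean positive
    membrane completeness (both means over positive cells only; all three
    factors 0 when no cell is positive).
    """
    n = len(measurements)
    if n == 0:
        raise ValueError("cannot score an empty cell set")
    pos = measurements[measurements["is_positive"]]
    pct = 100.0 * len(pos) / n
    if len(pos) == 0:
        return DIAResult(0.0, 0.0, 0.0, 0.0, n)
    avg_od = float(pos["membrane_mean_od"].mean())
    avg_comp = float(pos["membrane_completeness"].mean())
    return DIAResult(pct, avg_od, avg_comp, pct * avg_od * avg_comp, n)


def select_hotspot(
    measurements: pd.DataFrame,
    image_shape: tuple[int, int],
    *,
    window: int = 512,
    stride: int = 128,
    min_cells: int = 1000,
    max_cells: int = 2000,
) -> HotSpot:
    """Sliding-window hot-spot selection.

    Among windows holding ``min_cells``–``max_cells`` cells, returns the one
    with the highest composite score; ties are broken by the smallest
    (row, col) origin. Windows over capacity are considered only if no
    in-range window exists. If no window reaches ``min_cells``, all cells
    are returned flagged as degraded.
    """
    if len(measurements) == 0:
        raise ValueError("no cells to select a hot spot from")
    h, w = image_shape[:2]
    win_h, win_w = min(window, h), min(window, w)
    row_origins = list(range(0, max(h - win_h, 0) + 1, stride))
    col_origins = list(range(0, max(w - win_w, 0) + 1, stride))
    rows = measurements["centroid_row"].to_numpy()
    cols = measurements["centroid_col"].to_numpy()

    candidates = []  # (in_range, score, origin, ids)
    for r0 in row_origins:
        for c0 in col_origins:
            mask = (rows >= r0) & (rows < r0 + win_h) & (cols >= c0) & (cols < c0 + win_w)
            cnt = int(mask.sum())
            if cnt < min_cells:
                continue
            score = composite_score(measurements[mask]).composite_score
            candidates.append((cnt <= max_cells, score, (r0, c0),
                               measurements.loc[mask, "cell_id"].tolist()))
    in_range = [c for c in candidates if c[0]]
    pool = in_range if in_range else candidates
    if not pool:
        return HotSpot(origin=(0, 0), size=(h, w),
                       cell_ids=measurements["cell_id"].tolist(),
                       n_cells=len(measurements), degraded=True)
    best = min(pool, key=lambda c: (-c[1], c[2]))
    return HotSpot(origin=best[2], size=(win_h, win_w),
                   cell_ids=best[3], n_cells=len(best[3]), degraded=False)


def quantify_image(
    image,
    *,
    min_completeness: float = 0.0,
    od_threshold: float = 0.15,
    ring_width: int = 3,
    n_sectors: int = 36,
    hotspot_window: int = 512,
    hotspot_stride: int = 128,
    hotspot_min_cells: int = 1000,
    hotspot_max_cells: int = 2000,
    segmentation_kwargs: dict | None = None,
) -> tuple[DIAResult, pd.DataFrame, HotSpot]:
    """End-to-end quantification of one image.

    Returns the hot-spot DIA result, the full per-cell measurement table,
    and the selected hot spot.
    """
    seg = segment_cells(image, **(segmentation_kwargs or {}))
    if seg.n_cells == 0:
        raise ValueError("no cells detected in image")
    dab_map = deconvolve_dab(image)
    cells = measure_membrane(seg, dab_map, od_threshold=od_threshold,
                             ring_width=ring_width, n_sectors=n_sectors)
    cells = classify_positive(cells, min_completeness)
    spot = select_hotspot(cells, image.shape[:2], window=hotspot_window,
                          stride=hotspot_stride, min_cells=hotspot_min_cells,
                          max_cells=hotspot_max_cells)
    in_spot = cells[cells["cell_id"].isin(spot.cell_ids)]
    return composite_score(in_spot), cells, spot
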