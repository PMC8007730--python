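"""Per-cell aggregate scoring: mean + k*SD pixel selection and the clustering index.

The core statistic quantifies how strongly a fluorescent signal is
concentrated into bright puncta (p62 bodies, SOD1 aggregates) within a
single cell. For one cell and one channel:

1. compute the mean ``m`` and standard deviation ``s`` of intensity over
   the *whole* cell (aggregate pixels included; single pass, no iterative
   re-thresholding);
2. select the pixels whose intensity strictly exceeds ``m + k*s``
   (default ``k = 3``);
3. the clustering index is ``sum(intensity over selected pixels) / m`` —
   a dimensionless, scale-invariant measure of punctate concentration.
   The same statistic computed on an aggregate-prone cargo channel is
   called the aggregation index.

Puncta are the connected components of the selection (8-connected by
default), optionally filtered by a minimum area; the index itself always
uses the unfiltered selection so the headline statistic matches the
definitional formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import CellMaskSet

__all__ = [
    "ThresholdParams",
    "PixelSelection",
    "Punctum",
    "CellQuantResult",
    "cell_intensity_stats",
    "select_aggregate_pixels",
    "label_puncta",
    "clustering_index",
    "quantify_cell",
    "quantify_all_cells",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Tunable knobs of the selection rule.

    Parameters
    ----------
    k
        SD multiplier of the threshold ``mean + k*SD``. Default 3.
    strict
        If True (default), a pixel must *exceed* the threshold; on a
        constant cell (SD 0) the selection is then unambiguously empty.
    sd_mode
        ``"sample"`` (n-1 normalization, default) or ``"population"`` (n).
    min_punctum_px
        Minimum connected-component area, in pixels, for a component to be
        counted as a punctum. Default 4 suppresses single-pixel noise.
        Applies to puncta counting only, never to the index.
    connectivity
        4 or 8 pixel connectivity for component labeling. Default 8.
    """

    k: float = 3.0
    strict: bool = True
    sd_mode: str = "sample"
    min_punctum_px: int = 4
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")
        if self.min_punctum_px < 1:
            raise ValueError("min_punctum_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class PixelSelection:
    """Pixels of one cell selected by the threshold rule, with the statistics
    they were selected against."""

    cell_id: int
    selected: np.ndarray  # boolean grid, subset of the cell mask
    threshold: float
    cell_mean: float
    cell_sd: float
    n_cell_px: int

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))


@dataclass(frozen=True)
class Punctum:
    """One connected bright component: id, area in pixels, (row, col) centroid."""

    punctum_id: int
    area_px: int
    centroid: tuple[float, float]


@dataclass
class CellQuantResult:
    """Everything the pipeline reports for one cell."""

    cell_id: int
    cell_mean: float
    cell_sd: float
    threshold: float
    n_cell_px: int
    n_selected_px: int
    total_selected_intensity: float
    clustering_index: float
    n_puncta: int
    punctum_areas: list[int] = field(default_factory=list)

    def to_row(self) -> dict:
        areas = self.punctum_areas
        return {
            "cell_id": self.cell_id,
            "mean": self.cell_mean,
            "sd": self.cell_sd,
            "threshold": self.threshold,
            "n_cell_px": self.n_cell_px,
            "n_selected_px": self.n_selected_px,
            "clustering_index": self.clustering_index,
            "n_puncta": self.n_puncta,
            "mean_punctum_area": float(np.mean(areas)) if areas else 0.0,
        }


def cell_intensity_stats(
    image: np.ndarray,
    mask: CellMaskSet,
    cell_id: int,
    sd_mode: str = "sample",
) -> tuple[float, float, int]:
    """Mean, SD and pixel count of one channel over exactly one cell's pixels.

    ``sd_mode="sample"`` uses the n-1 normalization and requires at least
    2 pixels; ``"population"`` uses n.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    values = image[mask.cell_pixels(cell_id)]
    n = values.size
    if sd_mode == "sample":
        if n < 2:
            raise ValueError(f"cell {cell_id}: sample SD undefined for a single-pixel cell")
        sd = float(np.std(values, ddof=1))
    elif sd_mode == "population":
        sd = float(np.std(values, ddof=0))
    else:
        raise ValueError("sd_mode must be 'sample' or 'population'")
    return float(np.mean(values)), sd, n


def select_aggregate_pixels(
    image: np.ndarray,
    mask: CellMaskSet,
    cell_id: int,
    params: ThresholdParams = ThresholdParams(),
) -> PixelSelection:
    """Select the cell's pixels whose intensity exceeds ``mean + k*SD``.

    The statistics are taken over the whole cell in a single pass —
    aggregate pixels are not excluded and the threshold is not iterated.
    """
    mean, sd, n = cell_intensity_stats(image, mask, cell_id, sd_mode=params.sd_mode)
    threshold = mean + params.k * sd
    cell = mask.cell_pixels(cell_id)
    image = np.asarray(image, dtype=np.float64)
    if params.strict:
        selected = cell & (image > threshold)
    else:
        selected = cell & (image >= threshold)
    return PixelSelection(
        cell_id=cell_id,
        selected=selected,
        threshold=float(threshold),
        cell_mean=mean,
        cell_sd=sd,
        n_cell_px=n,
    )


_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def label_puncta(
    selection: PixelSelection,
    params: ThresholdParams = ThresholdParams(),
) -> list[Punctum]:
    """Connected components of the selection, small components discarded.

    Components with area below ``params.min_punctum_px`` are dropped.
    Centroids are unweighted pixel-coordinate means in (row, col).
    """
    structure = _STRUCT_8 if params.connectivity == 8 else _STRUCT_4
    labeled, n_comp = ndimage.label(selection.selected, structure=structure)
    puncta: list[Punctum] = []
    if n_comp == 0:
        return puncta
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n_comp + 1))
    centroids = ndimage.center_of_mass(selection.selected, labeled, range(1, n_comp + 1))
    next_id = 1
    for area, centroid in zip(areas, centroids):
        if area >= params.min_punctum_px:
            puncta.append(Punctum(next_id, int(area), (float(centroid[0]), float(centroid[1]))))
            next_id += 1
    return puncta


def clustering_index(
    image: np.ndarray,
    mask: CellMaskSet,
    cell_id: int,
    selection: PixelSelection,
) -> float:
    """Sum of intensity over the selected pixels divided by the whole-cell mean.

    Returns 0 for an empty selection. A zero cell mean with a nonempty
    selection is degenerate (the ratio is undefined) and raises.
    """
    if selection.cell_id != cell_id:
        raise ValueError("selection was produced for a different cell")
    image = np.asarray(image, dtype=np.float64)
    total = float(image[selection.selected].sum())
    if selection.n_selected == 0:
        return 0.0
    if selection.cell_mean == 0:
        raise ZeroDivisionError("cell mean is 0 with a nonempty selection")
    return total / selection.cell_mean


def quantify_cell(
    image: np.ndarray,
    mask: CellMaskSet,
    cell_id: int,
    params: ThresholdParams = ThresholdParams(),
) -> CellQuantResult:
    """Full per-cell record: stats, selection, puncta, clustering index."""
    selection = select_aggregate_pixels(image, mask, cell_id, params)
    puncta = label_puncta(selection, params)
    image = np.asarray(image, dtype=np.float64)
    total = float(image[selection.selected].sum())
    index = clustering_index(image, mask, cell_id, selection)
    return CellQuantResult(
        cell_id=cell_id,
        cell_mean=selection.cell_mean,
        cell_sd=selection.cell_sd,
        threshold=selection.threshold,
        n_cell_px=selection.n_cell_px,
        n_selected_px=selection.n_selected,
        total_selected_intensity=total,
        clustering_index=index,
        n_puncta=len(puncta),
        punctum_areas=[p.area_px for p in puncta],
    )


def quantify_all_cells(
    image: np.ndarray,
    mask: CellMaskSet,
    params: ThresholdParams = ThresholdParams(),
) -> list[CellQuantResult]:
    """quantify_cell over every cell id present in the mask, in id order."""
    return [quantify_cell(image, mask, cid, params) for cid in mask.cell_ids()]
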