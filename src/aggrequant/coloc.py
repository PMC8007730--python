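"""Pairwise Pearson colocalization of channels within a cell mask.

Only the pixels of the cell enter the correlation; background never
influences the coefficient. No intensity pre-thresholding (Costes) and no
Manders coefficients — plain product-moment correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_io import CellMaskSet

__all__ = ["ColocResult", "pearson_coefficient", "pearson_all_cells"]


@dataclass(frozen=True)
class ColocResult:
    cell_id: int
    channel_pair: tuple[str, str]
    r: float
    n_pixels: int

    def to_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "channel_a": self.channel_pair[0],
            "channel_b": self.channel_pair[1],
            "pearson_r": self.r,
            "n_pixels": self.n_pixels,
        }


def pearson_coefficient(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: CellMaskSet,
    cell_id: int,
    channel_pair: tuple[str, str] = ("a", "b"),
) -> ColocResult:
    """Pearson correlation of two channels over one cell's pixels.

    Raises on zero variance in either channel within the cell (the
    coefficient is undefined there; NaN is never propagated).
    """
    ch_a = np.asarray(ch_a, dtype=np.float64)
    ch_b = np.asarray(ch_b, dtype=np.float64)
    if ch_a.shape != ch_b.shape:
        raise ValueError(f"channel shapes differ: {ch_a.shape} vs {ch_b.shape}")
    if ch_a.shape != mask.shape:
        raise ValueError(f"channel shape {ch_a.shape} != mask shape {mask.shape}")
    inside = mask.cell_pixels(cell_id)
    a = ch_a[inside]
    b = ch_b[inside]
    if a.size < 2:
        raise ValueError(f"cell {cell_id}: need >= 2 pixels for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError(f"cell {cell_id}: zero variance in a channel; r undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return ColocResult(cell_id=cell_id, channel_pair=channel_pair, r=r, n_pixels=int(a.size))


def pearson_all_cells(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: CellMaskSet,
    channel_pair: tuple[str, str] = ("a", "b"),
) -> list[ColocResult]:
    """Per-cell coefficients for every cell in the mask.

    A mask with a single label covering the whole field degenerates to a
    per-image coefficient, which is the intended fallback.
    """
    return [
        pearson_coefficient(ch_a, ch_b, mask, cid, channel_pair) for cid in mask.cell_ids()
    ]
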