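import numpy as np
import pytest

from aggrequant import CellMaskSet


@pytest.fixture
def hand_cell():
    """The 100-pixel worked example: 99 pixels at 10, one at 200.

    Mean 11.9, sample SD exactly 19, threshold 68.9, clustering index
    200 / 11.9.
    """
    img = np.full((10, 10), 10.0)
    img[5, 5] = 200.0
    mask = CellMaskSet(np.ones((10, 10), dtype=np.int64))
    return img, mask


@pytest.fixture
def small_cell():
    """Five-pixel cell {1, 1, 1, 1, 11}: mean 3, sample SD sqrt(20)."""
    img = np.zeros((1, 5))
    img[0] = [1, 1, 1, 1, 11]
    mask = CellMaskSet(np.ones((1, 5), dtype=np.int64))
    return img, mask


def brute_force_selection(img, cell_mask, k=3.0, sd_mode="sample", strict=True):
    """Independent per-pixel oracle for the mean + k*SD selection rule.

    Statistics by the definitional formulas (explicit sums), comparison
    pixel by pixel — no shared code with the implementation path.
    """
    values = [img[r, c] for r in range(img.shape[0]) for c in range(img.shape[1])
              if cell_mask[r, c]]
    n = len(values)
    mean = sum(values) / n
    ssd = sum((v - mean) ** 2 for v in values)
    var = ssd / (n - 1) if sd_mode == "sample" else ssd / n
    sd = var**0.5
    thr = mean + k * sd
    out = np.zeros_like(cell_mask, dtype=bool)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if cell_mask[r, c]:
                if (img[r, c] > thr) if strict else (img[r, c] >= thr):
                    out[r, c] = True
    return out, mean, sd, thr
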