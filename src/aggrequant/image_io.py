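"""Image, label-mask and table I/O plus the shared in-memory data model.

All modules share one coordinate convention: 0-based, pixel-centered,
``(row, col)`` order. Intensities are promoted to ``float64`` on read and
never normalized — every downstream index is a ratio of raw values, so the
reader must not rescale.

TIFF dialects disagree on how time frames and channels interleave across
pages; the page order is declared explicitly (``"frames-outer"`` default,
meaning pages cycle channels fastest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "MultiChannelImage",
    "CellMaskSet",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "write_table",
]


@dataclass
class MultiChannelImage:
    """A stack of co-registered grayscale channels, optionally over time.

    Parameters
    ----------
    pixels
        Intensity array of shape ``(n_channels, H, W)`` for a static image
        or ``(n_frames, n_channels, H, W)`` for a time series. Values are
        finite and non-negative, in arbitrary fluorescence units.
    channels
        Ordered channel labels, e.g. ``["GFP", "mCherry"]``.
    frame_interval_min
        Spacing of the time axis in minutes, if the image has frames.
    """

    pixels: np.ndarray
    channels: list[str]
    frame_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"pixels must be (C, H, W) or (T, C, H, W), got shape {self.pixels.shape}"
            )
        n_ch = self.pixels.shape[-3]
        if n_ch != len(self.channels):
            raise ValueError(
                f"channel count mismatch: {n_ch} planes vs {len(self.channels)} names"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def has_frames(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0] if self.has_frames else 1

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape."""
        return self.pixels.shape[-2:]

    def channel(self, name: str, frame: int | None = None) -> np.ndarray:
        """Return one channel's 2-D intensity grid.

        ``frame`` is required for multi-frame images and rejected otherwise.
        """
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        if self.has_frames:
            if frame is None:
                raise ValueError("multi-frame image: a frame index is required")
            return self.pixels[frame, idx]
        if frame not in (None, 0):
            raise ValueError("static image has no frame axis")
        return self.pixels[idx]

    def frame_times_min(self) -> np.ndarray:
        """Acquisition times in minutes, starting at 0."""
        if self.frame_interval_min is None:
            raise ValueError("frame interval not set")
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_min


@dataclass
class CellMaskSet:
    """Integer label image assigning pixels to cells; 0 is background."""

    labels: np.ndarray
    frame: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label mask must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label mask contains non-integer values")
            labels = np.round(labels).astype(np.int64)
        if np.any(labels < 0):
            raise ValueError("label mask contains negative values")
        self.labels = labels.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_ids(self) -> list[int]:
        """Sorted ids of the cells present (background excluded)."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def cell_pixels(self, cell_id: int) -> np.ndarray:
        """Boolean grid of the pixels belonging to ``cell_id``."""
        if cell_id not in self.cell_ids():
            raise KeyError(f"cell id {cell_id} not present in mask")
        return self.labels == cell_id


def read_image(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    *,
    n_frames: int | None = None,
    page_order: str = "frames-outer",
    frame_interval_min: float | None = None,
) -> MultiChannelImage:
    """Read a single- or multi-page grayscale TIFF into a MultiChannelImage.

    Pages are assigned to (frame, channel) according to ``page_order``:
    ``"frames-outer"`` (default) treats the channel index as cycling fastest,
    ``"channels-outer"`` the frame index. With ``n_frames`` unset the file is
    read as a static multi-channel image (one page per channel).

    RGB/RGBA files are rejected — the pipeline is grayscale-per-channel.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise ValueError(f"{path.name}: RGB input not supported; supply grayscale channels")
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 2-D or 3-D grayscale data, got shape {data.shape}")

    n_pages = data.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_pages if n_frames is None else n_pages // n_frames)]
    channel_names = list(channel_names)
    n_ch = len(channel_names)

    if n_frames is None:
        if n_pages != n_ch:
            raise ValueError(
                f"{path.name}: channel count mismatch: {n_pages} pages vs {n_ch} channel names"
            )
        pixels = data.astype(np.float64)
    else:
        if n_pages != n_frames * n_ch:
            raise ValueError(
                f"{path.name}: {n_pages} pages cannot hold {n_frames} frames x {n_ch} channels"
            )
        if page_order == "frames-outer":
            pixels = data.reshape(n_frames, n_ch, *data.shape[1:]).astype(np.float64)
        elif page_order == "channels-outer":
            pixels = (
                data.reshape(n_ch, n_frames, *data.shape[1:]).transpose(1, 0, 2, 3).astype(np.float64)
            )
        else:
            raise ValueError(f"unknown page_order {page_order!r}")
    return MultiChannelImage(pixels, channel_names, frame_interval_min=frame_interval_min)


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write all planes as a multi-page float TIFF (frames-outer page order)."""
    data = image.pixels
    if image.has_frames:
        data = data.reshape(-1, *data.shape[-2:])
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_label_mask(path: str | Path) -> CellMaskSet:
    """Read an integer-valued grayscale TIFF as a cell label mask.

    An all-zero mask is valid but logged as a warning, since every
    downstream per-cell computation will be a no-op on it.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path.name}: label mask must be a single 2-D page")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path.name}: label mask contains fractional values")
        data = np.round(data).astype(np.int64)
    mask = CellMaskSet(data)
    if not mask.cell_ids():
        logger.warning("%s: mask contains no cells (all background)", path.name)
    return mask


def write_label_mask(mask: CellMaskSet, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.labels.astype(np.int32), photometric="minisblack")


def write_table(records: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write result records (dataclasses, dicts, or a DataFrame) to CSV.

    Comma-separated, header row, UTF-8; floats at full ``repr`` precision so
    a read-back reproduces the values exactly. ``columns`` supplies the
    schema when ``records`` is empty (header-only output).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "to_row"):
                rows.append(rec.to_row())
            elif hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows, columns=list(columns) if columns is not None else None)
    df.to_csv(Path(path), index=False, encoding="utf-8")
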