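"""Aggregation-index trajectories for tracked cells in time-lapse movies.

Each frame is scored independently with the static per-cell pipeline (no
temporal smoothing), so a trajectory is just the clustering index of one
cell evaluated frame by frame — the ratio form of the index gives
first-order robustness to multiplicative photobleaching. Cell identity over
time comes from the supplied per-frame masks; no tracking is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import CellMaskSet, MultiChannelImage
from .quant import ThresholdParams, quantify_cell

logger = logging.getLogger(__name__)

__all__ = ["IndexTrajectory", "GroupTrajectory", "aggregation_trajectory", "group_mean_trajectory"]


@dataclass
class IndexTrajectory:
    """Aggregation index of one cell across frames; times in minutes."""

    cell_id: int
    times_min: np.ndarray
    indexes: np.ndarray
    params: ThresholdParams

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        self.indexes = np.asarray(self.indexes, dtype=np.float64)
        if len(self.times_min) != len(self.indexes):
            raise ValueError("times and indexes differ in length")
        if len(self.times_min) > 1 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GroupTrajectory:
    """Pointwise mean +/- SEM of a group of per-cell trajectories."""

    group: str
    times_min: np.ndarray
    mean_index: np.ndarray
    sem_index: np.ndarray
    n_cells: int


def aggregation_trajectory(
    frames: MultiChannelImage,
    masks: list[CellMaskSet],
    cell_id: int,
    channel: str,
    params: ThresholdParams = ThresholdParams(),
) -> IndexTrajectory:
    """Score one cell's aggregation index in every frame of a movie.

    If the cell disappears from a frame's mask the trajectory is truncated
    at the last continuous frame, with a warning.
    """
    if not frames.has_frames:
        raise ValueError("a multi-frame image is required")
    if len(masks) != frames.n_frames:
        raise ValueError(f"{len(masks)} masks for {frames.n_frames} frames")
    times = frames.frame_times_min()
    indexes = []
    for t in range(frames.n_frames):
        if cell_id not in masks[t].cell_ids():
            logger.warning(
                "cell %d missing from frame %d; trajectory truncated at frame %d",
                cell_id, t, t - 1,
            )
            break
        result = quantify_cell(frames.channel(channel, frame=t), masks[t], cell_id, params)
        indexes.append(result.clustering_index)
    if not indexes:
        raise ValueError(f"cell {cell_id} absent from the first frame")
    return IndexTrajectory(
        cell_id=cell_id,
        times_min=times[: len(indexes)],
        indexes=np.asarray(indexes),
        params=params,
    )


def group_mean_trajectory(
    trajectories: list[IndexTrajectory],
    group: str = "",
) -> GroupTrajectory:
    """Pointwise mean and SEM (sample SD / sqrt(n)) over cells.

    All trajectories must share the same time grid (resample to a common
    grid beforehand if they do not). A single-cell group gets SEM 0 by
    convention, with a warning.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    times = trajectories[0].times_min
    for traj in trajectories[1:]:
        if not np.array_equal(traj.times_min, times):
            raise ValueError("trajectories are on different time grids")
    stack = np.vstack([t.indexes for t in trajectories])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n == 1:
        logger.warning("group %r has a single cell; SEM reported as 0", group)
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return GroupTrajectory(group=group, times_min=times, mean_index=mean, sem_index=sem, n_cells=n)
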