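"""Touch-evoked escape-response scoring for tadpoles swimming in round wells.

A trial is the (t, x, y) track of one animal for 3 s after a tail touch.
Three categories, mirroring how such assays are scored by eye:

* ``normal`` — the animal swims to the edge of the well within 3 s,
  operationalized as max radial distance from the well center reaching
  ``(1 - edge_tol) * radius`` (a finite-size animal cannot touch the wall
  exactly);
* ``none`` — the animal fails to move forward at all: total path length
  below ``move_tol * radius``;
* ``reduced`` — everything in between (in particular any swim shorter
  than the well radius).

Each animal is touched up to three times and the best of the three trials
is recorded (normal > reduced > none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "CATEGORIES",
    "classify_trial",
    "best_of_trials",
    "tabulate_responses",
    "load_trajectories",
]

#: Response categories, best first.
CATEGORIES = ("normal", "reduced", "none")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

RESPONSE_WINDOW_S = 3.0


@dataclass
class Trajectory:
    """One trial's track: (t_s, x, y) samples plus the well geometry.

    t = 0 is the touch; samples must be strictly increasing in time.
    Samples after the 3 s response window are ignored by the classifier.
    """

    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    well_center: tuple[float, float]
    well_radius: float
    animal_id: str = ""
    group: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.t_s) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.t_s[0] < 0 or not np.all(np.diff(self.t_s) > 0):
            raise ValueError("times must start at the touch (t >= 0) and strictly increase")
        if self.well_radius <= 0:
            raise ValueError("well radius must be positive")


def classify_trial(
    traj: Trajectory,
    edge_tol: float = 0.05,
    move_tol: float = 0.02,
) -> str:
    """Classify one trial as ``"normal"``, ``"reduced"`` or ``"none"``."""
    if not 0 < move_tol < edge_tol:
        raise ValueError("need 0 < move_tol < edge_tol")
    keep = traj.t_s <= RESPONSE_WINDOW_S
    x = traj.x[keep] - traj.well_center[0]
    y = traj.y[keep] - traj.well_center[1]
    if len(x) < 2:
        raise ValueError("no samples inside the 3 s response window")
    radial = np.hypot(x, y)
    path_len = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    if radial.max() >= (1.0 - edge_tol) * traj.well_radius:
        return "normal"
    if path_len < move_tol * traj.well_radius:
        return "none"
    return "reduced"


def best_of_trials(categories: list[str]) -> str:
    """Best category of up to three consecutive trials (normal > reduced > none).

    Trials beyond the third are ignored with a warning.
    """
    if not categories:
        raise ValueError("no trials to score")
    for c in categories:
        if c not in _RANK:
            raise ValueError(f"unknown category {c!r}")
    if len(categories) > 3:
        logger.warning("%d trials supplied; only the first 3 are scored", len(categories))
        categories = categories[:3]
    return min(categories, key=_RANK.__getitem__)


def tabulate_responses(per_animal: dict[str, list[str]]) -> pd.DataFrame:
    """Contingency table of per-animal categories by group.

    ``per_animal`` maps group label -> list of per-animal (best-of-trials)
    categories. Returns one row per group with counts, percentages and the
    group size; row counts always sum to the group size.
    """
    rows = []
    for group, cats in per_animal.items():
        counts = {c: 0 for c in CATEGORIES}
        for c in cats:
            if c not in counts:
                raise ValueError(f"unknown category {c!r}")
            counts[c] += 1
        n = len(cats)
        row = {"group": group, "n": n}
        for c in CATEGORIES:
            row[c] = counts[c]
        for c in CATEGORIES:
            row[f"pct_{c}"] = 100.0 * counts[c] / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def load_trajectories(
    track_csv: str,
    wells_csv: str,
) -> list[Trajectory]:
    """Read trial tracks and well geometry from the two-file CSV layout.

    ``track_csv`` columns: animal_id, group, trial, t_s, x, y.
    ``wells_csv`` columns: animal_id, cx, cy, radius.
    """
    tracks = pd.read_csv(track_csv)
    wells = pd.read_csv(wells_csv).set_index("animal_id")
    out = []
    for (animal, group, trial), sub in tracks.groupby(["animal_id", "group", "trial"], sort=True):
        if animal not in wells.index:
            raise KeyError(f"no well geometry for animal {animal!r}")
        w = wells.loc[animal]
        sub = sub.sort_values("t_s")
        out.append(
            Trajectory(
                t_s=sub["t_s"].to_numpy(),
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                well_center=(float(w["cx"]), float(w["cy"])),
                well_radius=float(w["radius"]),
                animal_id=str(animal),
                group=str(group),
                trial=int(trial),
            )
        )
    return out
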