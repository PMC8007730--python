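"""Synthetic microscopy, behavior and survival data with ground truth.

Every pipeline stage is exercised on generated inputs whose truth is known
by construction, so recovery can be measured without any real recordings:

* single-cell fields — a disk-shaped cell over a uniform background with
  isotropic Gaussian puncta (truncated at 3 radii) and additive Gaussian
  read noise. SNR is punctum amplitude / noise sigma.
* time-lapse series — puncta nucleate, grow, coalesce (center-distance
  mass merging) and optionally clear, frame by frame.
* PLA scenes — disk nuclei in a nuclear-stain channel plus
  diffraction-limited Gaussian dots in a signal channel.
* escape trajectories — tracks constructed to be normal / reduced /
  non-responders by the classifier's own definitions.
* event tables — exponential burst times with chosen group medians,
  right-censored at the end of imaging.

Every generator is a pure function of its spec: the seed fixes all
randomness, and the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import CellMaskSet, MultiChannelImage
from .survival_stats import EventTable

__all__ = [
    "SceneSpec",
    "TimelapseSpec",
    "BehaviorSpec",
    "generate_cell_image",
    "generate_timelapse",
    "generate_pla_scene",
    "generate_trajectories",
    "generate_event_times",
]


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic single-cell field.

    The defaults emulate a transfected cultured cell imaged at moderate
    SNR: a disk cell of radius 40 px on a 128 x 128 field, uniform
    background 100 AU, read-noise sigma 5 AU, and 5 bright puncta of
    2 px radius and amplitude 50 AU above background (SNR 10).
    """

    shape: tuple[int, int] = (128, 128)
    cells: tuple[tuple[float, float, float], ...] = ((64.0, 64.0, 40.0),)  # (row, col, radius)
    background: float = 100.0
    noise_sigma: float = 5.0
    n_puncta: int = 5
    punctum_radius: float = 2.0
    punctum_amplitude: float = 50.0
    min_spacing: float | None = None  # default 4 * punctum_radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.punctum_amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")


@dataclass(frozen=True)
class TimelapseSpec:
    """Punctum dynamics layered on a base scene.

    Per frame: every punctum's amplitude grows by ``growth_per_frame`` AU
    then loses a ``clearance_rate`` fraction; ``nucleation_rate`` new
    puncta appear (Poisson); puncta whose centers lie within
    ``coalescence_dist`` px merge, summing their mass. ``clearance_rate``
    0 reproduces monotone growth.
    """

    base: SceneSpec = SceneSpec()
    n_frames: int = 24
    frame_interval_min: float = 15.0
    nucleation_rate: float = 0.0
    growth_per_frame: float = 2.0
    coalescence_dist: float = 3.0
    clearance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nucleation_rate", "growth_per_frame", "clearance_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.clearance_rate <= 1:
            raise ValueError("clearance_rate is a per-frame fraction in [0, 1]")


@dataclass(frozen=True)
class BehaviorSpec:
    """Escape-trajectory cohort: per-group category proportions.

    Proportions are (normal, reduced, none) and must sum to 1 per group.
    Tracks are sampled at 10 Hz over the 3 s response window in a well of
    radius 10 length units centered at the origin.
    """

    groups: dict = field(default_factory=lambda: {"control": (0.8, 0.15, 0.05)})
    n_animals: int = 30
    trials_per_animal: int = 3
    well_radius: float = 10.0
    well_center: tuple[float, float] = (0.0, 0.0)
    sample_hz: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, props in self.groups.items():
            if len(props) != 3 or abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"group {g!r}: proportions must be 3 values summing to 1")


def _render_puncta(img: np.ndarray, puncta: pd.DataFrame) -> None:
    """Add truncated Gaussian punctum profiles to ``img`` in place."""
    h, w = img.shape
    for p in puncta.itertuples():
        r0, c0, rad, amp = p.row, p.col, p.radius, p.amplitude
        lo_r = max(0, int(np.floor(r0 - 3 * rad)))
        hi_r = min(h, int(np.ceil(r0 + 3 * rad)) + 1)
        lo_c = max(0, int(np.floor(c0 - 3 * rad)))
        hi_c = min(w, int(np.ceil(c0 + 3 * rad)) + 1)
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        profile = amp * np.exp(-d2 / (2 * rad**2))
        profile[d2 > (3 * rad) ** 2] = 0.0
        img[lo_r:hi_r, lo_c:hi_c] += profile


def _disk_mask(shape: tuple[int, int], cells) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int64)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (r0, c0, rad) in enumerate(cells, start=1):
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = i
    return labels


def _place_points(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    max_radius: float,
    min_spacing: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample ``n`` points in a disk with a pairwise spacing floor."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} puncta with spacing {min_spacing} after {max_tries} tries"
            )
        tries += 1
        theta = rng.uniform(0, 2 * np.pi)
        rad = max_radius * np.sqrt(rng.uniform())
        cand = (center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_spacing for p in pts):
            pts.append(cand)
    return np.asarray(pts).reshape(n, 2)


def generate_cell_image(
    spec: SceneSpec,
) -> tuple[MultiChannelImage, CellMaskSet, pd.DataFrame]:
    """Render a single-channel field with disk cells and Gaussian puncta.

    Returns the image (channel ``"GFP"``), the exact cell mask, and a
    truth table with one row per punctum (cell_id, row, col, radius,
    amplitude). Puncta are placed uniformly inside their cell, at least
    3 radii from the cell edge, with pairwise spacing of at least
    ``min_spacing`` (default 4 radii).
    """
    rng = np.random.default_rng(spec.seed)
    spacing = 4 * spec.punctum_radius if spec.min_spacing is None else spec.min_spacing
    rows = []
    for cell_id, (r0, c0, cell_rad) in enumerate(spec.cells, start=1):
        margin = 3 * spec.punctum_radius
        pts = _place_points(rng, spec.n_puncta, (r0, c0), cell_rad - margin, spacing)
        for row, col in pts:
            rows.append(
                {"cell_id": cell_id, "row": row, "col": col,
                 "radius": spec.punctum_radius, "amplitude": spec.punctum_amplitude}
            )
    truth = pd.DataFrame(rows, columns=["cell_id", "row", "col", "radius", "amplitude"])

    img = np.full(spec.shape, spec.background, dtype=np.float64)
    _render_puncta(img, truth)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    np.clip(img, 0.0, None, out=img)
    image = MultiChannelImage(img[None, ...], ["GFP"])
    mask = CellMaskSet(_disk_mask(spec.shape, spec.cells))
    return image, mask, truth


def _coalesce(puncta: list[dict], dist: float) -> list[dict]:
    """Merge puncta whose centers are within ``dist``: masses add, the
    center is mass-weighted, the radius is the larger of the pair."""
    merged = True
    puncta = [dict(p) for p in puncta]
    while merged:
        merged = False
        for i in range(len(puncta)):
            for j in range(i + 1, len(puncta)):
                a, b = puncta[i], puncta[j]
                if np.hypot(a["row"] - b["row"], a["col"] - b["col"]) <= dist:
                    mass_a = a["amplitude"] * a["radius"] ** 2
                    mass_b = b["amplitude"] * b["radius"] ** 2
                    rad = max(a["radius"], b["radius"])
                    total = mass_a + mass_b
                    puncta[i] = {
                        "row": (a["row"] * mass_a + b["row"] * mass_b) / total,
                        "col": (a["col"] * mass_a + b["col"] * mass_b) / total,
                        "radius": rad,
                        "amplitude": total / rad**2,
                    }
                    del puncta[j]
                    merged = True
                    break
            if merged:
                break
    return puncta


def generate_timelapse(
    spec: TimelapseSpec,
) -> tuple[MultiChannelImage, list[CellMaskSet], list[pd.DataFrame]]:
    """Evolve a punctum population over frames and render each frame.

    Frame 0 is the base scene's punctum set; each later frame applies, in
    order, growth, clearance, nucleation, then coalescence. Returns the
    frame stack, per-frame masks (the cell does not move), and the truth
    punctum table of every frame.
    """
    base = spec.base
    rng = np.random.default_rng(spec.seed)
    spacing = 4 * base.punctum_radius if base.min_spacing is None else base.min_spacing
    r0, c0, cell_rad = base.cells[0]
    margin = 3 * base.punctum_radius
    pts = _place_points(rng, base.n_puncta, (r0, c0), cell_rad - margin, spacing)
    puncta = [
        {"row": p[0], "col": p[1], "radius": base.punctum_radius,
         "amplitude": base.punctum_amplitude}
        for p in pts
    ]

    mask = CellMaskSet(_disk_mask(base.shape, base.cells))
    frames = []
    truths = []
    for t in range(spec.n_frames):
        truth = pd.DataFrame(puncta, columns=["row", "col", "radius", "amplitude"])
        truths.append(truth)
        img = np.full(base.shape, base.background, dtype=np.float64)
        _render_puncta(img, truth)
        if base.noise_sigma > 0:
            img += rng.normal(0.0, base.noise_sigma, size=base.shape)
        np.clip(img, 0.0, None, out=img)
        frames.append(img)

        # evolve for the next frame
        for p in puncta:
            p["amplitude"] = (p["amplitude"] + spec.growth_per_frame) * (1 - spec.clearance_rate)
        n_new = rng.poisson(spec.nucleation_rate)
        for _ in range(n_new):
            theta = rng.uniform(0, 2 * np.pi)
            rad = (cell_rad - margin) * np.sqrt(rng.uniform())
            puncta.append(
                {"row": r0 + rad * np.sin(theta), "col": c0 + rad * np.cos(theta),
                 "radius": base.punctum_radius, "amplitude": base.punctum_amplitude}
            )
        puncta = _coalesce(puncta, spec.coalescence_dist)

    stack = np.stack(frames)[:, None, :, :]
    image = MultiChannelImage(stack, ["GFP"], frame_interval_min=spec.frame_interval_min)
    return image, [mask] * spec.n_frames, truths


def generate_pla_scene(
    n_nuclei: int = 3,
    dots_per_nucleus: int = 5,
    dot_sigma: float = 2.0,
    snr: float = 20.0,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    nucleus_radius: float = 18.0,
    noise_sigma: float = 5.0,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render a two-channel PLA scene: ``"DAPI"`` nuclei and ``"RED"`` dots.

    Nuclei are disjoint disks; each receives ``dots_per_nucleus`` Gaussian
    dots of width ``dot_sigma`` and amplitude ``snr * noise_sigma``, placed
    at least ``4 * dot_sigma`` apart and well inside the nucleus. The truth
    table lists every dot's (row, col) and nucleus id.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    border = nucleus_radius + 4
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_nuclei:
        if tries > 5000:
            raise RuntimeError("could not place disjoint nuclei")
        tries += 1
        cand = (rng.uniform(border, h - border), rng.uniform(border, w - border))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= 2 * nucleus_radius + 8 for c in centers):
            centers.append(cand)

    dapi = np.full(shape, 20.0)
    rr, cc = np.mgrid[0:h, 0:w]
    for r0, c0 in centers:
        dapi[(rr - r0) ** 2 + (cc - c0) ** 2 <= nucleus_radius**2] = 200.0

    rows = []
    amplitude = snr * noise_sigma
    for nid, (r0, c0) in enumerate(centers, start=1):
        pts = _place_points(
            rng, dots_per_nucleus, (r0, c0), nucleus_radius - 2 * dot_sigma, 4 * dot_sigma
        )
        for row, col in pts:
            rows.append({"nucleus_id": nid, "row": row, "col": col,
                         "sigma": dot_sigma, "amplitude": amplitude})
    truth = pd.DataFrame(rows, columns=["nucleus_id", "row", "col", "sigma", "amplitude"])

    red = np.zeros(shape, dtype=np.float64)
    dot_profile = truth.rename(columns={"sigma": "radius"})
    _render_puncta(red, dot_profile)
    if noise_sigma > 0:
        dapi = dapi + rng.normal(0, noise_sigma, shape)
        red = red + rng.normal(0, noise_sigma, shape)
    np.clip(dapi, 0, None, out=dapi)
    np.clip(red, 0, None, out=red)
    image = MultiChannelImage(np.stack([dapi, red]), ["DAPI", "RED"])
    return image, truth


def _make_track(
    category: str,
    rng: np.random.Generator,
    spec: BehaviorSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one (t, x, y) track of the requested response category.

    Normal tracks reach 96% of the well radius before 3 s; reduced tracks
    swim outward but stop below half the radius; non-responders jitter in
    place with a vanishing path length.
    """
    n = int(round(3.0 * spec.sample_hz)) + 1
    t = np.arange(n) / spec.sample_hz
    cx, cy = spec.well_center
    R = spec.well_radius
    start_r = R * 0.3 * np.sqrt(rng.uniform())
    start_th = rng.uniform(0, 2 * np.pi)
    x0 = cx + start_r * np.cos(start_th)
    y0 = cy + start_r * np.sin(start_th)
    heading = rng.uniform(0, 2 * np.pi)

    if category == "normal":
        t_wall = rng.uniform(1.2, 2.4)
        # swim radially outward (through the start point, away from center)
        if start_r > 1e-9:
            heading = np.arctan2(y0 - cy, x0 - cx)
        target = 0.97 * R
        frac = np.clip(t / t_wall, 0, 1)
        radial = start_r + (target - start_r) * frac
        theta = np.full(n, heading)
        after = t > t_wall  # then swim around the well along the wall
        omega = rng.uniform(0.5, 1.5)
        theta[after] = heading + omega * (t[after] - t_wall)
        x = cx + radial * np.cos(theta)
        y = cy + radial * np.sin(theta)
    elif category == "reduced":
        dist = R * rng.uniform(0.15, 0.45)
        t_stop = rng.uniform(1.0, 2.5)
        frac = np.clip(t / t_stop, 0, 1)
        x = x0 + dist * frac * np.cos(heading)
        y = y0 + dist * frac * np.sin(heading)
    elif category == "none":
        jitter = 0.02 * R * 0.005  # path length stays far below move_tol * R
        x = x0 + rng.normal(0, jitter, n)
        y = y0 + rng.normal(0, jitter, n)
    else:
        raise ValueError(f"unknown category {category!r}")
    return t, x, y


def generate_trajectories(
    spec: BehaviorSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample a cohort of escape trials with known response categories.

    Each animal draws its true category from its group's proportions; all
    of its trials are generated from that category. Returns (tracks,
    wells, truth): the long-format track table (animal_id, group, trial,
    t_s, x, y), the well-geometry table, and the per-animal truth.
    """
    rng = np.random.default_rng(spec.seed)
    cats = ("normal", "reduced", "none")
    track_rows = []
    well_rows = []
    truth_rows = []
    for group, props in spec.groups.items():
        for i in range(spec.n_animals):
            animal = f"{group}_{i:03d}"
            category = cats[rng.choice(3, p=np.asarray(props, dtype=float))]
            truth_rows.append({"animal_id": animal, "group": group, "category": category})
            well_rows.append(
                {"animal_id": animal, "cx": spec.well_center[0],
                 "cy": spec.well_center[1], "radius": spec.well_radius}
            )
            for trial in range(1, spec.trials_per_animal + 1):
                t, x, y = _make_track(category, rng, spec)
                for ti, xi, yi in zip(t, x, y):
                    track_rows.append(
                        {"animal_id": animal, "group": group, "trial": trial,
                         "t_s": ti, "x": xi, "y": yi}
                    )
    tracks = pd.DataFrame(track_rows)
    wells = pd.DataFrame(well_rows)
    truth = pd.DataFrame(truth_rows)
    return tracks, wells, truth


def generate_event_times(
    group_medians: dict,
    n_per_group: int = 50,
    censor_time: float = 2880.0,
    seed: int = 0,
) -> EventTable:
    """Exponential burst times per group, right-censored at ``censor_time``.

    ``group_medians`` maps group label to the median survival time in
    minutes, or ``None`` for a group with no deaths in the observation
    window (everything censored). Defaults emulate a two-day (48 h) imaging session, long enough for a
    group with a median in the 900-1600 min range to cross 50% survival
    inside the observation window.
    """
    rng = np.random.default_rng(seed)
    subjects, groups, times, events = [], [], [], []
    for group, median in group_medians.items():
        if median is not None and median <= 0:
            raise ValueError(f"group {group!r}: median must be > 0")
        for i in range(n_per_group):
            subjects.append(f"{group}_{i:03d}")
            groups.append(group)
            if median is None:
                times.append(censor_time)
                events.append(0)
            else:
                t = rng.exponential(median / np.log(2))
                if t > censor_time:
                    times.append(censor_time)
                    events.append(0)
                else:
                    times.append(t)
                    events.append(1)
    return EventTable(
        np.asarray(subjects), np.asarray(groups), np.asarray(times), np.asarray(events)
    )
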