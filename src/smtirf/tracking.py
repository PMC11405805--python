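"""Spot detection, frame-to-frame linking, and trajectory filtering.

Detection is Laplacian-of-Gaussian blob finding with sub-pixel refinement
by intensity-weighted centroid; linking is per-frame-pair optimal bipartite
assignment under a distance gate (no gap closing, no splits/merges).
Filtering applies the standard single-particle-tracking hygiene rules:
tracks touching the movie start or end, too-short tracks, immobile tracks,
tracks near the field edge, and optionally implausibly long tracks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .trajectories import Spot, Trajectory, TrajectorySet

__all__ = [
    "FilterRules",
    "FilterAudit",
    "detect_spots",
    "link_spots",
    "filter_trajectories",
]


def detect_spots(
    stack: np.ndarray,
    radius: float,
    quality_threshold: float,
    pixel_size: float = 1.0,
) -> list[Spot]:
    """Detect bright spots in every frame of an image stack.

    The per-frame response is the scale-normalized negative LoG at scale
    ``sigma = radius / sqrt(2)`` (maximal for a Gaussian blob of the given
    radius); local maxima with response above ``quality_threshold`` are kept
    and refined to sub-pixel centroids using intensity weights in a 5x5
    window after local background subtraction.  Positions are returned in
    μm (``x`` along columns, ``y`` along rows); quality is the LoG response
    amplitude at the peak.
    """
    if stack.ndim == 2:
        stack = stack[None]
    if stack.size == 0:
        raise ValueError("empty stack")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    sigma = radius / pixel_size / math.sqrt(2.0)
    spots: list[Spot] = []
    h, w = stack.shape[1:]
    for f, frame in enumerate(stack):
        img = np.asarray(frame, dtype=float)
        response = -(sigma**2) * gaussian_laplace(img, sigma)
        peaks = peak_local_max(
            response,
            min_distance=max(1, int(round(sigma))),
            threshold_abs=quality_threshold,
            exclude_border=False,
        )
        # deterministic ordering: row-major
        order = np.lexsort((peaks[:, 1], peaks[:, 0])) if len(peaks) else []
        for r, c in peaks[order] if len(peaks) else []:
            r0, r1 = max(r - 2, 0), min(r + 3, h)
            c0, c1 = max(c - 2, 0), min(c + 3, w)
            window = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
            total = window.sum()
            if total > 0:
                rr, cc = np.mgrid[r0:r1, c0:c1]
                cy = float((window * rr).sum() / total)
                cx = float((window * cc).sum() / total)
            else:
                cy, cx = float(r), float(c)
            spots.append(
                Spot(
                    frame=f,
                    x=cx * pixel_size,
                    y=cy * pixel_size,
                    intensity=float(img[r, c]),
                    quality=float(response[r, c]),
                )
            )
    return spots


def link_spots(
    spots: list[Spot],
    max_link_distance: float = 0.5,
    frame_interval: float = 1.0,
    n_movie_frames: Optional[int] = None,
    field_width: Optional[float] = None,
    field_height: Optional[float] = None,
) -> TrajectorySet:
    """Link detections frame-to-frame into trajectories.

    For each consecutive frame pair the assignment minimizing total squared
    displacement subject to the gate ``max_link_distance`` (μm) is found by
    the Hungarian algorithm; unmatched detections end or start tracks.
    Deterministic: ties resolve by ascending spot index.
    """
    if not spots:
        return TrajectorySet(
            [], frame_interval, n_movie_frames, field_width, field_height
        )
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    frames = sorted(by_frame)
    if n_movie_frames is None:
        n_movie_frames = frames[-1] + 1

    gate2 = max_link_distance**2
    BIG = 1e12
    # active tracks: list of spot-lists; index into `active` per current spot
    finished: list[list[Spot]] = []
    active: list[list[Spot]] = [[s] for s in by_frame[frames[0]]]
    prev_frame = frames[0]
    for f in frames[1:]:
        cur = by_frame[f]
        if f != prev_frame + 1:
            finished.extend(active)
            active = [[s] for s in cur]
            prev_frame = f
            continue
        prev_pts = np.array([[t[-1].x, t[-1].y] for t in active])
        cur_pts = np.array([[s.x, s.y] for s in cur])
        n_prev, n_cur = len(active), len(cur)
        new_active: list[list[Spot]] = []
        matched_cur = set()
        if n_prev and n_cur:
            d2 = ((prev_pts[:, None, :] - cur_pts[None, :, :]) ** 2).sum(-1)
            cost = np.where(d2 <= gate2, d2, BIG)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < BIG:
                    active[i].append(cur[j])
                    new_active.append(active[i])
                    matched_cur.add(j)
                else:
                    finished.append(active[i])
            unmatched_prev = set(range(n_prev)) - set(rows.tolist())
            for i in sorted(unmatched_prev):
                finished.append(active[i])
        else:
            finished.extend(active)
        for j, s in enumerate(cur):
            if j not in matched_cur:
                new_active.append([s])
        active = new_active
        prev_frame = f
    finished.extend(active)

    # stable track IDs: sort by (start frame, x, y) of the first detection
    finished.sort(key=lambda t: (t[0].frame, t[0].x, t[0].y))
    trajectories = [
        Trajectory(
            id=i,
            frames=np.array([s.frame for s in t]),
            x=np.array([s.x for s in t]),
            y=np.array([s.y for s in t]),
            frame_interval=frame_interval,
        )
        for i, t in enumerate(finished)
    ]
    return TrajectorySet(
        trajectories, frame_interval, n_movie_frames, field_width, field_height
    )


@dataclass
class FilterRules:
    """The trajectory hygiene rules applied before dwell/diffusion analysis.

    - ``drop_first_frame_starts``: remove tracks that begin in frame 0
      (their binding time — hence dwell start — is unobserved).
    - ``drop_last_frame_ends``: remove tracks present in the final frame
      (their unbinding is unobserved).
    - ``min_frames``: minimum detections per track (default 3: tracks of
      <= 2 detections are removed).
    - ``min_total_displacement``: tracks whose maximum excursion from their
      start falls below this (μm; default 0.1) are removed as immobilized
      particles stuck to the substrate.
    - ``edge_margin``: tracks with any point within this distance (μm) of
      the field border are removed (requires field size on the set).
    - ``max_duration``: optional cap (s) to drop singular extra-long tracks.
    """

    drop_first_frame_starts: bool = True
    drop_last_frame_ends: bool = True
    min_frames: int = 3
    min_total_displacement: float = 0.1
    edge_margin: float = 1.0
    max_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.min_total_displacement < 0:
            raise ValueError("min_total_displacement must be >= 0")


RULE_NAMES = (
    "first_frame_start",
    "last_frame_end",
    "too_short",
    "immobile",
    "edge",
    "too_long",
)


@dataclass
class FilterAudit:
    """Per-rule removal counts from one filtering pass."""

    n_input: int
    n_kept: int
    removed: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _violations(traj: Trajectory, rules: FilterRules, tset: TrajectorySet) -> list[str]:
    v = []
    if rules.drop_first_frame_starts and traj.start_frame == 0:
        v.append("first_frame_start")
    if (
        rules.drop_last_frame_ends
        and tset.n_movie_frames is not None
        and traj.end_frame >= tset.n_movie_frames - 1
    ):
        v.append("last_frame_end")
    if len(traj) < rules.min_frames:
        v.append("too_short")
    if traj.max_displacement() < rules.min_total_displacement:
        v.append("immobile")
    if (
        rules.edge_margin > 0
        and tset.field_width is not None
        and tset.field_height is not None
    ):
        m = rules.edge_margin
        if (
            traj.x.min() < m
            or traj.y.min() < m
            or traj.x.max() > tset.field_width - m
            or traj.y.max() > tset.field_height - m
        ):
            v.append("edge")
    if rules.max_duration is not None and traj.duration > rules.max_duration:
        v.append("too_long")
    return v


def filter_trajectories(
    tset: TrajectorySet, rules: Optional[FilterRules] = None
) -> tuple[TrajectorySet, FilterAudit]:
    """Apply the hygiene rules; return survivors and a per-rule audit.

    A track violating several rules is counted under each; it is removed
    once.  Filtering is idempotent.
    """
    if rules is None:
        rules = FilterRules()
    kept = []
    counts = {name: 0 for name in RULE_NAMES}
    for traj in tset:
        v = _violations(traj, rules, tset)
        if v:
            for name in v:
                counts[name] += 1
        else:
            kept.append(traj)
    out = TrajectorySet(
        kept,
        frame_interval=tset.frame_interval,
        n_movie_frames=tset.n_movie_frames,
        field_width=tset.field_width,
        field_height=tset.field_height,
    )
    return out, FilterAudit(n_input=len(tset), n_kept=len(kept), removed=counts)
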