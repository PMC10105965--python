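"""Object-exploration bout detection and novel-place-recognition scoring.

A frame counts as exploratory toward an object when the head is within the
proximity radius (2 cm) of the object and oriented toward it (bearing within
a configurable cone).  The analysis clock starts when the animal first
leaves the arena corner zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BehaviorTrack",
    "ExplorationBout",
    "RecognitionScore",
    "detect_bouts",
    "recognition_score",
    "group_behavior_compare",
]

ARENA_SIDE_CM = 45.0
PROXIMITY_CM = 2.0
ORIENTATION_HALF_ANGLE_DEG = 45.0
MIN_BOUT_S = 0.25
CORNER_ZONE_CM = 10.0


@dataclass
class BehaviorTrack:
    """20 Hz head pose plus arena/object geometry for one session phase."""

    time: np.ndarray  # s
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    heading_deg: np.ndarray  # [0, 360)
    objects: dict  # {"A": (x, y), "B": (x, y)} cm
    arena_side_cm: float = ARENA_SIDE_CM
    phase: str = "familiarization"  # {familiarization, test}
    corner_zone_cm: float = CORNER_ZONE_CM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading_deg = np.mod(np.asarray(self.heading_deg, dtype=float), 360.0)
        n = len(self.time)
        if not (len(self.x) == len(self.y) == len(self.heading_deg) == n):
            raise ValueError("pose arrays must share length with time")
        if self.phase not in ("familiarization", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        side = self.arena_side_cm
        for name, (ox, oy) in self.objects.items():
            if not (0 <= ox <= side and 0 <= oy <= side):
                raise ValueError(f"object {name} outside arena")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def in_corner(self) -> np.ndarray:
        """Boolean mask: head inside any of the four corner squares."""
        s, c = self.arena_side_cm, self.corner_zone_cm
        near_x = (self.x <= c) | (self.x >= s - c)
        near_y = (self.y <= c) | (self.y >= s - c)
        return near_x & near_y


@dataclass
class ExplorationBout:
    onset: float  # s
    offset: float  # s
    object: str  # {"A", "B"}

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("bout duration must be positive")


@dataclass
class RecognitionScore:
    """Discrimination score: (t_novel − t_familiar) / (t_novel + t_familiar)."""

    t_novel: float
    t_familiar: float
    score: float | None
    latency_to_first_bout: float | None
    excluded: bool = False
    exclusion_reason: str = ""


def _angular_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest absolute angle between two directions, in [0, 180]."""
    d = np.mod(a - b, 360.0)
    return np.minimum(d, 360.0 - d)


def analysis_start_index(track: BehaviorTrack) -> int:
    """First frame after the animal leaves the corner zones.

    If the animal never enters a corner, the clock starts at frame 0.
    """
    in_corner = track.in_corner()
    if not in_corner[0]:
        return 0
    out = np.flatnonzero(~in_corner)
    return int(out[0]) if out.size else len(in_corner)


def detect_bouts(
    track: BehaviorTrack,
    proximity_cm: float = PROXIMITY_CM,
    theta_deg: float = ORIENTATION_HALF_ANGLE_DEG,
    min_bout_s: float = MIN_BOUT_S,
    object_radius_cm: float = 0.0,
) -> list[ExplorationBout]:
    """Maximal runs of exploratory frames toward each object, time-ordered.

    A frame is exploratory toward object O iff the head-to-edge distance is
    ≤ ``proximity_cm`` and the head direction is within ``theta_deg`` of the
    bearing to O.  Frames before the analysis-clock start are ignored.
    """
    start = analysis_start_index(track)
    fs = track.fs
    min_frames = max(1, int(round(min_bout_s * fs)))
    bouts: list[ExplorationBout] = []
    dt = 1.0 / fs

    for name, (ox, oy) in track.objects.items():
        dx = ox - track.x
        dy = oy - track.y
        dist = np.hypot(dx, dy) - object_radius_cm
        bearing = np.degrees(np.arctan2(dy, dx))
        ang = _angular_difference_deg(track.heading_deg, bearing)
        exploring = (dist <= proximity_cm) & (ang <= theta_deg)
        exploring[:start] = False

        padded = np.concatenate(([False], exploring, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for i, j in zip(edges[::2], edges[1::2]):
            if j - i < min_frames:
                continue
            bouts.append(
                ExplorationBout(
                    onset=float(track.time[i]),
                    offset=float(track.time[j - 1] + dt),
                    object=name,
                )
            )
    bouts.sort(key=lambda b: b.onset)
    return bouts


def exploration_times(bouts: list[ExplorationBout]) -> dict[str, float]:
    """Total exploration time per object label."""
    totals: dict[str, float] = {}
    for b in bouts:
        totals[b.object] = totals.get(b.object, 0.0) + b.duration
    return totals


def recognition_score(
    bouts: list[ExplorationBout],
    novel_object: str,
    clock_start_s: float = 0.0,
) -> RecognitionScore:
    """Score the test phase: (t_novel − t_familiar)/(t_novel + t_familiar).

    Animals with zero total exploration are flagged excluded with no score,
    mirroring the disqualification of animals that fail to explore.
    """
    totals = exploration_times(bouts)
    t_novel = totals.get(novel_object, 0.0)
    t_familiar = sum(v for k, v in totals.items() if k != novel_object)
    total = t_novel + t_familiar
    if total == 0.0:
        return RecognitionScore(
            t_novel=0.0,
            t_familiar=0.0,
            score=None,
            latency_to_first_bout=None,
            excluded=True,
            exclusion_reason="no object exploration",
        )
    latency = min(b.onset for b in bouts) - clock_start_s
    return RecognitionScore(
        t_novel=t_novel,
        t_familiar=t_familiar,
        score=(t_novel - t_familiar) / total,
        latency_to_first_bout=latency,
    )


def group_behavior_compare(
    scores: dict[str, list[float]],
    latencies: dict[str, list[float]] | None = None,
    paired_object_times: dict[str, tuple[list[float], list[float]]] | None = None,
) -> dict:
    """Genotype comparisons of recognition behavior.

    Unpaired two-tailed t-tests on score (and latency when provided) across
    the two groups; paired t-tests on within-animal object A vs B times per
    group.  Degenerate-variance cases are flagged, not raised.
    """
    groups = sorted(scores)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for g in groups:
        if len(scores[g]) < 2:
            raise ValueError(f"group {g!r} has < 2 animals")

    def unpaired(a: list[float], b: list[float]) -> dict:
        a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
        if np.var(a_arr) == 0 and np.var(b_arr) == 0:
            if np.mean(a_arr) == np.mean(b_arr):
                return {"t": 0.0, "p": 1.0, "undefined": False}
            return {"t": None, "p": None, "undefined": True}
        t, p = stats.ttest_ind(a_arr, b_arr)
        return {"t": float(t), "p": float(p), "undefined": False}

    out: dict = {"groups": groups, "score": unpaired(scores[groups[0]], scores[groups[1]])}
    if latencies is not None:
        out["latency"] = unpaired(latencies[groups[0]], latencies[groups[1]])
    if paired_object_times is not None:
        out["paired_object_times"] = {}
        for g, (ta, tb) in paired_object_times.items():
            a_arr, b_arr = np.asarray(ta, float), np.asarray(tb, float)
            diff = a_arr - b_arr
            if np.var(diff) == 0:
                row = (
                    {"t": 0.0, "p": 1.0, "undefined": False}
                    if np.all(diff == 0)
                    else {"t": None, "p": None, "undefined": True}
                )
            else:
                t, p = stats.ttest_rel(a_arr, b_arr)
                row = {"t": float(t), "p": float(p), "undefined": False}
            out["paired_object_times"][g] = row
    return out
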