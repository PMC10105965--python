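"""Peri-event analysis: time-lock ΔF/F to exploration bouts and quantify
MS–DG coupling via Pearson correlation of per-bout responses."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from septodg.behavior import BehaviorTrack, ExplorationBout
from septodg.photometry import DffTrace

log = logging.getLogger(__name__)

__all__ = [
    "PeriEventMatrix",
    "CouplingResult",
    "align_timebases",
    "snap_to_samples",
    "build_perievent",
    "bout_response",
    "coupling",
]

DEFAULT_WINDOW = (-2.0, 4.0)  # s relative to bout onset


@dataclass
class PeriEventMatrix:
    """Trial (bout) × timepoint ΔF/F matrix on a shared peri-onset window.

    Row length uses an inclusive grid: n = round((post − pre)·fs) + 1.
    """

    matrix: np.ndarray  # (n_bouts, n_timepoints), unscaled ΔF/F
    window: tuple[float, float]  # (pre, post) s
    rel_time: np.ndarray  # s relative to onset
    bouts: list[ExplorationBout]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.bouts):
            raise ValueError("one row per bout required")
        onsets = [b.onset for b in self.bouts]
        if onsets != sorted(onsets):
            raise ValueError("rows must be ordered by bout onset")

    def average(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def scaled(self, method: str = "minmax") -> np.ndarray:
        """Per-row scaling for heat-map display (never used for statistics)."""
        m = self.matrix
        if method == "minmax":
            lo = m.min(axis=1, keepdims=True)
            hi = m.max(axis=1, keepdims=True)
            rng = np.where(hi > lo, hi - lo, 1.0)
            return (m - lo) / rng
        if method == "zscore":
            mu = m.mean(axis=1, keepdims=True)
            sd = m.std(axis=1, keepdims=True)
            return (m - mu) / np.where(sd > 0, sd, 1.0)
        raise ValueError(f"unknown scaling {method!r}")


@dataclass
class CouplingResult:
    dg_responses: np.ndarray
    ms_responses: np.ndarray
    r: float | None
    p: float | None
    n: int
    undefined: bool = False
    reason: str = ""


def snap_to_samples(times_s: np.ndarray, trace: DffTrace) -> np.ndarray:
    """Snap event times onto the photometry sample grid (nearest sample).

    Maximum snapping error is half a photometry sample (50 ms at 10 Hz).
    """
    t = np.asarray(times_s, dtype=float)
    idx = np.clip(
        np.round((t - trace.time[0]) * trace.fs).astype(int), 0, len(trace.time) - 1
    )
    return trace.time[idx]


def align_timebases(
    photo: DffTrace, track: BehaviorTrack, bouts: list[ExplorationBout]
) -> list[ExplorationBout]:
    """Snap behavior bout boundaries onto the photometry time base.

    The 20 Hz behavior clock is downsampled 2:1 onto the 10 Hz photometry
    grid by nearest-sample assignment.
    """
    t0 = max(photo.time[0], track.time[0])
    t1 = min(photo.time[-1], track.time[-1])
    if t1 <= t0:
        raise ValueError("photometry and behavior recordings do not overlap")
    out = []
    for b in bouts:
        onset, offset = snap_to_samples(np.array([b.onset, b.offset]), photo)
        if offset <= onset:
            offset = onset + 1.0 / photo.fs
        out.append(ExplorationBout(onset=float(onset), offset=float(offset), object=b.object))
    return out


def build_perievent(
    dff: DffTrace,
    bouts: list[ExplorationBout],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> PeriEventMatrix:
    """One matrix row per bout, on an inclusive peri-onset sample grid.

    Bouts whose window extends beyond the trace are dropped and logged.
    """
    pre, post = window
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    fs = dff.fs
    n = int(round((post - pre) * fs)) + 1
    rel = pre + np.arange(n) / fs

    rows, kept = [], []
    for b in sorted(bouts, key=lambda b: b.onset):
        i0 = int(round((b.onset + pre - dff.time[0]) * fs))
        if i0 < 0 or i0 + n > len(dff.dff):
            log.info("dropping bout at %.2f s: window outside trace", b.onset)
            continue
        rows.append(dff.dff[i0 : i0 + n])
        kept.append(b)
    if not rows:
        raise ValueError("zero retained bouts")
    return PeriEventMatrix(matrix=np.vstack(rows), window=window, rel_time=rel, bouts=kept)


def bout_response(
    row: np.ndarray,
    rel_time: np.ndarray,
    bout_duration_s: float,
    baseline: bool = True,
) -> float:
    """Scalar response: mean ΔF/F during the bout, baseline-subtracted.

    Baseline is the mean over the pre-onset part of the window; set
    ``baseline=False`` for the raw during-bout mean.
    """
    during = (rel_time >= 0) & (rel_time < bout_duration_s)
    if not during.any():
        raise ValueError("empty bout interval within window")
    resp = float(np.mean(row[during]))
    if baseline:
        pre = rel_time < 0
        if pre.any():
            resp -= float(np.mean(row[pre]))
    return resp


def bout_responses(
    mat: PeriEventMatrix, baseline: bool = True
) -> np.ndarray:
    """Per-bout response scalars for a whole peri-event matrix."""
    return np.array(
        [
            bout_response(row, mat.rel_time, b.duration, baseline=baseline)
            for row, b in zip(mat.matrix, mat.bouts)
        ]
    )


def coupling(dg_responses: np.ndarray, ms_responses: np.ndarray) -> CouplingResult:
    """Pearson correlation of paired per-bout responses at the two sites.

    Pairs with missing data (NaN) in either site are dropped pairwise.
    Zero variance in either vector yields an explicitly undefined result.
    """
    dg = np.asarray(dg_responses, dtype=float)
    ms = np.asarray(ms_responses, dtype=float)
    if len(dg) != len(ms):
        raise ValueError("responses must be paired (equal length)")
    ok = np.isfinite(dg) & np.isfinite(ms)
    dg, ms = dg[ok], ms[ok]
    n = len(dg)
    if n < 3:
        raise ValueError("need at least 3 paired bouts")
    if np.var(dg) == 0 or np.var(ms) == 0:
        return CouplingResult(
            dg_responses=dg, ms_responses=ms, r=None, p=None, n=n,
            undefined=True, reason="zero variance in one site's responses",
        )
    r, p = stats.pearsonr(dg, ms)
    return CouplingResult(
        dg_responses=dg, ms_responses=ms, r=float(r), p=float(p), n=n
    )
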