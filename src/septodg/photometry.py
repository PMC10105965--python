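"""Fiber-photometry analysis: ΔF/F, motion control, and calcium-event detection.

ΔF/F is (F − F0)/F0 with F0 the session median; the event threshold is
3 × the sample SD of ΔF/F.  Motion control regresses the control-fluorophore
(mCherry) ΔF/F out of the activity (GCaMP) ΔF/F.  Events are maximal
contiguous suprathreshold excursions with a minimum-duration filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PhotometrySession",
    "DffTrace",
    "CalciumEventSet",
    "extract_channels",
    "compute_dff",
    "motion_correct",
    "detect_events",
    "session_activity",
]

#: default emission integration bands, nm
GCAMP_BAND = (500.0, 540.0)
MCHERRY_BAND = (580.0, 620.0)

THRESHOLD_MULTIPLIER = 3.0


@dataclass
class PhotometrySession:
    """Dual-channel fluorescence time series from one recording site."""

    time: np.ndarray  # s, 10 Hz
    f_gcamp: np.ndarray  # a.u.
    f_mcherry: np.ndarray  # a.u.
    site: str = "DG"  # {DG, MS}
    animal_id: str = ""
    genotype: str = "WT"  # {WT, AD}
    context: str = "homecage"  # {homecage, arena}

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_gcamp = np.asarray(self.f_gcamp, dtype=float)
        self.f_mcherry = np.asarray(self.f_mcherry, dtype=float)
        if not (len(self.time) == len(self.f_gcamp) == len(self.f_mcherry)):
            raise ValueError("time and channel arrays must have equal length")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name, arr in (("f_gcamp", self.f_gcamp), ("f_mcherry", self.f_mcherry)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative fluorescence")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.fs


@dataclass
class DffTrace:
    """ΔF/F trace with its baseline, dispersion, and event threshold."""

    time: np.ndarray  # s
    dff: np.ndarray  # dimensionless
    f0: float  # a.u.
    sd: float = field(default=0.0)
    threshold: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.time) != len(self.dff):
            raise ValueError("time and dff must have equal length")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class CalciumEventSet:
    """Suprathreshold calcium events and per-session activity statistics."""

    onsets: np.ndarray  # s
    offsets: np.ndarray  # s
    peaks: np.ndarray  # ΔF/F per event
    count: int
    rate_per_min: float  # events/min
    auc: float  # suprathreshold area, ΔF/F·s
    suprathreshold_fraction: float  # fraction of samples above threshold
    duration_s: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if np.any(self.offsets <= self.onsets):
            raise ValueError("event offsets must exceed onsets")
        if len(self.onsets) > 1 and np.any(self.onsets[1:] < self.offsets[:-1]):
            raise ValueError("events must be non-overlapping and time ordered")


def extract_channels(
    wavelengths_nm: np.ndarray,
    spectra: np.ndarray,
    gcamp_band: tuple[float, float] = GCAMP_BAND,
    mcherry_band: tuple[float, float] = MCHERRY_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate per-timepoint emission spectra over the two emission bands.

    Parameters
    ----------
    wavelengths_nm
        Monotonic wavelength grid, shape (W,).
    spectra
        Per-timepoint spectra, shape (T, W).

    Returns
    -------
    (f_gcamp, f_mcherry)
        Band-integrated fluorescence per timepoint (trapezoidal quadrature).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    spec = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spec.shape[1] != len(wl):
        raise ValueError("spectra second axis must match wavelength grid")
    for lo, hi in (gcamp_band, mcherry_band):
        if lo >= hi:
            raise ValueError("band must be (low, high) with low < high")
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError(f"band ({lo}, {hi}) nm outside wavelength grid")

    def band_integral(lo: float, hi: float) -> np.ndarray:
        sel = (wl >= lo) & (wl <= hi)
        return np.trapezoid(spec[:, sel], wl[sel], axis=1)

    return band_integral(*gcamp_band), band_integral(*mcherry_band)


def compute_dff(f: np.ndarray, time: np.ndarray | None = None) -> DffTrace:
    """ΔF/F = (F − F0)/F0 with F0 the median of the whole-session signal.

    The trace's ``sd`` is the sample SD of ΔF/F and ``threshold`` is 3 × sd.
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 samples")
    f0 = float(np.median(f))
    if f0 <= 0:
        raise ValueError("non-positive median fluorescence: degenerate input")
    dff = (f - f0) / f0
    sd = float(np.std(dff, ddof=1))
    if time is None:
        time = np.arange(f.size) / 10.0
    return DffTrace(time=time, dff=dff, f0=f0, sd=sd, threshold=THRESHOLD_MULTIPLIER * sd)


def motion_correct(dff_gcamp: DffTrace, dff_mcherry: DffTrace) -> DffTrace:
    """Subtract the mCherry-predicted component from the GCaMP ΔF/F.

    Ordinary least squares fits ``dff_gcamp ≈ a·dff_mcherry + b``; the
    corrected trace is ``dff_gcamp − a·dff_mcherry`` and therefore has zero
    sample correlation with the control channel.  SD and threshold are
    recomputed on the corrected trace.  A zero-variance control channel skips
    correction with a warning.
    """
    if len(dff_gcamp.dff) != len(dff_mcherry.dff):
        raise ValueError("traces must have equal length")
    if not np.allclose(dff_gcamp.time, dff_mcherry.time):
        raise ValueError("traces must share a time base")
    x = dff_mcherry.dff
    y = dff_gcamp.dff
    if np.var(x) == 0.0:
        warnings.warn("zero-variance mCherry trace; motion correction skipped")
        log.warning("motion correction skipped: control channel has zero variance")
        return DffTrace(
            time=dff_gcamp.time.copy(),
            dff=y.copy(),
            f0=dff_gcamp.f0,
            sd=dff_gcamp.sd,
            threshold=dff_gcamp.threshold,
        )
    a, _b = np.polyfit(x, y, 1)
    corrected = y - a * x
    sd = float(np.std(corrected, ddof=1))
    return DffTrace(
        time=dff_gcamp.time.copy(),
        dff=corrected,
        f0=dff_gcamp.f0,
        sd=sd,
        threshold=THRESHOLD_MULTIPLIER * sd,
    )


def _suprathreshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs [i, j) of consecutive True samples."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    dff: DffTrace, min_duration_s: float = 0.2, merge_gap_s: float = 0.2
) -> CalciumEventSet:
    """Detect calcium events as contiguous runs of ΔF/F > threshold.

    Runs separated by less than ``merge_gap_s`` are treated as one event
    (noise can briefly split a transient at its threshold crossing); merged
    runs shorter than ``min_duration_s`` are discarded.  AUC is the
    rectangle-rule integral of (ΔF/F − threshold)+ over the whole trace;
    the suprathreshold fraction is the fraction of samples above threshold.
    """
    if len(dff.dff) == 0:
        raise ValueError("empty trace")
    dt = 1.0 / dff.fs
    above = dff.dff > dff.threshold
    min_samples = max(1, int(round(min_duration_s * dff.fs)))
    gap_samples = int(round(merge_gap_s * dff.fs))

    merged: list[list[int]] = []
    for i, j in _suprathreshold_runs(above):
        if merged and i - merged[-1][1] <= gap_samples:
            merged[-1][1] = j
            continue
        merged.append([i, j])

    onsets, offsets, peaks = [], [], []
    for i, j in merged:
        if j - i < min_samples:
            continue
        onsets.append(dff.time[i])
        # offset = end of the last suprathreshold sample
        offsets.append(dff.time[j - 1] + dt)
        peaks.append(float(np.max(dff.dff[i:j])))

    duration = len(dff.dff) * dt
    auc = float(np.sum(np.clip(dff.dff - dff.threshold, 0.0, None)) * dt)
    count = len(onsets)
    return CalciumEventSet(
        onsets=np.array(onsets),
        offsets=np.array(offsets),
        peaks=np.array(peaks),
        count=count,
        rate_per_min=count / (duration / 60.0),
        auc=auc,
        suprathreshold_fraction=float(np.mean(above)),
        duration_s=duration,
    )


def session_activity(events: CalciumEventSet, duration_s: float | None = None) -> dict:
    """Per-session activity scalars used for group comparison.

    Both readouts are reported: event rate (events/min) and cumulative
    suprathreshold AUC; the suprathreshold time fraction rides along.
    """
    if duration_s is None:
        duration_s = events.duration_s
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return {
        "event_count": events.count,
        "event_rate_per_min": events.count / (duration_s / 60.0),
        "auc": events.auc,
        "suprathreshold_fraction": events.suprathreshold_fraction,
    }
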