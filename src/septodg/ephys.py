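"""Slice-electrophysiology analysis.

Voltage clamp: spontaneous IPSC detection (threshold-on-deviation from a
running-median baseline), group distribution statistics, and paired
pre-vs-light epoch contrasts.  Current clamp: passive membrane properties
from a hyperpolarizing pulse and the F–I relation from a 16-step current
ladder (−20 … +280 pA, 500 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal, stats

log = logging.getLogger(__name__)

__all__ = [
    "Sweep",
    "SweepSet",
    "SynapticEventTable",
    "IntrinsicProperties",
    "qc_access_resistance",
    "detect_sipscs",
    "sipsc_group_stats",
    "opto_epoch_compare",
    "intrinsic_properties",
    "fi_group_compare",
]

FS_HZ = 10_000.0
STEP_LADDER_PA = tuple(range(-20, 281, 20))  # 16 steps
STEP_DURATION_S = 0.5
RIN_PULSE_PA = -20.0
RIN_PULSE_S = 0.2
SPIKE_DETECT_MV = 0.0
SPIKE_REFRACTORY_S = 0.002
AP_THRESHOLD_DVDT = 20.0  # mV/ms


@dataclass
class Sweep:
    """One trace with its protocol annotation."""

    time: np.ndarray  # s
    signal: np.ndarray  # pA (voltage clamp) or mV (current clamp)
    injected_pa: float | None = None
    step_start_s: float | None = None
    step_duration_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.time) != len(self.signal):
            raise ValueError("time and signal must have equal length")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass
class SweepSet:
    """Recording sweeps plus protocol metadata for one cell."""

    sweeps: list[Sweep]
    mode: str  # {voltage_clamp, current_clamp}
    holding_mv: float | None = None
    light_epochs: list[tuple[float, float]] = field(default_factory=list)
    access_resistance_mohm: list[float] = field(default_factory=list)
    cell_id: str = ""
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for lo, hi in self.light_epochs:
            if hi <= lo:
                raise ValueError("light epoch end must exceed start")
        eps = sorted(self.light_epochs)
        for (a0, a1), (b0, _b1) in zip(eps, eps[1:]):
            if b0 < a1:
                raise ValueError("overlapping light epochs")
        if self.sweeps and self.light_epochs:
            dur = self.sweeps[0].duration_s
            for lo, hi in self.light_epochs:
                if lo < 0 or hi > dur + 1e-9:
                    raise ValueError("light epoch outside trace")


@dataclass
class SynapticEventTable:
    """Detected synaptic events: times (s) and positive amplitudes (pA)."""

    times: np.ndarray  # s, strictly increasing
    amplitudes: np.ndarray  # pA, > 0
    duration_s: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must match")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")

    @property
    def frequency_hz(self) -> float:
        return len(self.times) / self.duration_s if self.duration_s > 0 else 0.0

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class IntrinsicProperties:
    rmp_mv: float | None = None
    input_resistance_mohm: float | None = None
    tau_ms: float | None = None
    capacitance_pf: float | None = None
    ap_threshold_mv: float | None = None
    fi_table: pd.DataFrame | None = None  # columns: current_pa, spike_count
    rheobase_pa: float | None = None


def qc_access_resistance(sweeps: SweepSet, max_change: float = 0.20) -> dict:
    """Pass/fail on relative access-resistance drift (> 20% change fails).

    The boundary is strict: exactly 20% change passes.
    """
    ra = sweeps.access_resistance_mohm
    if len(ra) < 2:
        return {"status": "unverifiable", "change": None}
    start, end = ra[0], ra[-1]
    change = abs(end - start) / start
    status = "fail" if change > max_change else "pass"
    if status == "fail":
        log.info("cell %s excluded: access resistance changed %.0f%%", sweeps.cell_id, 100 * change)
    return {"status": status, "change": change}


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float = 1000.0) -> np.ndarray:
    sos = signal.butter(4, cutoff_hz, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_sipscs(
    sweep: Sweep,
    k: float = 3.5,
    min_iei_s: float = 0.005,
    min_width_s: float = 0.001,
    baseline_window_s: float = 0.201,
    lowpass_hz: float = 1000.0,
    clip_limits: tuple[float, float] | None = None,
) -> SynapticEventTable:
    """Detect inward synaptic currents on a voltage-clamp trace.

    The trace is low-pass filtered and a running-median baseline subtracted.
    Candidate peaks (local maxima of the inward deviation, spaced at least
    ``min_iei_s`` apart) become events when (a) the peak rises more than
    ``k`` × noise SD (robust MAD estimate) above its local pre-peak
    baseline (median over the 3–0.5 ms preceding the peak; this rejects
    slow ripples riding on another event's decay), and (b) the deviation
    stays above that level for at least ``min_width_s`` around the peak.
    Both acceptance rules tighten monotonically as ``k`` grows, so the
    event count is non-increasing in ``k``.  Amplitude is the peak
    deviation above the local baseline, reported positive.
    """
    fs = sweep.fs
    x = sweep.signal
    keep = np.ones(len(x), dtype=bool)
    if clip_limits is not None:
        clipped = (x <= clip_limits[0]) | (x >= clip_limits[1])
        if clipped.any():
            log.warning("excluding %d saturated samples", int(clipped.sum()))
            keep &= ~clipped
    filt = _lowpass(x, fs, lowpass_hz)

    # running median on a decimated copy: equivalent baseline, ~10x cheaper
    dec = max(1, int(fs // 1000))
    win = max(3, int(round(baseline_window_s * fs / dec)) | 1)
    base_dec = ndimage.median_filter(filt[::dec], size=win, mode="nearest")
    baseline = np.interp(np.arange(len(filt)), np.arange(0, len(filt), dec), base_dec)

    dev = baseline - filt  # inward (downward) deviation, positive
    noise_sd = 1.4826 * float(np.median(np.abs(dev[keep] - np.median(dev[keep]))))
    if noise_sd == 0.0:
        return SynapticEventTable(
            times=np.array([]), amplitudes=np.array([]), duration_s=sweep.duration_s,
            cell_id=sweep.label,
        )
    min_run = max(1, int(round(min_width_s * fs)))
    distance = max(1, int(round(min_iei_s * fs)))
    cands, _props = signal.find_peaks(dev, height=0.5 * k * noise_sd, distance=distance)
    # local baseline window ends 1.5 ms before the peak: clear of the rise
    # even after zero-phase filtering smears the onset
    pre_lo = max(2, int(round(0.006 * fs)))
    pre_hi = max(1, int(round(0.0015 * fs)))
    n = len(dev)
    peaks: list[int] = []
    amps_list: list[float] = []
    for pk in cands:
        if not keep[pk]:
            continue
        local_base = float(np.median(dev[max(0, pk - pre_lo) : max(1, pk - pre_hi)]))
        amp = float(dev[pk]) - local_base
        if amp <= k * noise_sd:
            continue
        # sustained width above the local event threshold
        level = local_base + k * noise_sd
        i = pk
        while i > 0 and dev[i - 1] > level:
            i -= 1
        j = pk
        while j < n - 1 and dev[j + 1] > level:
            j += 1
        if j - i + 1 < min_run:
            continue
        peaks.append(pk)
        amps_list.append(amp)

    times = np.array([sweep.time[pk] for pk in peaks])
    amps = np.array(amps_list)
    return SynapticEventTable(
        times=times, amplitudes=amps, duration_s=sweep.duration_s, cell_id=sweep.label
    )


def sipsc_group_stats(
    tables: dict[str, list[SynapticEventTable]],
) -> dict:
    """Compare sIPSC statistics between two groups of cells.

    Per-cell mean amplitude and frequency are compared with unpaired
    two-tailed t-tests; pooled amplitudes and inter-event intervals with
    two-sample KS tests.  Mean ± SEM per group is reported.
    """
    groups = sorted(tables)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for g in groups:
        if len(tables[g]) < 2:
            raise ValueError(f"group {g!r} has < 2 cells")
        if all(len(t.times) == 0 for t in tables[g]):
            raise ValueError(f"group {g!r} has zero events")

    def cell_means(ts: list[SynapticEventTable], attr: str) -> np.ndarray:
        vals = []
        for t in ts:
            if attr == "amplitude":
                if len(t.amplitudes):
                    vals.append(float(np.mean(t.amplitudes)))
            else:
                vals.append(t.frequency_hz)
        return np.asarray(vals)

    out: dict = {"groups": groups, "per_group": {}}
    for g in groups:
        amp = cell_means(tables[g], "amplitude")
        freq = cell_means(tables[g], "frequency")
        out["per_group"][g] = {
            "amplitude_mean": float(np.mean(amp)),
            "amplitude_sem": float(stats.sem(amp)) if len(amp) > 1 else None,
            "frequency_mean": float(np.mean(freq)),
            "frequency_sem": float(stats.sem(freq)) if len(freq) > 1 else None,
            "n_cells": len(tables[g]),
        }
    for attr in ("amplitude", "frequency"):
        a = cell_means(tables[groups[0]], attr)
        b = cell_means(tables[groups[1]], attr)
        t, p = stats.ttest_ind(a, b)
        out[f"{attr}_ttest"] = {"t": float(t), "p": float(p)}

    pooled_amp = [np.concatenate([t.amplitudes for t in tables[g]]) for g in groups]
    pooled_iei = [
        np.concatenate([t.intervals for t in tables[g] if len(t.times) > 1]) for g in groups
    ]
    d, p = stats.ks_2samp(pooled_amp[0], pooled_amp[1])
    out["amplitude_ks"] = {"D": float(d), "p": float(p)}
    if all(len(x) for x in pooled_iei):
        d, p = stats.ks_2samp(pooled_iei[0], pooled_iei[1])
        out["interval_ks"] = {"D": float(d), "p": float(p)}
    return out


def epoch_event_stats(
    table: SynapticEventTable,
    light_epochs: list[tuple[float, float]],
    window_s: float = 20.0,
) -> dict:
    """Per-cell frequency/amplitude in pre-light vs light windows.

    For each stimulation cycle the pre window is the ``window_s`` seconds
    immediately preceding light onset and the light window is
    [onset, onset + window_s).  Boundary events are assigned by onset time
    (an event exactly at epoch onset counts as 'light').  Windows are
    averaged across cycles.
    """
    if not light_epochs:
        raise ValueError("no light epochs")
    pre_f, light_f, pre_a, light_a = [], [], [], []
    for lo, hi in sorted(light_epochs):
        w = min(window_s, hi - lo)
        pre_mask = (table.times >= lo - window_s) & (table.times < lo)
        light_mask = (table.times >= lo) & (table.times < lo + w)
        pre_f.append(pre_mask.sum() / window_s)
        light_f.append(light_mask.sum() / w)
        if pre_mask.any():
            pre_a.append(float(np.mean(table.amplitudes[pre_mask])))
        if light_mask.any():
            light_a.append(float(np.mean(table.amplitudes[light_mask])))
    return {
        "pre_frequency": float(np.mean(pre_f)),
        "light_frequency": float(np.mean(light_f)),
        "pre_amplitude": float(np.mean(pre_a)) if pre_a else None,
        "light_amplitude": float(np.mean(light_a)) if light_a else None,
        "n_cycles": len(light_epochs),
    }


def opto_epoch_compare(
    cells: list[tuple[SynapticEventTable, list[tuple[float, float]]]],
    window_s: float = 20.0,
) -> dict:
    """Paired pre-vs-light comparison across cells (two-tailed paired t)."""
    rows = [epoch_event_stats(t, eps, window_s) for t, eps in cells]
    out: dict = {"n_cells": len(rows), "per_cell": rows}
    for attr in ("frequency", "amplitude"):
        pre = [r[f"pre_{attr}"] for r in rows]
        light = [r[f"light_{attr}"] for r in rows]
        pairs = [(a, b) for a, b in zip(pre, light) if a is not None and b is not None]
        if len(pairs) < 2:
            out[f"{attr}_paired_t"] = {"t": None, "p": None, "undefined": True}
            continue
        a, b = map(np.asarray, zip(*pairs))
        if np.var(a - b) == 0:
            row = (
                {"t": 0.0, "p": 1.0, "undefined": False}
                if np.all(a == b)
                else {"t": None, "p": None, "undefined": True}
            )
        else:
            t, p = stats.ttest_rel(a, b)
            row = {"t": float(t), "p": float(p), "undefined": False}
        row["mean_pre"] = float(np.mean(a))
        row["mean_light"] = float(np.mean(b))
        out[f"{attr}_paired_t"] = row
    return out


def count_spikes(
    v: np.ndarray,
    fs: float,
    threshold_mv: float = SPIKE_DETECT_MV,
    refractory_s: float = SPIKE_REFRACTORY_S,
) -> int:
    """Upward threshold crossings with a refractory deduplication."""
    above = v > threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return 0
    refr = int(round(refractory_s * fs))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(c)
    return len(kept)


def _fit_tau_ms(t_s: np.ndarray, v: np.ndarray, v0: float, v_ss: float) -> float | None:
    """Single-exponential fit of a charging phase; returns tau in ms."""

    def model(t, tau):
        return v_ss + (v0 - v_ss) * np.exp(-t / tau)

    try:
        amp = v_ss - v0
        if amp == 0:
            return None
        # crude init: time to reach 63% of the deflection
        frac = (v - v0) / amp
        idx = np.flatnonzero(frac >= 0.632)
        tau0 = t_s[idx[0]] if len(idx) else t_s[-1] / 3
        popt, _ = optimize.curve_fit(model, t_s, v, p0=[max(tau0, 1e-4)], maxfev=2000)
        tau = float(popt[0])
        if tau <= 0:
            return None
        return tau * 1000.0
    except (RuntimeError, ValueError):
        return None


def intrinsic_properties(sweeps: SweepSet) -> IntrinsicProperties:
    """Passive and active membrane properties from current-clamp sweeps.

    RMP: mean pre-step voltage on the zero-current sweep.  Input resistance:
    steady-state deflection (last 25% of the pulse) over the −20 pA, 200 ms
    pulse.  τ: single-exponential fit of the pulse charging phase;
    C = τ/R.  AP threshold: voltage at which dV/dt first exceeds 20 mV/ms
    before the first spike.  F–I: refractory-deduplicated 0 mV crossings per
    500 ms step.
    """
    if sweeps.mode != "current_clamp":
        raise ValueError("intrinsic properties require current-clamp sweeps")
    props = IntrinsicProperties()

    rin_sweep = next((s for s in sweeps.sweeps if s.label == "rin_pulse"), None)
    step_sweeps = [s for s in sweeps.sweeps if s.label == "fi_step"]

    zero = next((s for s in step_sweeps if s.injected_pa == 0), None)
    rmp_source = zero or (step_sweeps[0] if step_sweeps else rin_sweep)
    if rmp_source is not None and rmp_source.step_start_s:
        pre = rmp_source.signal[rmp_source.time < rmp_source.step_start_s]
        props.rmp_mv = float(np.mean(pre)) if len(pre) else None

    if rin_sweep is not None:
        fs = rin_sweep.fs
        t0 = rin_sweep.step_start_s or 0.0
        dur = rin_sweep.step_duration_s or RIN_PULSE_S
        i_pa = rin_sweep.injected_pa if rin_sweep.injected_pa is not None else RIN_PULSE_PA
        pre = rin_sweep.signal[rin_sweep.time < t0]
        v_rest = float(np.mean(pre)) if len(pre) else float(rin_sweep.signal[0])
        in_step = (rin_sweep.time >= t0) & (rin_sweep.time < t0 + dur)
        t_step = rin_sweep.time[in_step] - t0
        v_step = rin_sweep.signal[in_step]
        ss = v_step[t_step >= 0.75 * dur]
        v_ss = float(np.mean(ss))
        dv = v_ss - v_rest  # mV
        if i_pa != 0 and dv != 0:
            # R[MΩ] = ΔV[mV] / ΔI[nA]
            props.input_resistance_mohm = dv / (i_pa / 1000.0)
        tau_ms = _fit_tau_ms(t_step, v_step, v_rest, v_ss)
        props.tau_ms = tau_ms
        if tau_ms is not None and props.input_resistance_mohm:
            # C[pF] = τ[ms] / R[GΩ] -> τ(ms)/R(MΩ) * 1000
            props.capacitance_pf = tau_ms / props.input_resistance_mohm * 1000.0
        if props.rmp_mv is None and len(pre):
            props.rmp_mv = v_rest

    if step_sweeps:
        rows = []
        for s in sorted(step_sweeps, key=lambda s: s.injected_pa):
            t0 = s.step_start_s or 0.0
            dur = s.step_duration_s or STEP_DURATION_S
            in_step = (s.time >= t0) & (s.time < t0 + dur)
            n = count_spikes(s.signal[in_step], s.fs)
            rows.append({"current_pa": s.injected_pa, "spike_count": n})
        props.fi_table = pd.DataFrame(rows)
        firing = props.fi_table[props.fi_table.spike_count > 0]
        if len(firing):
            props.rheobase_pa = float(firing.current_pa.iloc[0])

        # AP threshold from the first spiking sweep
        first = next(
            (s for s in sorted(step_sweeps, key=lambda s: s.injected_pa)
             if count_spikes(s.signal, s.fs) > 0),
            None,
        )
        if first is not None:
            v = first.signal
            dvdt = np.gradient(v) * first.fs / 1000.0  # mV/ms
            spike_idx = np.flatnonzero((v[:-1] <= SPIKE_DETECT_MV) & (v[1:] > SPIKE_DETECT_MV))
            if len(spike_idx):
                pre_seg = slice(max(0, spike_idx[0] - int(0.01 * first.fs)), spike_idx[0] + 1)
                cand = np.flatnonzero(dvdt[pre_seg] > AP_THRESHOLD_DVDT)
                if len(cand):
                    props.ap_threshold_mv = float(v[pre_seg][cand[0]])
    return props


def fi_group_compare(fi_tables: dict[str, list[pd.DataFrame]]) -> dict:
    """Two-way ANOVA (genotype × injected current) on F–I spike counts.

    Type II sums of squares; steps missing from any cell are excluded
    listwise (logged).  A single-current design is rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    groups = sorted(fi_tables)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")

    common = None
    for g in groups:
        for tbl in fi_tables[g]:
            steps = set(tbl.current_pa)
            common = steps if common is None else common & steps
    if common is None or len(common) < 2:
        raise ValueError("need at least two common current levels for a two-way design")
    dropped = set()
    for g in groups:
        for tbl in fi_tables[g]:
            dropped |= set(tbl.current_pa) - common
    if dropped:
        log.info("excluding current steps missing in some cells: %s", sorted(dropped))

    rows = []
    for g in groups:
        for ci, tbl in enumerate(fi_tables[g]):
            sub = tbl[tbl.current_pa.isin(common)]
            for _, r in sub.iterrows():
                rows.append(
                    {"genotype": g, "cell": f"{g}_{ci}", "current": r.current_pa,
                     "spikes": r.spike_count}
                )
    df = pd.DataFrame(rows)
    model = smf.ols("spikes ~ C(genotype) * C(current)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "anova": table,
        "genotype_F": float(table.loc["C(genotype)", "F"]),
        "genotype_p": float(table.loc["C(genotype)", "PR(>F)"]),
        "current_p": float(table.loc["C(current)", "PR(>F)"]),
        "interaction_p": float(table.loc["C(genotype):C(current)", "PR(>F)"]),
    }
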