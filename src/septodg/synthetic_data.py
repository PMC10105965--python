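"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: dual-site
photometry sessions (correlated transient trains, shared motion artifacts),
arena behavior tracks with scripted exploration bouts, voltage-clamp sIPSC
traces with optional light-epoch modulation, current-clamp RC/LIF step
protocols, and labeled tracing volumes (capsule-shaped processes, spherical
somata, configurable co-localization).

All generators are bit-reproducible given ``SimConfig.seed``; sub-generators
derive child seeds deterministically so stages are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from septodg._rng import child_rng
from septodg.behavior import BehaviorTrack, ExplorationBout
from septodg.ephys import (
    RIN_PULSE_PA,
    RIN_PULSE_S,
    STEP_DURATION_S,
    STEP_LADDER_PA,
    Sweep,
    SweepSet,
)
from septodg.photometry import PhotometrySession
from septodg.tracing import LabeledVolume, RoiMask

__all__ = [
    "GenotypeParams",
    "PhotometryParams",
    "EphysParams",
    "ImagingParams",
    "SimConfig",
    "GroundTruth",
    "simulate_photometry_session",
    "simulate_paired_sessions",
    "simulate_behavior_track",
    "simulate_sipsc_trace",
    "simulate_current_steps",
    "simulate_tracing_volume",
    "gaussian_emission_spectra",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenotypeParams:
    """Per-genotype generator knobs (free parameters, not measured claims)."""

    event_rate_per_min: float = 6.0
    transient_amplitude: float = 0.5  # ΔF/F units
    coupling_rho: float = 0.8  # MS–DG per-bout amplitude correlation

    def validate(self) -> None:
        if self.event_rate_per_min < 0:
            raise ValueError("event rate must be >= 0")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling rho must lie in [-1, 1]")


@dataclass
class PhotometryParams:
    duration_s: float = 600.0
    fs_photo: float = 10.0
    fs_video: float = 20.0
    baseline: float = 100.0  # a.u.
    drift_amplitude: float = 0.0  # fractional slow drift
    motion_amplitude: float = 0.0  # a.u., shared across channels
    noise_sd: float = 0.5  # a.u.
    rise_s: float = 0.1  # GCaMP6f-like kinetics
    decay_s: float = 0.4
    amplitude_cv: float = 0.3  # lognormal-ish spread of transient amplitudes
    exploration_gain: float = 1.0  # rate multiplier inside bouts

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("non-positive duration")
        if self.noise_sd < 0:
            raise ValueError("negative noise SD")
        if self.fs_video / self.fs_photo != int(self.fs_video / self.fs_photo):
            raise ValueError("fs_video must be an integer multiple of fs_photo")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be positive")


@dataclass
class EphysParams:
    fs: float = 10_000.0
    sipsc_rate_hz: float = 5.0
    amp_lognorm_mu: float = math.log(50.0)  # pA
    amp_lognorm_sigma: float = 0.3
    rise_ms: float = 0.5
    decay_ms: float = 8.0
    noise_sd_pa: float = 2.0
    opto_rate_modulation: float = 1.0  # event-rate multiplier inside light epochs
    opto_amp_modulation: float = 1.0
    duration_s: float = 60.0
    # membrane model
    rmp_mv: float = -70.0
    r_mohm: float = 150.0
    tau_ms: float = 20.0
    rheobase_pa: float = 110.0
    noise_sd_mv: float = 0.0

    def validate(self) -> None:
        if self.sipsc_rate_hz < 0 or self.noise_sd_pa < 0:
            raise ValueError("rates and noise SD must be >= 0")
        if self.r_mohm <= 0 or self.tau_ms <= 0:
            raise ValueError("R and tau must be positive")
        if self.duration_s <= 0:
            raise ValueError("non-positive duration")


@dataclass
class ImagingParams:
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    volume_shape: tuple[int, int, int] = (40, 128, 128)
    process_count: int = 30
    tube_radius_um: float = 1.0
    tube_length_um: float = 30.0
    soma_count: int = 50
    soma_radius_um: float = 5.0
    colocalization_fraction: float = 0.64
    section_shape: tuple[int, int] = (512, 512)
    pixel_size_um: tuple[float, float] = (1.0, 1.0)
    signal_level: float = 200.0
    background_level: float = 10.0
    noise_sd: float = 2.0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um) or any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume shape and voxel size must be positive")
        if self.tube_radius_um <= 0:
            raise ValueError("tube radius must be positive")
        if not 0.0 <= self.colocalization_fraction <= 1.0:
            raise ValueError("colocalization fraction must lie in [0, 1]")
        if self.process_count < 0 or self.soma_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimConfig:
    seed: int = 0
    n_animals_per_group: int = 6
    genotype_params: dict = field(
        default_factory=lambda: {
            "WT": GenotypeParams(),
            "AD": GenotypeParams(event_rate_per_min=12.0),
        }
    )
    photometry: PhotometryParams = field(default_factory=PhotometryParams)
    ephys: EphysParams = field(default_factory=EphysParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gp in self.genotype_params.values():
            gp.validate()
        self.photometry.validate()
        self.ephys.validate()
        self.imaging.validate()


@dataclass
class GroundTruth:
    """True generator parameters/events for one simulated object."""

    event_times_s: np.ndarray | None = None
    event_amplitudes: np.ndarray | None = None
    bouts: list[ExplorationBout] | None = None
    bout_amplitudes: np.ndarray | None = None  # per-bout transient amplitude
    coupling_rho: float | None = None
    analysis_start_s: float | None = None
    # ephys
    r_mohm: float | None = None
    tau_ms: float | None = None
    rmp_mv: float | None = None
    rheobase_pa: float | None = None
    spike_counts: dict | None = None
    # imaging
    process_count: int | None = None
    process_volumes_um3: np.ndarray | None = None
    total_tube_volume_um3: float | None = None
    soma_count: int | None = None
    colocalized_count: int | None = None
    colocalized_fraction: float | None = None
    region_counts: dict | None = None
    region_areas_um2: dict | None = None
    starter_area_um2: float | None = None

    def validate_events(self, duration_s: float) -> None:
        if self.event_times_s is not None and len(self.event_times_s):
            if self.event_times_s.min() < 0 or self.event_times_s.max() > duration_s:
                raise ValueError("true event times must lie within the trace duration")


# ---------------------------------------------------------------------------
# kernels


def _biexp_kernel(fs: float, rise: float, decay: float, length_factor: float = 8.0) -> np.ndarray:
    """Double-exponential kernel normalized to unit peak."""
    t = np.arange(0.0, length_factor * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def _add_events(
    trace: np.ndarray, fs: float, times_s: np.ndarray, amps: np.ndarray, kernel: np.ndarray
) -> None:
    """Superimpose amp-scaled kernels starting at each event time (in place)."""
    n = len(trace)
    for t, a in zip(times_s, amps):
        i = int(round(t * fs))
        if i >= n:
            continue
        j = min(n, i + len(kernel))
        trace[i:j] += a * kernel[: j - i]


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _motion_artifact(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Slow shared artifact: smoothed Gaussian noise scaled to the amplitude."""
    if amplitude == 0.0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    width = max(3, n // 100)
    kern = np.hanning(width)
    kern /= kern.sum()
    smooth = np.convolve(raw, kern, mode="same")
    sd = smooth.std()
    return amplitude * smooth / sd if sd > 0 else np.zeros(n)


# ---------------------------------------------------------------------------
# photometry


def simulate_photometry_session(
    cfg: SimConfig,
    genotype: str = "WT",
    site: str = "DG",
    animal_id: str = "m0",
    track: BehaviorTrack | None = None,
    context: str = "homecage",
) -> tuple[PhotometrySession, GroundTruth]:
    """One dual-channel photometry session with Poisson calcium transients.

    GCaMP = baseline·(1 + drift) + transients + shared motion artifact +
    noise; mCherry = baseline + the same motion artifact + independent noise.
    When a behavior ``track`` is attached, the event rate is multiplied by
    ``exploration_gain`` inside its scripted bouts.
    """
    p = cfg.photometry
    gp = cfg.genotype_params[genotype]
    rng = child_rng(cfg.seed, "photometry", genotype, site, animal_id)
    fs = p.fs_photo
    n = int(round(p.duration_s * fs))
    t = np.arange(n) / fs

    rate_hz = gp.event_rate_per_min / 60.0
    if track is not None and p.exploration_gain != 1.0:
        # thinning against the piecewise-constant bout-modulated rate
        lam_max = rate_hz * max(1.0, p.exploration_gain)
        cand = _poisson_times(rng, lam_max, p.duration_s)
        in_bout = np.zeros(len(cand), dtype=bool)
        for b in getattr(track, "scripted_bouts", []):
            in_bout |= (cand >= b.onset) & (cand < b.offset)
        lam = np.where(in_bout, rate_hz * p.exploration_gain, rate_hz)
        keep = rng.uniform(size=len(cand)) < lam / lam_max
        times = cand[keep]
    else:
        times = _poisson_times(rng, rate_hz, p.duration_s)
    amps_dff = gp.transient_amplitude * np.exp(
        rng.standard_normal(len(times)) * p.amplitude_cv - 0.5 * p.amplitude_cv**2
    )

    drift = p.drift_amplitude * np.sin(2 * np.pi * t / max(p.duration_s, 1e-9))
    motion = _motion_artifact(rng, n, p.motion_amplitude)

    gcamp = p.baseline * (1.0 + drift)
    _add_events(gcamp, fs, times, p.baseline * amps_dff, _biexp_kernel(fs, p.rise_s, p.decay_s))
    gcamp = gcamp + motion + rng.standard_normal(n) * p.noise_sd
    mcherry = p.baseline + motion + rng.standard_normal(n) * p.noise_sd

    session = PhotometrySession(
        time=t,
        f_gcamp=np.clip(gcamp, 0.0, None),
        f_mcherry=np.clip(mcherry, 0.0, None),
        site=site,
        animal_id=animal_id,
        genotype=genotype,
        context=context,
    )
    truth = GroundTruth(event_times_s=times, event_amplitudes=amps_dff)
    truth.validate_events(p.duration_s)
    return session, truth


def simulate_paired_sessions(
    cfg: SimConfig,
    genotype: str = "WT",
    animal_id: str = "m0",
    bouts: list[ExplorationBout] | None = None,
    rho: float | None = None,
    background_rate_per_min: float = 0.0,
) -> tuple[PhotometrySession, PhotometrySession, GroundTruth]:
    """Paired DG/MS sessions with bout-locked, ρ-correlated transients.

    Each bout triggers one transient at its onset in both sites; the
    per-bout amplitudes form a bivariate pair with correlation ``rho``
    (defaulting to the genotype's coupling).  Optional background transients
    are uncorrelated across sites.
    """
    p = cfg.photometry
    gp = cfg.genotype_params[genotype]
    if rho is None:
        rho = gp.coupling_rho
    if bouts is None:
        bouts = default_bout_script(p.duration_s)
    rng = child_rng(cfg.seed, "paired_photometry", genotype, animal_id)
    fs = p.fs_photo
    n = int(round(p.duration_s * fs))
    t = np.arange(n) / fs
    kernel = _biexp_kernel(fs, p.rise_s, p.decay_s)

    nb = len(bouts)
    z_dg = rng.standard_normal(nb)
    z_ms = rho * z_dg + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(nb)
    base = gp.transient_amplitude
    cv = p.amplitude_cv
    amp_dg = np.clip(base * (1.0 + cv * z_dg), 0.05 * base, None)
    amp_ms = np.clip(base * (1.0 + cv * z_ms), 0.05 * base, None)
    onsets = np.array([b.onset for b in bouts])

    sessions = []
    for site, amps in (("DG", amp_dg), ("MS", amp_ms)):
        gcamp = np.full(n, p.baseline)
        _add_events(gcamp, fs, onsets, p.baseline * amps, kernel)
        if background_rate_per_min > 0:
            bg_t = _poisson_times(rng, background_rate_per_min / 60.0, p.duration_s)
            bg_a = base * np.ones(len(bg_t))
            _add_events(gcamp, fs, bg_t, p.baseline * bg_a, kernel)
        motion = _motion_artifact(rng, n, p.motion_amplitude)
        gcamp = gcamp + motion + rng.standard_normal(n) * p.noise_sd
        mcherry = p.baseline + motion + rng.standard_normal(n) * p.noise_sd
        sessions.append(
            PhotometrySession(
                time=t,
                f_gcamp=np.clip(gcamp, 0.0, None),
                f_mcherry=np.clip(mcherry, 0.0, None),
                site=site,
                animal_id=animal_id,
                genotype=genotype,
                context="arena",
            )
        )
    truth = GroundTruth(
        bouts=bouts,
        bout_amplitudes=np.vstack([amp_dg, amp_ms]),
        coupling_rho=rho,
        event_times_s=onsets,
    )
    return sessions[0], sessions[1], truth


def gaussian_emission_spectra(
    f_gcamp: np.ndarray,
    f_mcherry: np.ndarray,
    wavelengths_nm: np.ndarray,
    gcamp_peak_nm: float = 515.0,
    mcherry_peak_nm: float = 600.0,
    width_nm: float = 12.0,
) -> np.ndarray:
    """Spectrometer-style per-timepoint spectra from two channel amplitudes.

    Each channel contributes a unit-peak Gaussian emission band scaled by its
    fluorescence, so band integrals recover the amplitudes up to the known
    Gaussian band integral.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    g1 = np.exp(-0.5 * ((wl - gcamp_peak_nm) / width_nm) ** 2)
    g2 = np.exp(-0.5 * ((wl - mcherry_peak_nm) / width_nm) ** 2)
    return np.outer(np.asarray(f_gcamp, float), g1) + np.outer(np.asarray(f_mcherry, float), g2)


# ---------------------------------------------------------------------------
# behavior


OBJECT_POSITIONS = {
    "familiarization": {"A": (15.0, 15.0), "B": (30.0, 30.0)},
    "test": {"A": (15.0, 15.0), "B": (33.0, 12.0)},  # B relocated
}
CORNER_DWELL_S = 2.0


def default_bout_script(
    duration_s: float,
    n_bouts: int = 20,
    bout_s: float = 1.0,
    first_onset_s: float = 10.0,
    objects: tuple[str, ...] = ("A", "B"),
) -> list[ExplorationBout]:
    """Evenly spaced alternating-object bout script."""
    if n_bouts < 1:
        return []
    span = duration_s - first_onset_s - bout_s - 5.0
    gap = span / max(1, n_bouts - 1)
    bouts = []
    for i in range(n_bouts):
        onset = first_onset_s + i * gap
        bouts.append(
            ExplorationBout(onset=onset, offset=onset + bout_s, object=objects[i % len(objects)])
        )
    return bouts


def simulate_behavior_track(
    cfg: SimConfig,
    phase: str = "familiarization",
    scripted_bouts: list[ExplorationBout] | None = None,
    duration_s: float | None = None,
) -> tuple[BehaviorTrack, GroundTruth]:
    """Arena track: corner dwell, then a bounded walk with scripted bouts.

    The pose trajectory is driven by the ground-truth bout list: scripted
    frames place the head within 1.5 cm of the target object facing it;
    all other frames are pushed ≥ 4 cm from both objects so the bout
    detector recovers the script exactly (frame-snapped edges).
    """
    if phase not in ("familiarization", "test"):
        raise ValueError(f"phase must be familiarization or test, got {phase!r}")
    p = cfg.photometry
    fs = p.fs_video
    duration = duration_s if duration_s is not None else p.duration_s
    rng = child_rng(cfg.seed, "behavior", phase)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    objects = dict(OBJECT_POSITIONS[phase])

    if scripted_bouts is None:
        scripted_bouts = default_bout_script(duration)
    # snap script to the video frame grid
    snapped = []
    for b in scripted_bouts:
        i0 = int(round(b.onset * fs))
        i1 = int(round(b.offset * fs))
        if i1 <= i0 or i1 > n:
            raise ValueError("scripted bout outside track or zero frames")
        snapped.append(ExplorationBout(onset=i0 / fs, offset=i1 / fs, object=b.object))
    scripted_bouts = snapped

    # bounded random walk
    x = np.empty(n)
    y = np.empty(n)
    steps = rng.standard_normal((n, 2)) * 0.5
    pos = np.array([5.0, 5.0])  # start inside a corner zone
    side = 45.0
    n_dwell = int(CORNER_DWELL_S * fs)
    for i in range(n):
        if i >= n_dwell:
            pos = pos + steps[i]
            # drift toward center keeps the walk out of the corners
            pos += 0.02 * (np.array([side / 2, side / 2]) - pos)
            pos = np.clip(pos, 1.0, side - 1.0)
        x[i], y[i] = pos

    heading = np.mod(np.degrees(np.arctan2(np.gradient(y), np.gradient(x)))
                     + rng.standard_normal(n) * 10.0, 360.0)

    # keep non-bout frames non-exploratory: push away from both objects
    bout_mask = np.zeros(n, dtype=bool)
    for b in scripted_bouts:
        bout_mask[int(round(b.onset * fs)) : int(round(b.offset * fs))] = True
    for ox, oy in objects.values():
        dx, dy = x - ox, y - oy
        d = np.hypot(dx, dy)
        too_close = (d < 4.0) & ~bout_mask
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(d > 0, dx / d, 1.0)
            uy = np.where(d > 0, dy / d, 0.0)
        x[too_close] = np.clip(ox + 4.0 * ux[too_close], 1.0, side - 1.0)
        y[too_close] = np.clip(oy + 4.0 * uy[too_close], 1.0, side - 1.0)

    # scripted frames: sit 1.5 cm from the object, facing it
    for b in scripted_bouts:
        i0, i1 = int(round(b.onset * fs)), int(round(b.offset * fs))
        ox, oy = objects[b.object]
        phi = rng.uniform(0, 2 * np.pi)
        px = np.clip(ox + 1.5 * np.cos(phi), 1.0, side - 1.0)
        py = np.clip(oy + 1.5 * np.sin(phi), 1.0, side - 1.0)
        x[i0:i1] = px
        y[i0:i1] = py
        heading[i0:i1] = np.mod(np.degrees(np.arctan2(oy - py, ox - px)), 360.0)

    track = BehaviorTrack(
        time=t, x=x, y=y, heading_deg=heading, objects=objects,
        arena_side_cm=side, phase=phase,
    )
    track.scripted_bouts = scripted_bouts  # ground-truth attachment
    truth = GroundTruth(bouts=scripted_bouts, analysis_start_s=None)
    return track, truth


# ---------------------------------------------------------------------------
# ephys


def _validate_epochs(epochs: list[tuple[float, float]], duration_s: float) -> None:
    eps = sorted(epochs)
    for lo, hi in eps:
        if hi <= lo:
            raise ValueError("epoch end must exceed start")
        if lo < 0 or hi > duration_s:
            raise ValueError("light epoch outside trace")
    for (a0, a1), (b0, _) in zip(eps, eps[1:]):
        if b0 < a1:
            raise ValueError("overlapping light epochs")


def default_light_epochs(duration_s: float, epoch_s: float = 20.0, period_s: float = 60.0,
                         first_onset_s: float = 20.0) -> list[tuple[float, float]]:
    """20 s light epochs delivered every 60 s."""
    epochs = []
    t0 = first_onset_s
    while t0 + epoch_s <= duration_s:
        epochs.append((t0, t0 + epoch_s))
        t0 += period_s
    return epochs


def simulate_sipsc_trace(
    cfg: SimConfig,
    light_epochs: list[tuple[float, float]] | None = None,
    cell_id: str = "c0",
) -> tuple[SweepSet, GroundTruth]:
    """Voltage-clamp trace of Poisson sIPSCs with lognormal amplitudes.

    Events are inward (downward) biexponential deflections reported as
    positive amplitudes.  Inside light epochs the event rate is multiplied
    by ``opto_rate_modulation`` and amplitudes by ``opto_amp_modulation``.
    """
    e = cfg.ephys
    rng = child_rng(cfg.seed, "sipsc", cell_id)
    fs = e.fs
    duration = e.duration_s
    if light_epochs:
        _validate_epochs(light_epochs, duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    rate = e.sipsc_rate_hz
    if light_epochs and e.opto_rate_modulation != 1.0:
        lam_max = rate * max(1.0, e.opto_rate_modulation)
        cand = _poisson_times(rng, lam_max, duration)
        in_light = np.zeros(len(cand), dtype=bool)
        for lo, hi in light_epochs:
            in_light |= (cand >= lo) & (cand < hi)
        lam = np.where(in_light, rate * e.opto_rate_modulation, rate)
        keep = rng.uniform(size=len(cand)) < lam / lam_max
        times = cand[keep]
    else:
        times = _poisson_times(rng, rate, duration)

    amps = rng.lognormal(e.amp_lognorm_mu, e.amp_lognorm_sigma, size=len(times))
    if light_epochs and e.opto_amp_modulation != 1.0:
        in_light = np.zeros(len(times), dtype=bool)
        for lo, hi in light_epochs:
            in_light |= (times >= lo) & (times < hi)
        amps = np.where(in_light, amps * e.opto_amp_modulation, amps)

    trace = rng.standard_normal(n) * e.noise_sd_pa
    kernel = _biexp_kernel(fs, e.rise_ms / 1000.0, e.decay_ms / 1000.0)
    _add_events(trace, fs, times, -amps, kernel)  # inward = downward

    sweep = Sweep(time=t, signal=trace, label=cell_id)
    sweeps = SweepSet(
        sweeps=[sweep],
        mode="voltage_clamp",
        holding_mv=-65.0,
        light_epochs=list(light_epochs or []),
        cell_id=cell_id,
    )
    truth = GroundTruth(event_times_s=times, event_amplitudes=amps)
    truth.validate_events(duration)
    return sweeps, truth


def simulate_current_steps(cfg: SimConfig, cell_id: str = "c0") -> tuple[SweepSet, GroundTruth]:
    """Current-clamp protocol: −20 pA/200 ms pulse plus the 16-step ladder.

    Passive response is RC charging V(t) = RMP + I·R·(1 − e^(−t/τ));
    spikes follow a leaky-integrate-and-fire rule whose threshold is set so
    that the configured rheobase current is the smallest suprathreshold step.
    """
    e = cfg.ephys
    rng = child_rng(cfg.seed, "steps", cell_id)
    fs = e.fs
    dt = 1.0 / fs
    tau_s = e.tau_ms / 1000.0
    r_gohm = e.r_mohm / 1000.0  # mV per pA

    charge_frac = 1.0 - math.exp(-STEP_DURATION_S / tau_s)
    v_th = e.rmp_mv + e.rheobase_pa * r_gohm * charge_frac * (1.0 - 1e-9)

    pre_s, post_s = 0.1, 0.1

    def make_sweep(i_pa: float, step_s: float, label: str, spiking: bool) -> tuple[Sweep, int]:
        n = int(round((pre_s + step_s + post_s) * fs))
        t = np.arange(n) / fs
        v = np.full(n, e.rmp_mv)
        i0 = int(round(pre_s * fs))
        i1 = int(round((pre_s + step_s) * fs))
        n_spikes = 0
        if not spiking:
            ts = t[i0:i1] - t[i0]
            v[i0:i1] = e.rmp_mv + i_pa * r_gohm * (1.0 - np.exp(-ts / tau_s))
            v_end = v[i1 - 1]
            ts2 = t[i1:] - t[i1]
            v[i1:] = e.rmp_mv + (v_end - e.rmp_mv) * np.exp(-ts2 / tau_s)
        else:
            vm = e.rmp_mv
            spike_wave = np.concatenate([
                np.linspace(v_th, 30.0, int(0.001 * fs)),
                np.linspace(30.0, e.rmp_mv, int(0.001 * fs)),
            ])
            k = i0
            while k < i1:
                vm = vm + dt * ((e.rmp_mv - vm) + i_pa * r_gohm) / tau_s
                if vm >= v_th:
                    n_spikes += 1
                    w = min(len(spike_wave), i1 - k)
                    v[k : k + w] = spike_wave[:w]
                    k += w
                    vm = e.rmp_mv
                    continue
                v[k] = vm
                k += 1
            v_end = v[i1 - 1] if v[i1 - 1] < v_th else e.rmp_mv
            ts2 = t[i1:] - t[i1]
            v[i1:] = e.rmp_mv + (v_end - e.rmp_mv) * np.exp(-ts2 / tau_s)
        if e.noise_sd_mv > 0:
            v = v + rng.standard_normal(n) * e.noise_sd_mv
        return (
            Sweep(time=t, signal=v, injected_pa=i_pa, step_start_s=pre_s,
                  step_duration_s=step_s, label=label),
            n_spikes,
        )

    sweeps: list[Sweep] = []
    rin_sweep, _ = make_sweep(RIN_PULSE_PA, RIN_PULSE_S, "rin_pulse", spiking=False)
    sweeps.append(rin_sweep)

    spike_counts: dict[float, int] = {}
    for i_pa in STEP_LADDER_PA:
        spiking = i_pa * r_gohm * charge_frac >= (v_th - e.rmp_mv)
        sw, n_spikes = make_sweep(float(i_pa), STEP_DURATION_S, "fi_step", spiking=spiking)
        sweeps.append(sw)
        spike_counts[float(i_pa)] = n_spikes

    firing = [i for i, c in spike_counts.items() if c > 0]
    truth = GroundTruth(
        r_mohm=e.r_mohm,
        tau_ms=e.tau_ms,
        rmp_mv=e.rmp_mv,
        rheobase_pa=min(firing) if firing else None,
        spike_counts=spike_counts,
    )
    sweep_set = SweepSet(sweeps=sweeps, mode="current_clamp", cell_id=cell_id)
    return sweep_set, truth


# ---------------------------------------------------------------------------
# tracing volumes


def add_capsule(
    volume: np.ndarray,
    p0_um: np.ndarray,
    p1_um: np.ndarray,
    radius_um: float,
    voxel_size_um: tuple[float, float, float],
    value: float = 1.0,
) -> float:
    """Paint a capsule (cylinder + hemispherical caps) into a (z,y,x) grid.

    Voxel centers within ``radius_um`` of the segment p0–p1 are set to at
    least ``value``.  Returns the analytic capsule volume π·r²·L + 4/3·π·r³.
    """
    p0 = np.asarray(p0_um, float)
    p1 = np.asarray(p1_um, float)
    vs = np.asarray(voxel_size_um, float)
    r = float(radius_um)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - r) / vs - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + r) / vs + 0.5).astype(int) + 1,
        np.asarray(volume.shape),
    )
    if np.any(lo >= hi):
        return math.pi * r**2 * float(np.linalg.norm(p1 - p0)) + 4.0 / 3.0 * math.pi * r**3
    grids = np.meshgrid(
        *[(np.arange(lo[d], hi[d]) + 0.5) * vs[d] for d in range(3)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)  # physical voxel centers
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        s = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + s[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    inside = dist <= r
    sub = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = np.maximum(sub[inside], value)
    return math.pi * r**2 * math.sqrt(L2) + 4.0 / 3.0 * math.pi * r**3


def paint_disk(image: np.ndarray, center_px: tuple[float, float], radius_px: float,
               value: float) -> int:
    """Paint a filled disk into a 2D image; returns painted pixel count."""
    cy, cx = center_px
    y0 = max(0, int(cy - radius_px - 1))
    y1 = min(image.shape[0], int(cy + radius_px + 2))
    x0 = max(0, int(cx - radius_px - 1))
    x1 = min(image.shape[1], int(cx + radius_px + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= radius_px**2
    image[y0:y1, x0:x1][inside] = value
    return int(inside.sum())


#: default retrograde region layout: fraction of somata per named ROI
RETRO_REGION_WEIGHTS = {
    "MS": 0.35, "DB": 0.25, "VTA": 0.10, "cCA": 0.08, "cDG": 0.07,
    "HY": 0.05, "ENT": 0.04, "LS": 0.03, "TH": 0.03,
}


def _grid_positions(rng: np.random.Generator, n: int, box: tuple[int, int, int, int],
                    min_sep_px: float) -> list[tuple[float, float]]:
    """Jittered-grid soma centers inside (y0, y1, x0, x1), non-touching."""
    y0, y1, x0, x1 = box
    cols = max(1, int((x1 - x0) / min_sep_px))
    rows = max(1, int((y1 - y0) / min_sep_px))
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    if n > len(cells):
        raise ValueError(f"cannot place {n} non-touching somata in ROI (capacity {len(cells)})")
    chosen = rng.choice(len(cells), size=n, replace=False)
    out = []
    jitter = 0.15 * min_sep_px
    for idx in chosen:
        r, c = cells[idx]
        cy = y0 + (r + 0.5) * (y1 - y0) / rows + rng.uniform(-jitter, jitter)
        cx = x0 + (c + 0.5) * (x1 - x0) / cols + rng.uniform(-jitter, jitter)
        out.append((cy, cx))
    return out


def simulate_tracing_volume(
    cfg: SimConfig, mode: str = "anterograde_volume", image_id: str = "v0"
) -> tuple[LabeledVolume, dict[str, RoiMask], GroundTruth]:
    """Synthetic tracing data with exact geometric ground truth.

    ``anterograde_volume``: 3D YFP volume with randomly oriented capsule
    processes inside a hilus ROI, plus a soma channel in an MS ROI.
    ``retrograde_sections``: 2D section with mCherry+ somata distributed
    across named ROIs, a painted starter region, and a configured fraction
    of somata co-labeled in the GABA channel.
    """
    im = cfg.imaging
    rng = child_rng(cfg.seed, "tracing", mode, image_id)

    if mode == "anterograde_volume":
        shape = im.volume_shape
        vs = im.voxel_size_um
        extent = np.asarray(shape) * np.asarray(vs)
        yfp = np.full(shape, im.background_level, dtype=float)
        hilus = np.zeros(shape, dtype=bool)
        hilus[:, :, : shape[2]] = True  # hilus ROI = full extruded section

        volumes = []
        for _ in range(im.process_count):
            c = rng.uniform(0.15, 0.85, size=3) * extent
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            half = 0.5 * im.tube_length_um * u
            vol = add_capsule(yfp, c - half, c + half, im.tube_radius_um, vs,
                              value=im.signal_level)
            volumes.append(vol)
        if im.noise_sd > 0:
            yfp = yfp + rng.standard_normal(shape) * im.noise_sd

        # MS soma image: one 2D plane stored as a single-section channel stack
        ms_shape = (1, *im.section_shape)
        soma = np.full(ms_shape, im.background_level, dtype=float)
        ms_mask = np.zeros(ms_shape, dtype=bool)
        ms_mask[0] = True
        r_px = im.soma_radius_um / im.pixel_size_um[0]
        centers = _grid_positions(
            rng, im.soma_count,
            (5, im.section_shape[0] - 5, 5, im.section_shape[1] - 5),
            min_sep_px=2.6 * r_px,
        )
        for cy, cx in centers:
            paint_disk(soma[0], (cy, cx), r_px, im.signal_level)
        if im.noise_sd > 0:
            soma = soma + rng.standard_normal(ms_shape) * im.noise_sd

        volume = LabeledVolume(channels={"YFP": yfp}, voxel_size_um=vs)
        ms_volume = LabeledVolume(
            channels={"YFP_soma": soma},
            voxel_size_um=(40.0, *im.pixel_size_um),
        )
        rois = {
            "hilus": RoiMask(name="hilus", mask=hilus),
            "MS": RoiMask(name="MS", mask=ms_mask),
        }
        truth = GroundTruth(
            process_count=im.process_count,
            process_volumes_um3=np.asarray(volumes),
            total_tube_volume_um3=float(np.sum(volumes)),
            soma_count=im.soma_count,
        )
        # stash the companion soma image on the volume for pipeline use
        volume.ms_soma_volume = ms_volume
        return volume, rois, truth

    if mode == "retrograde_sections":
        shape = (1, *im.section_shape)
        px = im.pixel_size_um
        px_area = px[0] * px[1]
        mcherry = np.full(shape, im.background_level, dtype=float)
        gaba = np.full(shape, im.background_level, dtype=float)
        r_px = im.soma_radius_um / px[0]

        # tile region boxes over the section
        names = list(RETRO_REGION_WEIGHTS) + ["starter-DG"]
        ncols = 4
        nrows = math.ceil(len(names) / ncols)
        h, w = im.section_shape
        bh, bw = h // nrows, w // ncols
        rois: dict[str, RoiMask] = {}
        region_counts: dict[str, int] = {}
        region_areas: dict[str, float] = {}
        coloc_total = 0
        n_ms = 0

        for i, name in enumerate(names):
            r0, c0 = (i // ncols) * bh, (i % ncols) * bw
            mask = np.zeros(shape, dtype=bool)
            mask[0, r0 + 2 : r0 + bh - 2, c0 + 2 : c0 + bw - 2] = True
            rois[name] = RoiMask(name=name, mask=mask)
            if name == "starter-DG":
                # starter cells: painted somata in the DG box
                n = max(4, im.soma_count // 4)
            else:
                n = int(round(im.soma_count * RETRO_REGION_WEIGHTS[name]))
            if name == "MS":
                n = im.soma_count  # MS carries the configured soma count
            centers = _grid_positions(
                rng, n, (r0 + 6, r0 + bh - 6, c0 + 6, c0 + bw - 6), min_sep_px=2.6 * r_px
            )
            painted = 0
            for cy, cx in centers:
                painted += paint_disk(mcherry[0], (cy, cx), r_px, im.signal_level)
            region_counts[name] = n
            region_areas[name] = painted * px_area
            if name == "MS":
                n_ms = n
                coloc = rng.uniform(size=n) < im.colocalization_fraction
                coloc_total = int(coloc.sum())
                for (cy, cx), is_pos in zip(centers, coloc):
                    if is_pos:
                        paint_disk(gaba[0], (cy, cx), r_px, im.signal_level)

        if im.noise_sd > 0:
            mcherry = mcherry + rng.standard_normal(shape) * im.noise_sd
            gaba = gaba + rng.standard_normal(shape) * im.noise_sd

        volume = LabeledVolume(
            channels={"mCherry": mcherry, "GABA": gaba},
            voxel_size_um=(40.0, *px),
        )
        truth = GroundTruth(
            region_counts=region_counts,
            region_areas_um2=region_areas,
            starter_area_um2=region_areas["starter-DG"],
            soma_count=n_ms,
            colocalized_count=coloc_total,
            colocalized_fraction=coloc_total / n_ms if n_ms else None,
        )
        return volume, rois, truth

    raise ValueError(f"unknown mode {mode!r}")
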