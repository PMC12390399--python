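"""Synthetic UWB radar-scene simulator.

Generates labelled frame sequences with the statistical structure the
processing pipeline assumes: a strong static cross-antenna coupling return
near zero delay, static furniture clutter, a breathing torso reflector whose
range depends on posture (ceiling radar looking down: a standing torso is
*closer* than a seated one), and class-specific limb micro-motions —
intermittent small-amplitude hand motion for "working", slow large-amplitude
arm sweeps for "stretching".  The emulated geometry is a 2.6 m-high office:
desk at 0.75 m (seated) or 1.0 m (standing), chair seat at 0.5 m, with the
radar's unambiguous one-way range capped at 3 m.

The transmitted pulse is a Gaussian-modulated cosine spanning the 3.1-4.8 GHz
operating band.  Echoes are rendered by evaluating the continuous pulse at
the exact round-trip delay 2R(t)/c, so sub-bin range modulation (breathing,
constant-velocity motion) produces physically correct carrier-phase rotation
and hence the expected Doppler content downstream.

All randomness flows from explicit seeds; identical seeds give identical
recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .radar_io import (
    BIN_SPACING_PS,
    CLASSES,
    FRAME_PERIOD_MS,
    N_BINS,
    SPEED_OF_LIGHT,
    DatasetManifest,
    FrameSequence,
    ManifestEntry,
    write_recording,
)

logger = logging.getLogger(__name__)

#: Default pulse parameters: band midpoint and -6 dB bandwidth of the
#: 3.1-4.8 GHz operating band.
CENTER_FREQUENCY_GHZ = 3.95
BANDWIDTH_GHZ = 1.7

#: Maximum one-way range covered by a frame (6 m round trip).
MAX_RANGE_M = 3.0


# ---------------------------------------------------------------------------
# Pulse
# ---------------------------------------------------------------------------

@dataclass
class PulseTemplate:
    """Gaussian-modulated cosine pulse, unit energy at the native bin spacing.

    ``taps`` is the pulse sampled at ``bin_spacing`` over +/-4 sigma; the
    continuous waveform ``scale * exp(-t^2/(2 sigma^2)) * cos(2 pi fc t)`` is
    kept so echoes can be rendered at arbitrary sub-bin delays.
    """

    taps: np.ndarray
    center_frequency: float  # GHz
    bandwidth: float  # GHz
    bin_spacing: float  # ps
    sigma_s: float  # Gaussian envelope std-dev, seconds
    scale: float  # amplitude normalizer giving unit tap energy

    @property
    def half_width_s(self) -> float:
        """Half support of the rendered pulse (4 sigma), seconds."""
        return 4.0 * self.sigma_s

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Continuous pulse amplitude at times ``t`` (s, centered on 0)."""
        t = np.asarray(t, dtype=np.float64)
        env = np.exp(-(t ** 2) / (2.0 * self.sigma_s ** 2))
        return self.scale * env * np.cos(2e9 * np.pi * self.center_frequency * t)


def make_pulse(
    center_frequency: float = CENTER_FREQUENCY_GHZ,
    bandwidth: float = BANDWIDTH_GHZ,
    bin_spacing: float = BIN_SPACING_PS,
) -> PulseTemplate:
    """Build the transmit pulse template.

    The Gaussian envelope width is chosen so that the -6 dB spectral extent
    of the pulse equals ``bandwidth``: for an amplitude spectrum
    ``exp(-(2 pi f)^2 sigma^2 / 2)``, half-amplitude at ``f = bandwidth/2``
    gives ``sigma = sqrt(2 ln 2) / (pi * bandwidth)``.

    Raises
    ------
    ValueError
        If the carrier is under-sampled at ``bin_spacing`` (fewer than two
        bins per carrier period would alias), or bandwidth is non-physical.
    """
    if not (0.0 < bandwidth < 2.0 * center_frequency):
        raise ValueError(f"bandwidth {bandwidth} GHz invalid for fc={center_frequency} GHz")
    dt = bin_spacing * 1e-12
    carrier_period = 1.0 / (center_frequency * 1e9)
    if carrier_period / dt < 2.0:
        raise ValueError(
            f"bin_spacing {bin_spacing} ps too coarse for {center_frequency} GHz "
            f"carrier ({carrier_period / dt:.2f} bins per period < 2): aliasing"
        )
    sigma = np.sqrt(2.0 * np.log(2.0)) / (np.pi * bandwidth * 1e9)
    half = int(np.ceil(4.0 * sigma / dt))
    t = np.arange(-half, half + 1) * dt
    raw = np.exp(-(t ** 2) / (2.0 * sigma ** 2)) * np.cos(
        2e9 * np.pi * center_frequency * t
    )
    scale = 1.0 / np.sqrt(np.sum(raw ** 2))
    return PulseTemplate(
        taps=(raw * scale).astype(np.float64),
        center_frequency=center_frequency,
        bandwidth=bandwidth,
        bin_spacing=bin_spacing,
        sigma_s=sigma,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Scene building blocks
# ---------------------------------------------------------------------------

@dataclass
class Scatterer:
    """A point reflector with a one-way range trajectory R(t) in metres."""

    range_trajectory: Callable[[np.ndarray], np.ndarray]
    amplitude: float
    kind: str  # one of {coupling, clutter, torso, limb}

    def ranges(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.range_trajectory(np.asarray(t, dtype=np.float64)),
                          dtype=np.float64)


def static_scatterer(range_m: float, amplitude: float, kind: str) -> Scatterer:
    return Scatterer(lambda t, r=range_m: np.full_like(t, r, dtype=np.float64),
                     amplitude, kind)


@dataclass
class ParticipantProfile:
    """Per-person variability: body position, reflectivity and kinematics."""

    torso_range_offset: float  # m
    reflectivity_scale: float
    breathing_rate: float  # Hz
    breathing_amplitude: float  # m
    limb_motion_rate_scale: float
    seed: int


def sample_participant(seed: int) -> ParticipantProfile:
    """Draw a participant profile; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    return ParticipantProfile(
        torso_range_offset=float(rng.uniform(-0.10, 0.10)),
        reflectivity_scale=float(rng.uniform(0.7, 1.3)),
        breathing_rate=float(rng.uniform(0.15, 0.35)),
        breathing_amplitude=float(rng.uniform(0.002, 0.008)),
        limb_motion_rate_scale=float(rng.uniform(0.8, 1.2)),
        seed=int(seed),
    )


def _default_noise_sigma() -> float:
    # Single-frame peak SNR of a unit-reflectivity torso return ~= 20 dB:
    # sigma = (pulse peak amplitude) / 10.
    return float(np.max(np.abs(make_pulse().taps))) / 10.0


@dataclass
class SceneConfig:
    """Office geometry and noise/clutter configuration."""

    radar_height: float = 2.6  # m, ceiling mount looking down
    desk_height_seated: float = 0.75
    desk_height_standing: float = 1.0
    chair_seat_height: float = 0.5
    noise_sigma: float = field(default_factory=_default_noise_sigma)
    clutter: Optional[list[Scatterer]] = None  # None -> drawn per recording
    coupling_amplitude: float = 3.0
    coupling_range: float = 0.05  # m, near zero delay

    def __post_init__(self) -> None:
        for name in ("desk_height_seated", "desk_height_standing", "chair_seat_height"):
            h = getattr(self, name)
            if not (0.0 < h <= self.radar_height):
                raise ValueError(f"{name}={h} must be positive and <= radar_height")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_sequence(
    scatterers: Sequence[Scatterer],
    times: np.ndarray,
    pulse: PulseTemplate,
    n_bins: int = N_BINS,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render frames at slow-time stamps ``times`` by linear superposition.

    Each scatterer contributes ``amplitude * p(t_bin - 2 R(t)/c)``; white
    Gaussian noise of scale ``noise_sigma`` is added per sample.  Scatterers
    whose delay falls beyond the fast-time span are clipped (logged once).
    """
    times = np.asarray(times, dtype=np.float64)
    dt = pulse.bin_spacing * 1e-12
    t_bins = np.arange(n_bins) * dt
    span = t_bins[-1] + pulse.half_width_s
    frames = np.zeros((times.size, n_bins), dtype=np.float64)
    clipped = False
    for s in scatterers:
        tau = 2.0 * s.ranges(times) / SPEED_OF_LIGHT  # (n_frames,)
        visible = tau <= span
        if not np.all(visible):
            clipped = True
        if not np.any(visible):
            continue
        # (n_frames, n_bins) evaluation of the continuous pulse
        rel = t_bins[None, :] - tau[visible, None]
        frames[visible] += s.amplitude * pulse.evaluate(rel)
    if clipped:
        logger.warning("scatterer delay beyond fast-time span: clipped")
    if noise_sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    return frames.astype(np.float32)


def render_frame(
    scatterers: Sequence[Scatterer],
    t: float,
    pulse: PulseTemplate,
    n_bins: int = N_BINS,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a single frame at slow time ``t`` (see :func:`render_sequence`)."""
    if n_bins < pulse.taps.size:
        raise ValueError(f"n_bins={n_bins} smaller than pulse support {pulse.taps.size}")
    return render_sequence(scatterers, np.array([t]), pulse, n_bins,
                           noise_sigma, rng)[0]


# ---------------------------------------------------------------------------
# Class-specific scene composition
# ---------------------------------------------------------------------------

def _burst_schedule(rng: np.random.Generator, duration: float):
    """Intermittent typing bursts: 1-3 s of motion between 1-5 s pauses."""
    events = []  # (start, stop, amplitude_m, rate_hz, phase)
    t = float(rng.uniform(0.0, 2.0))
    while t < duration:
        burst = float(rng.uniform(1.0, 3.0))
        events.append(
            (t, min(t + burst, duration),
             float(rng.uniform(0.01, 0.03)),
             float(rng.uniform(2.0, 5.0)),
             float(rng.uniform(0.0, 2.0 * np.pi)))
        )
        t += burst + float(rng.uniform(1.0, 5.0))
    return events


def _intermittent_limb(base_range: float, events, rate_scale: float) -> Callable:
    def traj(t: np.ndarray) -> np.ndarray:
        r = np.full_like(t, base_range, dtype=np.float64)
        for start, stop, amp, rate, phase in events:
            gate = (t >= start) & (t < stop)
            r[gate] += amp * np.sin(2.0 * np.pi * rate * rate_scale * (t[gate] - start)
                                    + phase)
        return r
    return traj


def _stretch_arm(base_range: float, amp: float, rate: float, phase: float) -> Callable:
    # Arm raised toward the ceiling radar: range decreases by up to `amp`.
    def traj(t: np.ndarray) -> np.ndarray:
        lift = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * rate * t + phase))
        return np.maximum(base_range - lift, 0.05)
    return traj


def compose_scene(
    scene: SceneConfig,
    profile: ParticipantProfile,
    class_label: str,
    rng: np.random.Generator,
    duration: float,
) -> list[Scatterer]:
    """Build the scatterer list for one recording of the given class."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label: {class_label!r}")
    scatterers: list[Scatterer] = []
    if scene.coupling_amplitude > 0.0:
        scatterers.append(
            static_scatterer(scene.coupling_range, scene.coupling_amplitude, "coupling")
        )
    if scene.clutter is not None:
        scatterers.extend(scene.clutter)
    else:
        for _ in range(int(rng.integers(2, 5))):
            scatterers.append(
                static_scatterer(
                    float(rng.uniform(1.55, min(scene.radar_height, MAX_RANGE_M))),
                    float(rng.uniform(0.2, 0.6)),
                    "clutter",
                )
            )
    if class_label == "empty":
        return scatterers

    seated = class_label.startswith("seated")
    if seated:
        torso_height = scene.chair_seat_height + float(rng.uniform(0.6, 0.8))
        desk_height = scene.desk_height_seated
    else:
        torso_height = float(rng.uniform(1.5, 1.8))  # standing stature
        desk_height = scene.desk_height_standing
    torso_range = scene.radar_height - torso_height + profile.torso_range_offset
    torso_range = float(np.clip(torso_range, 0.1, MAX_RANGE_M))

    f_b, a_b = profile.breathing_rate, profile.breathing_amplitude
    phase_b = float(rng.uniform(0.0, 2.0 * np.pi))
    scatterers.append(
        Scatterer(
            lambda t, r=torso_range: r + a_b * np.sin(2.0 * np.pi * f_b * t + phase_b),
            1.0 * profile.reflectivity_scale,
            "torso",
        )
    )

    if class_label.endswith("working"):
        hand_range = scene.radar_height - desk_height + profile.torso_range_offset
        events = _burst_schedule(rng, duration)
        scatterers.append(
            Scatterer(
                _intermittent_limb(hand_range, events, profile.limb_motion_rate_scale),
                0.4 * profile.reflectivity_scale,
                "limb",
            )
        )
    else:  # stretching: two arms, slow large sweeps
        for k in range(2):
            scatterers.append(
                Scatterer(
                    _stretch_arm(
                        torso_range + float(rng.uniform(-0.05, 0.1)),
                        float(rng.uniform(0.3, 0.5)),
                        float(rng.uniform(0.2, 0.5)) * profile.limb_motion_rate_scale,
                        float(rng.uniform(0.0, 2.0 * np.pi)),
                    ),
                    0.6 * profile.reflectivity_scale,
                    "limb",
                )
            )
    return scatterers


def simulate_recording(
    scene: SceneConfig,
    profile: ParticipantProfile,
    class_label: str,
    duration: float,
    seed: int,
    pulse: Optional[PulseTemplate] = None,
    n_bins: int = N_BINS,
    start_time: float = 0.0,
    participant_id: Optional[str] = None,
) -> FrameSequence:
    """Simulate one labelled recording of ``duration`` seconds at 12 ms frames."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label: {class_label!r}")
    pulse = pulse or make_pulse()
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / (FRAME_PERIOD_MS / 1000.0)))
    times = np.arange(n_frames) * (FRAME_PERIOD_MS / 1000.0)
    scatterers = compose_scene(scene, profile, class_label, rng, duration)
    frames = render_sequence(scatterers, times, pulse, n_bins,
                             scene.noise_sigma, rng)
    return FrameSequence(
        frames=frames,
        frame_period=FRAME_PERIOD_MS,
        bin_spacing=pulse.bin_spacing,
        start_time=start_time,
        participant_id=participant_id,
        class_label=class_label,
    )


def motion_profile(seq: FrameSequence) -> np.ndarray:
    """Per-bin slow-time standard deviation: where motion energy lives."""
    return np.std(seq.frames.astype(np.float64), axis=0)


# ---------------------------------------------------------------------------
# Protocol-level dataset generation
# ---------------------------------------------------------------------------

def _child_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_dataset(
    n_participants: int,
    out_dir: str,
    posture_duration: float = 180.0,
    empty_duration: float = 1800.0,
    master_seed: int = 0,
    scene: Optional[SceneConfig] = None,
) -> DatasetManifest:
    """Generate the full study protocol and write recordings to ``out_dir``.

    Per participant: one recording per posture class of ``posture_duration``
    seconds.  The single ``empty_duration`` of unoccupied-room time is
    partitioned into ``n_participants`` equal disjoint blocks, one block
    attributed to each participant, so leave-one-subject-out folds stay
    disjoint even for the person-independent empty class.
    """
    import os

    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    period = FRAME_PERIOD_MS / 1000.0
    empty_block = empty_duration / n_participants
    for name, dur in (("posture_duration", posture_duration),
                      ("empty block duration", empty_block)):
        n = dur / period
        if dur <= 0 or abs(n - round(n)) > 1e-6:
            raise ValueError(f"{name} ({dur} s) is not a positive multiple of the "
                             f"{period * 1000:.0f} ms frame period")
    scene = scene or SceneConfig()
    pulse = make_pulse()
    os.makedirs(out_dir, exist_ok=True)
    manifest = DatasetManifest()
    posture_classes = [c for c in CLASSES if c != "empty"]
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        profile = sample_participant(_child_seed(master_seed, p, 0))
        for ci, cls in enumerate(posture_classes):
            seed = _child_seed(master_seed, p, 1 + ci)
            seq = simulate_recording(scene, profile, cls, posture_duration, seed,
                                     pulse=pulse, participant_id=pid)
            path = os.path.join(out_dir, f"{pid}_{cls}.h5")
            write_recording(seq, path)
            manifest.entries.append(
                ManifestEntry(path, pid, cls, posture_duration, seed)
            )
        seed = _child_seed(master_seed, p, 99)
        seq = simulate_recording(scene, profile, "empty", empty_block, seed,
                                 pulse=pulse, start_time=p * empty_block,
                                 participant_id=pid)
        path = os.path.join(out_dir, f"{pid}_empty.h5")
        write_recording(seq, path)
        manifest.entries.append(ManifestEntry(path, pid, "empty", empty_block, seed))
    manifest.validate()
    return manifest
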