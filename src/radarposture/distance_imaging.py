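"""Distance-image generation.

Turns a raw 12 ms frame sequence into 96x288 8-bit "distance images" that
show motion-envelope intensity over (slow time x range):

1. stride-4 sub-sampling into four temporally shifted sub-sequences with an
   effective 48 ms frame period (a 4x data augmentation);
2. 4.8 s sliding-window segmentation (100 frames, 75% overlap, 25-frame hop);
3. per segment: fast-time band-pass IIR -> slow-time high-pass FIR (the
   first 4 outputs are dropped to remove the filter edge, 100 -> 96 frames)
   -> absolute value -> slow-time low-pass IIR envelope -> non-linear
   amplitude squashing x / (1 + 1.05^(30 - x)) -> min-max normalization to
   8-bit.

The slow-time FIR has exactly zero DC gain, so a segment that is constant
along slow time (a static scene) maps to an identically zero image before
normalization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .radar_io import FRAME_PERIOD_MS, FrameSequence

#: Segment geometry: 4.8 s of the 48 ms sub-sequence.
WINDOW_FRAMES = 100
OVERLAP_FRACTION = 0.75
#: Slow-time frames retained after the FIR edge is dropped.
IMAGE_ROWS = 96
#: FIR length implied by the 100 -> 96 frame reduction.
FIR_TAPS = 5

SUBSAMPLE_STRIDE = 4


@dataclass
class SubSequence:
    """One of the four stride-4 sub-sequences of a raw recording."""

    frames: np.ndarray  # (m, n_bins)
    offset: int  # o in {0,1,2,3}
    frame_period: float  # ms, 48.0
    participant_id: Optional[str] = None
    class_label: Optional[str] = None
    start_time: float = 0.0

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class Segment:
    """A 100-frame (4.8 s) slow-time window of a sub-sequence."""

    frames: np.ndarray  # (100, n_bins)
    window_index: int
    start_time: float  # s, in the parent recording's clock
    offset: int
    participant_id: Optional[str] = None
    class_label: Optional[str] = None


@dataclass
class DistanceImage:
    """96x288 8-bit motion-envelope image plus provenance metadata."""

    pixels: np.ndarray  # (96, n_bins) uint8
    participant_id: Optional[str] = None
    class_label: Optional[str] = None
    window_index: int = 0
    offset: int = 0


def subsample(seq: FrameSequence, offset: int) -> SubSequence:
    """Extract sub-sequence ``{x_{o+4k}}`` with effective 48 ms frame period.

    The four offsets partition the parent frames exactly; interleaving the
    four sub-sequences reconstructs the parent.
    """
    if offset not in (0, 1, 2, 3):
        raise ValueError(f"offset must be in {{0,1,2,3}}, got {offset}")
    return SubSequence(
        frames=seq.frames[offset::SUBSAMPLE_STRIDE],
        offset=offset,
        frame_period=SUBSAMPLE_STRIDE * seq.frame_period,
        participant_id=seq.participant_id,
        class_label=seq.class_label,
        start_time=seq.start_time,
    )


def window_segments(
    sub: SubSequence,
    window_frames: int = WINDOW_FRAMES,
    overlap_fraction: float = OVERLAP_FRACTION,
) -> list[Segment]:
    """Slice a sub-sequence into complete sliding windows.

    hop = window_frames * (1 - overlap_fraction); windows start at 0, hop,
    2*hop, ...; only complete windows are returned (count
    ``floor((m - window)/hop) + 1`` for m >= window, else none).
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    hop = int(round(window_frames * (1.0 - overlap_fraction)))
    hop = max(hop, 1)
    m = sub.n_frames
    segments = []
    for w, start in enumerate(range(0, m - window_frames + 1, hop)):
        segments.append(
            Segment(
                frames=sub.frames[start:start + window_frames],
                window_index=w,
                start_time=sub.start_time
                + (sub.offset + SUBSAMPLE_STRIDE * start) * FRAME_PERIOD_MS / 1000.0,
                offset=sub.offset,
                participant_id=sub.participant_id,
                class_label=sub.class_label,
            )
        )
    return segments


def squash(x):
    """Non-linear amplitude squashing ``x / (1 + 1.05^(30 - x))``.

    Attenuates residual low-level noise (output ~ 0 for small x) while
    approaching the identity for large x; squash(30) = 15 exactly.
    Elementwise over arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    # 1.05^(30-x) = exp((30-x) ln 1.05); clip the exponent to avoid overflow
    # for pathologically negative inputs.
    expo = np.clip((30.0 - x) * np.log(1.05), -700.0, 700.0)
    return x / (1.0 + np.exp(expo))


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

@dataclass
class FilterBank:
    """The three-stage filter chain of the distance pipeline.

    ``fast_time_bandpass`` and ``envelope_lowpass`` are recursive (IIR)
    ``(b, a)`` coefficient pairs; ``slow_time_highpass`` is a 5-tap FIR whose
    taps sum exactly to zero (no DC gain).  All filtering is causal.
    """

    fast_time_bandpass: tuple[np.ndarray, np.ndarray]
    slow_time_highpass: np.ndarray
    envelope_lowpass: tuple[np.ndarray, np.ndarray]

    def validate(self) -> None:
        if abs(float(np.sum(self.slow_time_highpass))) > 1e-12:
            raise ValueError("slow-time FIR taps must sum to 0")
        for name in ("fast_time_bandpass", "envelope_lowpass"):
            _, a = getattr(self, name)
            if np.any(np.abs(np.roots(a)) >= 1.0):
                raise ValueError(f"{name} is unstable")


def default_filter_bank(
    bin_spacing_ps: float = 61.0,
    passband_ghz: tuple[float, float] = (3.1, 4.8),
    slow_rate_hz: float = 1000.0 / (SUBSAMPLE_STRIDE * FRAME_PERIOD_MS),
    highpass_cutoff_hz: float = 1.0,
    envelope_cutoff_hz: float = 2.0,
) -> FilterBank:
    """Default filters: 4th-order Butterworth band-pass over the operating
    band along fast time; 5-tap windowed-sinc high-pass (rescaled to exact
    zero tap sum) along slow time; 2nd-order Butterworth envelope low-pass."""
    fast_fs = 1e12 / bin_spacing_ps  # ~16.39 GHz
    bp = signal.butter(4, [passband_ghz[0] * 1e9, passband_ghz[1] * 1e9],
                       btype="bandpass", fs=fast_fs)
    taps = signal.firwin(FIR_TAPS, highpass_cutoff_hz, fs=slow_rate_hz,
                         pass_zero=False)
    taps = taps - taps.mean()  # enforce exact zero DC gain
    lp = signal.butter(2, envelope_cutoff_hz, btype="lowpass", fs=slow_rate_hz)
    bank = FilterBank(
        fast_time_bandpass=(np.asarray(bp[0]), np.asarray(bp[1])),
        slow_time_highpass=np.asarray(taps),
        envelope_lowpass=(np.asarray(lp[0]), np.asarray(lp[1])),
    )
    bank.validate()
    return bank


_DEFAULT_BANK: Optional[FilterBank] = None


def _bank(filters: Optional[FilterBank]) -> FilterBank:
    global _DEFAULT_BANK
    if filters is not None:
        return filters
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = default_filter_bank()
    return _DEFAULT_BANK


# ---------------------------------------------------------------------------
# Image construction
# ---------------------------------------------------------------------------

def distance_intensity(
    segment: Segment, filters: Optional[FilterBank] = None
) -> np.ndarray:
    """Pre-normalization intensity: the filter chain up to and including the
    squashing stage.  Returns a ``(96, n_bins)`` float array."""
    filters = _bank(filters)
    x = np.asarray(segment.frames, dtype=np.float64)
    if x.shape[0] != WINDOW_FRAMES:
        raise ValueError(f"segment must have {WINDOW_FRAMES} frames, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    b, a = filters.fast_time_bandpass
    x = signal.lfilter(b, a, x, axis=1)  # fast time
    x = signal.lfilter(filters.slow_time_highpass, [1.0], x, axis=0)  # slow time
    x = x[FIR_TAPS - 1:]  # drop the FIR edge: 100 -> 96 frames
    x = np.abs(x)
    b, a = filters.envelope_lowpass
    x = signal.lfilter(b, a, x, axis=0)
    return squash(x)


def normalize_to_uint8(x: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 255], rounding half-up.

    A constant image (no dynamic range) maps to all zeros.
    """
    x = np.asarray(x, dtype=np.float64)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0.0:
        return np.zeros(x.shape, dtype=np.uint8)
    scaled = (x - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def make_distance_image(
    segment: Segment, filters: Optional[FilterBank] = None
) -> DistanceImage:
    """Run the full distance pipeline on one 100-frame segment.

    Output is a 96 x n_bins (288 for native recordings) 8-bit image;
    deterministic for fixed input and filters.
    """
    intensity = distance_intensity(segment, filters)
    return DistanceImage(
        pixels=normalize_to_uint8(intensity),
        participant_id=segment.participant_id,
        class_label=segment.class_label,
        window_index=segment.window_index,
        offset=segment.offset,
    )


def save_png(image, path: str | os.PathLike) -> None:
    """Write an 8-bit single-channel PNG (works for both image modalities)."""
    from PIL import Image

    Image.fromarray(image.pixels, mode="L").save(os.fspath(path))


def image_filename(image, prefix: str = "") -> str:
    """Canonical filename ``{participant}_{class}_{offset}_{window}.png``."""
    return (f"{prefix}{image.participant_id}_{image.class_label}"
            f"_{image.offset}_{image.window_index}.png")
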