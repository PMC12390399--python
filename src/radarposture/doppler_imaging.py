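"""Doppler-image generation.

A ceiling radar sees posture motion as radial velocity: a reflector moving
at v m/s toward the radar shifts the 3.95 GHz carrier by f_D = 2 v f_c / c
hertz.  This module recovers that signature from the raw 12 ms frame
sequence:

1. Hilbert transform along fast time turns each real frame into its
   analytic signal, so positive and negative Doppler (approach vs retreat)
   become distinguishable;
2. a short-time Fourier transform along slow time with an 83-frame (996 ms)
   Kaiser(beta=6) window and a 9-frame hop (~90% overlap); magnitudes are
   averaged across fast time to give one 80-bin Doppler row per window;
3. 4.8 s excerpts time-aligned with the distance segments are resampled to
   50 rows and min-max normalized to 8-bit, giving 50x80 Doppler images.

The STFT is computed once per recording at the native 12 ms rate (not on the
stride-4 sub-sequences); the four augmentation offsets of one time window
share the same underlying rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .radar_io import FRAME_PERIOD_MS, FrameSequence
from .distance_imaging import Segment, normalize_to_uint8

#: STFT geometry: 996 ms window = 83 frames at 12 ms, 9-frame hop.
STFT_WINDOW = 83
STFT_HOP = 9
KAISER_BETA = 6.0

#: Doppler image geometry.
IMAGE_ROWS = 50
IMAGE_BINS = 80
SEGMENT_SECONDS = 4.8

# 83 FFT bins are reduced to 80 by dropping the 2 most negative and the
# single most positive extreme bins after zero-centering; this keeps the
# axis as symmetric about 0 Hz as an even bin count allows.
_DROP_NEG = 2
_DROP_POS = 1


@dataclass
class DopplerMap:
    """Full-recording Doppler representation: one 80-bin row per STFT window."""

    rows: np.ndarray  # (n_rows, 80) non-negative magnitudes
    row_times: np.ndarray  # (n_rows,) window-center times, s
    frequency_axis: np.ndarray  # (80,) Hz, centered on 0

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])

    @property
    def t_min(self) -> float:
        """Start of the first STFT window (s)."""
        half = (STFT_WINDOW - 1) / 2.0 * FRAME_PERIOD_MS / 1000.0
        return float(self.row_times[0]) - half

    @property
    def t_max(self) -> float:
        """End of the last STFT window (s)."""
        half = (STFT_WINDOW - 1) / 2.0 * FRAME_PERIOD_MS / 1000.0
        return float(self.row_times[-1]) + half


@dataclass
class DopplerImage:
    """50x80 8-bit Doppler image with metadata matching its distance twin."""

    pixels: np.ndarray  # (50, 80) uint8
    participant_id: Optional[str] = None
    class_label: Optional[str] = None
    window_index: int = 0
    offset: int = 0


def analytic_signal(frames: np.ndarray) -> np.ndarray:
    """Hilbert transform along fast time (last axis).

    The real part of the output equals the input and negative-frequency
    content is suppressed.  Accepts a single frame or a frame matrix.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.shape[-1] < 2:
        raise ValueError("need at least 2 fast-time samples")
    if not np.all(np.isfinite(frames)):
        raise ValueError("non-finite input")
    return signal.hilbert(frames, axis=-1)


def frequency_axis(frame_period_ms: float = FRAME_PERIOD_MS) -> np.ndarray:
    """Doppler frequencies (Hz) of the 80 retained bins, centered on 0."""
    fs = 1000.0 / frame_period_ms
    freqs = np.fft.fftshift(np.fft.fftfreq(STFT_WINDOW, d=1.0 / fs))
    return freqs[_DROP_NEG: STFT_WINDOW - _DROP_POS]


def doppler_row(window: np.ndarray) -> np.ndarray:
    """One Doppler row from 83 analytic frames.

    Per fast-time bin: taper the 83 slow-time samples with a Kaiser(beta=6)
    window, Fourier-transform along slow time, take magnitudes; then average
    across fast-time bins, zero-center the axis, and keep the central 80
    bins.
    """
    window = np.asarray(window)
    if window.shape[0] != STFT_WINDOW:
        raise ValueError(f"window must have {STFT_WINDOW} frames, got {window.shape[0]}")
    taper = np.kaiser(STFT_WINDOW, KAISER_BETA)
    spec = np.fft.fft(window * taper[:, None], axis=0)
    mag = np.abs(spec).mean(axis=1)
    mag = np.fft.fftshift(mag)
    return mag[_DROP_NEG: STFT_WINDOW - _DROP_POS]


def doppler_map(
    seq: FrameSequence, window: int = STFT_WINDOW, hop: int = STFT_HOP
) -> DopplerMap:
    """Sliding-window Doppler spectrogram of a full recording.

    Rows for window starts 0, hop, 2*hop, ...; ``floor((n-window)/hop) + 1``
    rows for n >= window, otherwise an empty map (with a warning).
    """
    import warnings

    period = seq.frame_period / 1000.0
    freqs = frequency_axis(seq.frame_period)
    n = seq.n_frames
    if n < window:
        warnings.warn(f"recording has {n} < {window} frames: empty Doppler map")
        return DopplerMap(rows=np.zeros((0, IMAGE_BINS)),
                          row_times=np.zeros(0), frequency_axis=freqs)
    analytic = analytic_signal(seq.frames)
    taper = np.kaiser(window, KAISER_BETA)
    starts = np.arange(0, n - window + 1, hop)
    rows = np.empty((starts.size, IMAGE_BINS))
    for i, s in enumerate(starts):
        spec = np.fft.fft(analytic[s:s + window] * taper[:, None], axis=0)
        mag = np.fft.fftshift(np.abs(spec).mean(axis=1))
        rows[i] = mag[_DROP_NEG: window - _DROP_POS]
    row_times = seq.start_time + (starts + (window - 1) / 2.0) * period
    return DopplerMap(rows=rows, row_times=row_times, frequency_axis=freqs)


def extract_doppler_image(
    dmap: DopplerMap,
    t_start: float,
    duration: float = SEGMENT_SECONDS,
    participant_id: Optional[str] = None,
    class_label: Optional[str] = None,
    window_index: int = 0,
    offset: int = 0,
) -> DopplerImage:
    """Extract a 50x80 image for the interval [t_start, t_start + duration].

    Rows whose center time falls inside the interval are selected and
    linearly resampled along time to exactly 50 rows, then min-max
    normalized to 8-bit.  The interval must lie within the map's time span
    (one hop of slack is allowed at the trailing edge, since the last STFT
    window can stop up to hop-1 frames short of the recording end).
    """
    if dmap.n_rows == 0:
        raise ValueError("empty Doppler map")
    t_end = t_start + duration
    period = STFT_HOP * FRAME_PERIOD_MS / 1000.0
    if t_start < dmap.t_min - 1e-9 or t_end > dmap.t_max + period + 1e-9:
        raise ValueError(
            f"interval [{t_start:.3f}, {t_end:.3f}] s outside Doppler map span "
            f"[{dmap.t_min:.3f}, {dmap.t_max:.3f}] s"
        )
    mask = (dmap.row_times >= t_start - 1e-9) & (dmap.row_times <= t_end + 1e-9)
    sel = np.flatnonzero(mask)
    if sel.size < 2:
        raise ValueError("interval covers fewer than 2 Doppler rows")
    src_t = dmap.row_times[sel]
    src = dmap.rows[sel]
    dst_t = np.linspace(src_t[0], src_t[-1], IMAGE_ROWS)
    resampled = np.empty((IMAGE_ROWS, src.shape[1]))
    for j in range(src.shape[1]):
        resampled[:, j] = np.interp(dst_t, src_t, src[:, j])
    return DopplerImage(
        pixels=normalize_to_uint8(resampled),
        participant_id=participant_id,
        class_label=class_label,
        window_index=window_index,
        offset=offset,
    )


def doppler_image_for_segment(dmap: DopplerMap, segment: Segment) -> DopplerImage:
    """The Doppler image time-aligned with a distance segment."""
    return extract_doppler_image(
        dmap,
        segment.start_time,
        participant_id=segment.participant_id,
        class_label=segment.class_label,
        window_index=segment.window_index,
        offset=segment.offset,
    )
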