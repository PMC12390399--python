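"""Raw radar data model and on-disk containers.

A monostatic impulse radar records one amplitude profile over propagation
delay ("fast time") every 12 ms; stacking consecutive frames yields a 2-D
matrix whose second axis ("slow time") carries motion information.  This
module defines the in-memory :class:`FrameSequence` for such recordings, a
self-describing HDF5 container for persistence, and a CSV dataset manifest.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
import pandas as pd

#: Canonical class order used everywhere a class index is needed
#: (matches the confusion-matrix ordering: empty, seated stretching,
#: standing stretching, seated working, standing working).
CLASSES = (
    "empty",
    "seated_stretching",
    "standing_stretching",
    "seated_working",
    "standing_working",
)

#: Raw recording frame period in milliseconds (one frame every 12 ms,
#: i.e. a slow-time rate of ~83.3 Hz).
FRAME_PERIOD_MS = 12.0

#: Fast-time bin spacing in picoseconds and bin count used by the simulator.
BIN_SPACING_PS = 61.0
N_BINS = 288

#: One-way propagation speed used for delay/range conversions (m/s).
SPEED_OF_LIGHT = 2.998e8


@dataclass
class FrameSequence:
    """A slow-time stack of fast-time amplitude frames with timing metadata.

    Parameters
    ----------
    frames
        ``(n_frames, n_bins)`` float array of echo amplitudes (ADC-like
        units).  All frames share the same fast-time axis.
    frame_period
        Slow-time sampling period in milliseconds (12.0 for raw recordings).
    bin_spacing
        Fast-time delay per bin, in picoseconds.
    start_time
        Absolute start time of the recording in seconds.
    participant_id, class_label
        Optional provenance metadata; ``class_label`` must be one of
        :data:`CLASSES` when present.
    """

    frames: np.ndarray
    frame_period: float = FRAME_PERIOD_MS
    bin_spacing: float = BIN_SPACING_PS
    start_time: float = 0.0
    participant_id: Optional[str] = None
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.frames.shape[1]) if self.frames.ndim == 2 else 0

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames * self.frame_period / 1000.0

    def times(self) -> np.ndarray:
        """Slow-time stamps (s) of each frame relative to ``start_time``."""
        return np.arange(self.n_frames) * self.frame_period / 1000.0


def validate_recording(seq: FrameSequence) -> list[str]:
    """Check :class:`FrameSequence` invariants; return one diagnostic per violation.

    Returns an empty list iff the sequence is valid.  Diagnostics name the
    offending field (and, for non-finite amplitudes, the coordinate).
    """
    diags: list[str] = []
    frames = np.asarray(seq.frames)
    if frames.ndim != 2:
        diags.append(
            f"frames: expected a 2-D (n_frames, n_bins) matrix, got ndim={frames.ndim}"
        )
    else:
        bad = np.argwhere(~np.isfinite(frames))
        for r, c in bad[:10]:
            diags.append(f"frames: non-finite amplitude at ({r}, {c})")
        if len(bad) > 10:
            diags.append(f"frames: {len(bad) - 10} further non-finite amplitudes")
    if not (np.isfinite(seq.frame_period) and seq.frame_period > 0):
        diags.append(f"frame_period: must be > 0, got {seq.frame_period}")
    if not (np.isfinite(seq.bin_spacing) and seq.bin_spacing > 0):
        diags.append(f"bin_spacing: must be > 0, got {seq.bin_spacing}")
    if seq.class_label is not None and seq.class_label not in CLASSES:
        diags.append(f"class_label: {seq.class_label!r} not in {CLASSES}")
    return diags


_SCALAR_ATTRS = ("frame_period_ms", "bin_spacing_ps", "start_time_s")


def write_recording(seq: FrameSequence, path: str | os.PathLike) -> None:
    """Persist a frame sequence to a self-describing HDF5 file.

    Layout: dataset ``/frames`` (float32, n_frames x n_bins) with scalar
    attributes ``frame_period_ms``, ``bin_spacing_ps``, ``start_time_s`` and,
    when present, ``participant_id`` / ``class_label``.  The file is fully
    self-describing: :func:`read_recording` needs no external manifest.

    Raises
    ------
    ValueError
        If the sequence violates an invariant (checked before any file is
        created, so a failed write leaves no artifact behind).
    """
    diags = validate_recording(seq)
    if diags:
        raise ValueError("invalid FrameSequence: " + "; ".join(diags))
    with h5py.File(os.fspath(path), "w") as f:
        d = f.create_dataset("frames", data=seq.frames.astype(np.float32))
        d.attrs["frame_period_ms"] = float(seq.frame_period)
        d.attrs["bin_spacing_ps"] = float(seq.bin_spacing)
        d.attrs["start_time_s"] = float(seq.start_time)
        if seq.participant_id is not None:
            d.attrs["participant_id"] = str(seq.participant_id)
        if seq.class_label is not None:
            d.attrs["class_label"] = str(seq.class_label)


def read_recording(path: str | os.PathLike) -> FrameSequence:
    """Load a frame sequence written by :func:`write_recording`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If the ``frames`` dataset or a mandatory scalar attribute is absent
        (the message names the missing item).
    ValueError
        If the stored matrix is not 2-D or violates an invariant.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise KeyError("missing attribute/dataset: frames")
        d = f["frames"]
        for attr in _SCALAR_ATTRS:
            if attr not in d.attrs:
                raise KeyError(f"missing attribute: {attr}")
        frames = np.asarray(d[()], dtype=np.float32)
        if frames.ndim != 2:
            raise ValueError(
                f"stored frames have ndim={frames.ndim}, expected a 2-D matrix"
            )
        seq = FrameSequence(
            frames=frames,
            frame_period=float(d.attrs["frame_period_ms"]),
            bin_spacing=float(d.attrs["bin_spacing_ps"]),
            start_time=float(d.attrs["start_time_s"]),
            participant_id=(
                str(d.attrs["participant_id"]) if "participant_id" in d.attrs else None
            ),
            class_label=(
                str(d.attrs["class_label"]) if "class_label" in d.attrs else None
            ),
        )
    diags = validate_recording(seq)
    if diags:
        raise ValueError("corrupt recording: " + "; ".join(diags))
    return seq


def export_csv(seq: FrameSequence, path: str | os.PathLike) -> None:
    """Write the frame matrix as CSV (one frame per row) for inspection."""
    np.savetxt(os.fspath(path), seq.frames, delimiter=",", fmt="%.6g")


@dataclass
class ManifestEntry:
    path: str
    participant_id: str
    class_label: str
    duration_s: float
    seed: int


@dataclass
class DatasetManifest:
    """Index of a generated dataset: one row per recording."""

    entries: list[ManifestEntry] = dataclasses.field(default_factory=list)

    def validate(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths are not unique")
        for e in self.entries:
            if not e.participant_id or not e.class_label:
                raise ValueError(f"manifest entry {e.path}: empty participant/class")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries])


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    manifest.validate()
    manifest.to_frame().to_csv(os.fspath(path), index=False)


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    df = pd.read_csv(os.fspath(path))
    m = DatasetManifest(
        entries=[
            ManifestEntry(
                path=str(r.path),
                participant_id=str(r.participant_id),
                class_label=str(r.class_label),
                duration_s=float(r.duration_s),
                seed=int(r.seed),
            )
            for r in df.itertuples()
        ]
    )
    m.validate()
    return m
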