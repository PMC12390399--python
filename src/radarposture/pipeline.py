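"""End-to-end plumbing: raw recordings -> paired distance/Doppler samples.

The Doppler map is computed once per recording at the native 12 ms rate;
distance segments come from the four stride-4 sub-sequences.  Each distance
segment is paired with the Doppler excerpt for the same absolute 4.8 s time
window, so the classifier sees two views of the same instant.  Segments
whose Doppler window would run past the end of the map are dropped (only the
trailing edge of a recording is affected).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .distance_imaging import (
    FilterBank,
    SUBSAMPLE_STRIDE,
    WINDOW_FRAMES,
    make_distance_image,
    subsample,
    window_segments,
)
from .doppler_imaging import doppler_image_for_segment, doppler_map
from .fusion_models import SamplePair
from .radar_io import CLASSES, FRAME_PERIOD_MS, DatasetManifest, FrameSequence, read_recording
from .scene_simulator import (
    SceneConfig,
    make_pulse,
    sample_participant,
    simulate_recording,
)


def recording_to_pairs(
    seq: FrameSequence,
    filters: Optional[FilterBank] = None,
    max_pairs: Optional[int] = None,
) -> list[SamplePair]:
    """All complete distance/Doppler sample pairs of one recording.

    Pairs are ordered by (window_index, offset) so that truncating with
    ``max_pairs`` keeps all four augmentation offsets represented.
    """
    dmap = doppler_map(seq)
    if dmap.n_rows == 0:
        return []
    pairs = []
    per_offset = [window_segments(subsample(seq, o)) for o in range(SUBSAMPLE_STRIDE)]
    n_windows = max((len(s) for s in per_offset), default=0)
    for w in range(n_windows):
        for o in range(SUBSAMPLE_STRIDE):
            if w >= len(per_offset[o]):
                continue
            segment = per_offset[o][w]
            t_end = segment.start_time + WINDOW_FRAMES * SUBSAMPLE_STRIDE * FRAME_PERIOD_MS / 1000.0
            if t_end > dmap.t_max + STFT_SLACK_S:
                continue
            dimg = make_distance_image(segment, filters)
            vimg = doppler_image_for_segment(dmap, segment)
            pairs.append(SamplePair.from_images(dimg, vimg))
            if max_pairs is not None and len(pairs) >= max_pairs:
                return pairs
    return pairs


#: Trailing slack allowed between a segment end and the last STFT window end
#: (the last window can stop up to hop-1 frames short of the recording end).
STFT_SLACK_S = 9 * FRAME_PERIOD_MS / 1000.0


def pairs_from_manifest(
    manifest: DatasetManifest,
    filters: Optional[FilterBank] = None,
    max_pairs_per_recording: Optional[int] = None,
) -> list[SamplePair]:
    pairs = []
    for entry in manifest.entries:
        seq = read_recording(entry.path)
        pairs.extend(recording_to_pairs(seq, filters, max_pairs_per_recording))
    return pairs


def duration_for_pairs(pairs_per_class: int) -> float:
    """Recording duration (s) guaranteeing ``pairs_per_class`` complete pairs.

    With q = ceil(pairs/4) windows per offset at a 25-frame hop on the 48 ms
    sub-sequence, plus the 100-frame window, plus slack for the STFT tail.
    """
    q = -(-pairs_per_class // SUBSAMPLE_STRIDE)
    hop = 25
    n_frames = SUBSAMPLE_STRIDE * ((q - 1) * hop + WINDOW_FRAMES) + 120
    return n_frames * FRAME_PERIOD_MS / 1000.0


def build_sample_dataset(
    n_participants: int = 4,
    pairs_per_class: int = 100,
    master_seed: int = 0,
    scene: Optional[SceneConfig] = None,
    filters: Optional[FilterBank] = None,
) -> list[SamplePair]:
    """Simulate an in-memory labelled dataset of paired samples.

    For every pseudo-participant and every class (empty time is attributed
    per participant as a disjoint block), a recording long enough for
    ``pairs_per_class`` pairs is simulated and processed end to end.
    """
    scene = scene or SceneConfig()
    pulse = make_pulse()
    duration = duration_for_pairs(pairs_per_class)
    dataset: list[SamplePair] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        profile = sample_participant(_seed(master_seed, p, 0))
        for ci, cls in enumerate(CLASSES):
            seq = simulate_recording(
                scene, profile, cls, duration, _seed(master_seed, p, 1 + ci),
                pulse=pulse, participant_id=pid,
            )
            dataset.extend(recording_to_pairs(seq, filters, pairs_per_class))
    return dataset


def _seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2 ** 31))
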