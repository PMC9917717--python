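"""Face-up event classification from head-pitch traces.

A raised face — roughly a proxy for looking at the partner instead of the
touch panel — is detected as an excursion of the z-scored head pitch
beyond +2 SD, a deliberately strict threshold that selects only a few
percent of video frames.  Per-sample states of the two participants are
combined into mutually exclusive ``both_up`` / ``self_up`` / ``other_up``
tracks, which later serve as event regressors (with ``self`` and
``other`` merged into ``either_up`` at the group stage, since self-up of
one participant is other-up of the partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, ParameterError
from .io import PoseSeries

__all__ = [
    "EventTracks",
    "zscore_pitch",
    "detect_face_up",
    "label_events",
    "build_design",
    "binary_track_from_epochs",
]

DEFAULT_THRESHOLD_SD = 2.0
DEFAULT_MIN_DURATION_S = 0.3
DEFAULT_MERGE_GAP_S = 0.2
DEFAULT_DELAY_S = 5.0


@dataclass
class EventTracks:
    """Sample-wise behavioral state of a dyad at the pose frame rate.

    ``both_up``, ``self_up_a`` and ``self_up_b`` are mutually exclusive;
    ``self_up_a`` (participant A up alone) is simultaneously *other-up*
    for participant B, so no separate other-up arrays are stored.
    """

    fs: float
    up_a: np.ndarray
    up_b: np.ndarray
    both_up: np.ndarray = field(default=None)  # type: ignore[assignment]
    self_up_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    self_up_b: np.ndarray = field(default=None)  # type: ignore[assignment]
    events: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def other_up_a(self) -> np.ndarray:
        """Partner-up-alone seen from A's perspective (= self_up_b)."""
        return self.self_up_b

    @property
    def other_up_b(self) -> np.ndarray:
        return self.self_up_a

    @property
    def either_up(self) -> np.ndarray:
        """Exactly one participant up (self_up ∪ other_up)."""
        return self.self_up_a | self.self_up_b

    def swapped(self) -> "EventTracks":
        """Relabel with participants A and B exchanged."""
        ev = self.events.copy()
        ev["label"] = ev["label"].map(
            {"both_up": "both_up", "self_up_A": "self_up_B", "self_up_B": "self_up_A"}
        )
        return EventTracks(fs=self.fs, up_a=self.up_b, up_b=self.up_a,
                           both_up=self.both_up, self_up_a=self.self_up_b,
                           self_up_b=self.self_up_a, events=ev)


def zscore_pitch(pose: PoseSeries, min_valid_s: float = 30.0) -> np.ndarray:
    """Z-score the pitch trace over the session's valid samples.

    The z-transform removes between-participant offsets (seating height,
    camera angle); invalid samples are excluded from the moments and stay
    NaN in the output.
    """
    valid = pose.valid & np.isfinite(pose.pitch)
    if valid.sum() < min_valid_s * pose.fs:
        raise ParameterError(
            f"only {valid.sum() / pose.fs:.1f} s of valid pose data "
            f"(need >= {min_valid_s} s)"
        )
    mu = pose.pitch[valid].mean()
    sd = pose.pitch[valid].std(ddof=0)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateInputError("pitch trace has zero variance")
    z = np.full(pose.pitch.shape, np.nan)
    z[valid] = (pose.pitch[valid] - mu) / sd
    return z


def detect_face_up(z: np.ndarray, threshold: float = DEFAULT_THRESHOLD_SD,
                   positive: bool = True) -> np.ndarray:
    """Binary face-up track: z beyond the threshold in the face-raising
    direction.  Invalid (NaN) samples are never classified as up."""
    z = np.asarray(z, dtype=float)
    signed = z if positive else -z
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(signed, nan=-np.inf) > threshold


def _morph(track: np.ndarray, fs: float, min_duration_s: float, merge_gap_s: float) -> np.ndarray:
    """Bridge sub-gap dips, then drop sub-duration runs (tracker-jitter cleanup)."""
    track = np.asarray(track, dtype=bool).copy()
    n = track.size
    if n == 0:
        return track
    merge_gap = int(round(merge_gap_s * fs))
    min_run = int(round(min_duration_s * fs))
    if merge_gap > 0 and track.any():
        off_runs = _runs(~track)
        for start, stop in off_runs:
            if 0 < start and stop < n and stop - start <= merge_gap:
                track[start:stop] = True
    if min_run > 0:
        for start, stop in _runs(track):
            if stop - start < min_run:
                track[start:stop] = False
    return track


def _runs(mask: np.ndarray) -> np.ndarray:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return edges.reshape(-1, 2)


def label_events(up_a: np.ndarray, up_b: np.ndarray, fs: float,
                 min_duration_s: float = DEFAULT_MIN_DURATION_S,
                 merge_gap_s: float = DEFAULT_MERGE_GAP_S) -> EventTracks:
    """Combine the two face-up tracks into both-up/self-up/other-up labels.

    Each track is first cleaned morphologically (gaps shorter than
    ``merge_gap_s`` bridged, runs shorter than ``min_duration_s`` dropped;
    set both to 0 to disable), then labeled sample-wise:
    ``both_up = A ∧ B``, ``self_up_A = A ∧ ¬B``, ``self_up_B = B ∧ ¬A``.
    An event list (onset_s, offset_s, label) is derived from the runs of
    each labeled track.
    """
    up_a = np.asarray(up_a, dtype=bool)
    up_b = np.asarray(up_b, dtype=bool)
    if up_a.shape != up_b.shape:
        raise AlignmentError(f"track shapes differ: {up_a.shape} vs {up_b.shape}")
    a = _morph(up_a, fs, min_duration_s, merge_gap_s)
    b = _morph(up_b, fs, min_duration_s, merge_gap_s)
    both = a & b
    self_a = a & ~b
    self_b = b & ~a
    rows = []
    for label, track in (("both_up", both), ("self_up_A", self_a), ("self_up_B", self_b)):
        for start, stop in _runs(track):
            rows.append({"onset_s": start / fs, "offset_s": stop / fs, "label": label})
    events = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])
    events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return EventTracks(fs=fs, up_a=a, up_b=b, both_up=both,
                       self_up_a=self_a, self_up_b=self_b, events=events)


def binary_track_from_epochs(epochs, fs: float, n_samples: int) -> np.ndarray:
    """Rasterize (onset_s, offset_s) epochs onto a sample grid."""
    track = np.zeros(n_samples, dtype=bool)
    for onset, offset in epochs:
        if offset < onset:
            raise ParameterError(f"epoch with offset {offset} before onset {onset}")
        i0 = max(int(np.ceil(onset * fs)), 0)
        i1 = min(int(np.ceil(offset * fs)), n_samples)
        track[i0:i1] = True
    return track


def build_design(tracks: EventTracks, n_samples: int, target_fs: float = 10.0,
                 delay_s: float = DEFAULT_DELAY_S, perspective: str = "A"):
    """Down-sample the behavioral tracks into a GLM design matrix.

    Regressors (``both_up``, ``self_up``, ``other_up`` from the stated
    participant's perspective, plus a constant) are resampled to
    ``target_fs`` by nearest-sample selection so they stay binary, and
    shifted forward by ``delay_s`` seconds relative to the response series
    to absorb the hemodynamic delay-of-peak: the regressor value at
    response time ``t`` is the behavioral state at ``t − delay_s``.
    Response samples earlier than ``delay_s`` have no defined regressor and
    are dropped; the returned ``valid`` boolean selects the usable rows of
    the response series.

    Returns ``(X, valid)`` where ``X`` is a DataFrame with columns
    ``const, both_up, self_up, other_up`` of length ``valid.sum()``.
    """
    if perspective == "A":
        self_up, other_up = tracks.self_up_a, tracks.self_up_b
    elif perspective == "B":
        self_up, other_up = tracks.self_up_b, tracks.self_up_a
    else:
        raise ParameterError(f"perspective must be 'A' or 'B', got {perspective!r}")
    t_target = np.arange(n_samples) / target_fs
    t_source = t_target - delay_s
    valid = t_source >= -0.5 / tracks.fs
    idx = np.clip(np.round(t_source * tracks.fs).astype(int), 0, tracks.up_a.size - 1)
    in_range = valid & (np.round(t_source * tracks.fs) <= tracks.up_a.size - 1)
    idx_v = idx[in_range]
    x = pd.DataFrame(
        {
            "const": 1.0,
            "both_up": tracks.both_up[idx_v].astype(float),
            "self_up": self_up[idx_v].astype(float),
            "other_up": other_up[idx_v].astype(float),
        }
    )
    return x, in_range
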