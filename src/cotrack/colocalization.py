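"""Frame-wise two-channel colocalization detection and dwell histograms.

Per frame, each channel-A particle is matched one-to-one to its nearest
channel-B particle within the search radius (greedy by ascending distance,
ties broken by the smaller B then A track id). A pair colocalized at frame
``f`` and again within ``1 + max_gap_frames`` frames extends the same event;
events are maximal runs. Events reaching the last frame of the movie or of
either track are flagged right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError
from .tracks import TrackSet


@dataclass(frozen=True)
class ColocalizationEvent:
    a_track: int
    b_track: int
    start_frame: int
    end_frame: int  # inclusive
    right_censored: bool
    left_censored: bool = False

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class DwellDistribution:
    """Binned duration distribution with censoring bookkeeping.

    ``counts[d]`` is the (possibly fractional, for deconvolved output) mass at
    duration ``d`` frames; index 0 exists so that a deconvolved distribution
    can place pure-random coincidences at true duration zero.
    """

    bin_width_s: float
    counts: np.ndarray
    censored_counts: np.ndarray
    n_events: int
    n_censored: int
    n_excluded: int
    kind: str  # observed | null | deconvolved

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.censored_counts = np.asarray(self.censored_counts, dtype=float)
        if self.kind not in {"observed", "null", "deconvolved"}:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")

    @property
    def durations_s(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.bin_width_s

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise DataError("cannot normalize an empty distribution")
        return self.counts / total


def detect_colocalizations(
    a: TrackSet,
    b: TrackSet,
    search_radius_um: float = 0.15,
    max_gap_frames: int = 0,
) -> list[ColocalizationEvent]:
    """Detect maximal colocalization events between two registered channels."""
    if search_radius_um <= 0:
        raise ConfigError("search_radius_um must be > 0")
    if max_gap_frames < 0:
        raise ConfigError("max_gap_frames must be >= 0")
    if a.dt_s != b.dt_s or a.n_frames != b.n_frames:
        raise DataError("channel track sets disagree on dt or n_frames")
    n_frames = a.n_frames

    a_frames = _per_frame_index(a, n_frames)
    b_frames = _per_frame_index(b, n_frames)
    a_present = {t.track_id: set(t.frames.tolist()) for t in a.tracks}
    b_present = {t.track_id: set(t.frames.tolist()) for t in b.tracks}

    active: dict[tuple[int, int], list[int]] = {}  # (a_id, b_id) -> [start, last]
    events: list[ColocalizationEvent] = []

    def joint_present(key: tuple[int, int], frame: int) -> bool:
        return frame in a_present[key[0]] and frame in b_present[key[1]]

    def close(key: tuple[int, int], start: int, last: int) -> None:
        # right-censored when the pair was unobservable throughout the whole
        # extension window after the event: had it still been together at any
        # jointly-detected frame within the gap window, the event would have
        # been extended, so a single observable frame makes the end informative
        censored = not any(
            joint_present(key, last + g)
            for g in range(1, max_gap_frames + 2)
            if last + g < n_frames
        )
        # left-censored when the start is uninformative: the pair was never
        # jointly observable (and apart) in the window before the event, so
        # this may be the continuation of an interrupted earlier event
        left = not any(
            joint_present(key, start - g)
            for g in range(1, max_gap_frames + 2)
            if start - g >= 0
        )
        events.append(ColocalizationEvent(key[0], key[1], start, last, censored, left))

    for f in range(n_frames):
        a_ids, a_xy = a_frames[f]
        b_ids, b_xy = b_frames[f]
        matches: list[tuple[int, int]] = []
        if len(a_ids) and len(b_ids):
            tree = cKDTree(b_xy)
            pairs = tree.query_ball_point(a_xy, search_radius_um)
            cands = []
            for i, hits in enumerate(pairs):
                for j in hits:
                    d = float(np.hypot(*(a_xy[i] - b_xy[j])))
                    cands.append((d, b_ids[j], a_ids[i]))
            cands.sort()
            used_a, used_b = set(), set()
            for d, b_id, a_id in cands:
                if a_id in used_a or b_id in used_b:
                    continue
                used_a.add(a_id)
                used_b.add(b_id)
                matches.append((a_id, b_id))
        # extend or open events
        for a_id, b_id in matches:
            key = (a_id, b_id)
            if key in active and f - active[key][1] <= 1 + max_gap_frames:
                active[key][1] = f
            else:
                if key in active:
                    close(key, *active[key])
                active[key] = [f, f]
        # close events that can no longer be extended
        for k in list(active):
            if f - active[k][1] > max_gap_frames:
                close(k, *active[k])
                del active[k]
    for k in sorted(active):
        close(k, *active[k])
    events.sort(key=lambda e: (e.start_frame, e.a_track, e.b_track))
    return events


def _per_frame_index(ts: TrackSet, n_frames: int):
    ids: list[list[int]] = [[] for _ in range(n_frames)]
    xys: list[list[np.ndarray]] = [[] for _ in range(n_frames)]
    for t in ts.tracks:
        for i, f in enumerate(t.frames):
            ids[f].append(t.track_id)
            xys[f].append(t.xy_um[i])
    return [
        (np.asarray(ids[f], dtype=int), np.asarray(xys[f], dtype=float).reshape(-1, 2))
        for f in range(n_frames)
    ]


def dwell_distribution(
    events: list[ColocalizationEvent],
    dt_s: float,
    min_duration_frames: int = 2,
    max_duration_frames: int | None = None,
    kind: str = "observed",
) -> DwellDistribution:
    """Histogram of event durations at bin width ``dt_s``.

    Events shorter than ``min_duration_frames`` are excluded (and counted);
    right-censored events are tallied in a separate histogram used downstream
    for censored rate fitting.
    """
    if max_duration_frames is None:
        max_duration_frames = max((e.duration_frames for e in events), default=1)
    counts = np.zeros(max_duration_frames + 1)
    censored = np.zeros(max_duration_frames + 1)
    n_events = n_censored = n_excluded = 0
    for e in events:
        d = e.duration_frames
        if d > max_duration_frames:
            raise DataError(f"event duration {d} exceeds max_duration_frames")
        if d < min_duration_frames:
            n_excluded += 1
            continue
        if e.right_censored:
            censored[d] += 1
            n_censored += 1
        else:
            counts[d] += 1
            n_events += 1
    return DwellDistribution(
        bin_width_s=dt_s,
        counts=counts,
        censored_counts=censored,
        n_events=n_events,
        n_censored=n_censored,
        n_excluded=n_excluded,
        kind=kind,
    )
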