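"""Track data model, tabular I/O, bead registration, and segment linking.

Conventions used throughout the package:

* frames are 0-based integers; time at frame ``f`` is ``f * dt_s``
* coordinates are planar, in micrometres
* a track's ``frames`` are strictly increasing but may contain holes after
  linking (a hole means the molecule was not detected at that frame)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

CSV_COLUMNS = ["field_id", "channel", "track_id", "frame", "x_um", "y_um", "intensity"]

#: canonical numeric formatting for the track CSV format (byte-stable round trip)
_COORD_FMT = "{:.6f}"
_INTENSITY_FMT = "{:.3f}"


@dataclass
class Track:
    """One molecule's time-ordered localizations in one channel."""

    field_id: str
    channel: str
    track_id: int
    frames: np.ndarray
    xy_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.xy_um.ndim != 2 or self.xy_um.shape[1] != 2:
            raise DataError(f"track {self.track_id}: xy_um must be (n, 2)")
        n = len(self.frames)
        if len(self.xy_um) != n or len(self.intensity) != n:
            raise DataError(f"track {self.track_id}: frames/xy/intensity length mismatch")
        if n == 0:
            raise DataError(f"track {self.track_id}: empty track")
        if np.any(np.diff(self.frames) <= 0):
            raise DataError(f"track {self.track_id}: frames not strictly increasing")

    @property
    def n_localizations(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])


@dataclass
class TrackSet:
    """A collection of tracks from one or more fields of view."""

    tracks: list[Track]
    field_area_um2: float
    dt_s: float
    n_frames: int

    @property
    def n_localizations(self) -> int:
        return sum(t.n_localizations for t in self.tracks)

    def channels(self) -> list[str]:
        return sorted({t.channel for t in self.tracks})

    def by_channel(self, channel: str) -> "TrackSet":
        return TrackSet(
            [t for t in self.tracks if t.channel == channel],
            self.field_area_um2,
            self.dt_s,
            self.n_frames,
        )

    def density_per_um2(self, channel: str | None = None) -> float:
        """Time-averaged localizations per frame per um^2."""
        tracks = self.tracks if channel is None else [t for t in self.tracks if t.channel == channel]
        n = sum(t.n_localizations for t in tracks)
        return n / self.n_frames / self.field_area_um2

    def mean_count_per_frame(self, channel: str | None = None) -> float:
        return self.density_per_um2(channel) * self.field_area_um2

    # ---------------------------------------------------------------- I/O

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for t in self.tracks:
            recs.append(
                pd.DataFrame(
                    {
                        "field_id": t.field_id,
                        "channel": t.channel,
                        "track_id": t.track_id,
                        "frame": t.frames,
                        "x_um": t.xy_um[:, 0],
                        "y_um": t.xy_um[:, 1],
                        "intensity": t.intensity,
                    }
                )
            )
        if not recs:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.concat(recs, ignore_index=True)[CSV_COLUMNS]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        field_area_um2: float,
        dt_s: float,
        n_frames: int | None = None,
    ) -> "TrackSet":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"track table missing columns: {missing}")
        if n_frames is None:
            n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        tracks = []
        for (fid, ch, tid), g in df.groupby(["field_id", "channel", "track_id"], sort=True):
            g = g.sort_values("frame")
            tracks.append(
                Track(
                    field_id=str(fid),
                    channel=str(ch),
                    track_id=int(tid),
                    frames=g["frame"].to_numpy(),
                    xy_um=g[["x_um", "y_um"]].to_numpy(),
                    intensity=g["intensity"].to_numpy(),
                )
            )
        return cls(tracks, field_area_um2, dt_s, n_frames)

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(",".join(CSV_COLUMNS) + "\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.field_id},{row.channel},{row.track_id},{row.frame},"
                    f"{_COORD_FMT.format(row.x_um)},{_COORD_FMT.format(row.y_um)},"
                    f"{_INTENSITY_FMT.format(row.intensity)}\n"
                )

    @classmethod
    def read_csv(cls, path, field_area_um2: float, dt_s: float, n_frames: int | None = None) -> "TrackSet":
        df = pd.read_csv(path, dtype={"field_id": str, "channel": str})
        return cls.from_dataframe(df, field_area_um2, dt_s, n_frames)


# ------------------------------------------------------------------ registration


@dataclass
class RegistrationModel:
    """Affine map from one channel's coordinate system into the other's."""

    matrix: np.ndarray  # shape (2, 3): [A | b], maps (x, y) -> A @ (x, y) + b
    rms_residual_um: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ConfigError("registration matrix must have shape (2, 3)")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "RegistrationModel":
        a = self.matrix[:, :2]
        b = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return RegistrationModel(np.column_stack([a_inv, -a_inv @ b]), self.rms_residual_um)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"matrix": self.matrix.tolist(), "rms_residual_um": self.rms_residual_um},
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "RegistrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["matrix"]), float(d["rms_residual_um"]))

    @classmethod
    def identity(cls) -> "RegistrationModel":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), 0.0)


def fit_registration(beads_src: np.ndarray, beads_dst: np.ndarray) -> RegistrationModel:
    """Least-squares affine map taking ``beads_src`` onto ``beads_dst``.

    Requires at least three non-collinear bead pairs.
    """
    src = np.asarray(beads_src, dtype=float)
    dst = np.asarray(beads_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise DataError("bead coordinate arrays must both have shape (n, 2)")
    n = len(src)
    if n < 3:
        raise DataError(f"need >= 3 bead pairs for an affine fit, got {n}")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1e-12):
        raise DataError("bead positions are collinear; affine map is degenerate")
    design = np.column_stack([src, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    matrix = coef.T  # (2, 3)
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationModel(matrix, rms)


def apply_registration(model: RegistrationModel, tracks: TrackSet, channel: str = "B") -> TrackSet:
    """Transform the coordinates of all tracks in ``channel``; all else unchanged."""
    out = []
    for t in tracks.tracks:
        if t.channel == channel:
            out.append(replace(t, xy_um=model.apply(t.xy_um)))
        else:
            out.append(t)
    return TrackSet(out, tracks.field_area_um2, tracks.dt_s, tracks.n_frames)


# ------------------------------------------------------------------ linking


def link_segments(
    tracks: TrackSet,
    max_gap_frames: int = 2,
    max_link_distance_um: float = 0.3,
) -> TrackSet:
    """Greedy nearest-neighbour repair of detection-dropout splits.

    A segment ending at frame ``f`` may continue as an unmatched segment
    starting at frame ``s`` with ``1 <= s - f <= max_gap_frames + 1`` (i.e. up
    to ``max_gap_frames`` missing frames are bridged), provided the start
    position is within ``max_link_distance_um`` of the end position. Candidates
    are consumed greedily by ascending distance, ties broken by the smaller
    candidate ``track_id``. Linked tracks keep the first segment's id; no
    localization is duplicated or lost.
    """
    if max_gap_frames < 0:
        raise ConfigError("max_gap_frames must be >= 0")
    linked_tracks: list[Track] = []
    for (fid, ch), group in _group_field_channel(tracks.tracks):
        segs = sorted(group, key=lambda t: (t.start_frame, t.track_id))
        successor: dict[int, int] = {}  # seg index -> seg index
        has_pred = set()
        starts_by_frame: dict[int, list[int]] = {}
        for i, s in enumerate(segs):
            starts_by_frame.setdefault(s.start_frame, []).append(i)
        open_enders: list[int] = []  # indices available to link forward
        ends = [s.end_frame for s in segs]
        for frame in sorted(starts_by_frame):
            # retire enders that are out of reach, admit newly-ended segments
            open_enders = [
                i
                for i in range(len(segs))
                if i not in successor
                and 1 <= frame - ends[i] <= max_gap_frames + 1
            ]
            starters = [i for i in starts_by_frame[frame] if i not in has_pred]
            if not open_enders or not starters:
                continue
            cands = []
            for i in open_enders:
                end_xy = segs[i].xy_um[-1]
                for j in starters:
                    if j == i:
                        continue
                    d = float(np.hypot(*(segs[j].xy_um[0] - end_xy)))
                    if d <= max_link_distance_um:
                        cands.append((d, segs[j].track_id, i, j))
            cands.sort()
            used_i, used_j = set(), set()
            for d, _, i, j in cands:
                if i in used_i or j in used_j:
                    continue
                successor[i] = j
                has_pred.add(j)
                used_i.add(i)
                used_j.add(j)
        # assemble chains
        for i, s in enumerate(segs):
            if i in has_pred:
                continue
            chain = [i]
            while chain[-1] in successor:
                chain.append(successor[chain[-1]])
            parts = [segs[k] for k in chain]
            linked_tracks.append(
                Track(
                    field_id=fid,
                    channel=ch,
                    track_id=parts[0].track_id,
                    frames=np.concatenate([p.frames for p in parts]),
                    xy_um=np.concatenate([p.xy_um for p in parts]),
                    intensity=np.concatenate([p.intensity for p in parts]),
                )
            )
    return TrackSet(linked_tracks, tracks.field_area_um2, tracks.dt_s, tracks.n_frames)


def _group_field_channel(tracks: Iterable[Track]):
    groups: dict[tuple[str, str], list[Track]] = {}
    for t in tracks:
        groups.setdefault((t.field_id, t.channel), []).append(t)
    return sorted(groups.items())
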