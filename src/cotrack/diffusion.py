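"""TAMSD computation, diffusion-coefficient fits, and confinement classification.

The confinement index follows the probability-level construction: for a
sliding window of duration ``t`` over which the trajectory's maximal
displacement from the window start is ``R``, the probability that a free
Brownian walker with diffusion coefficient ``D`` stays inside a region of
radius ``R`` is approximated by ``log10(psi) = 0.2048 - 2.5117 * D * t / R^2``,
and the index is ``L = -log10(psi) - 1`` for ``psi < 0.1`` (else 0). Frames in
sustained high-``L`` stretches are classified as confined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .tracks import Track

STATE_FREE = 0
STATE_CONFINED = 1
STATE_UNDEFINED = 2


@dataclass
class MSDProfile:
    lags_s: np.ndarray
    tamsd_um2: np.ndarray
    n_pairs: np.ndarray
    track_n_frames: int
    d_um2_s: float | None = None
    n_points_fit: int | None = None
    d_clipped: bool = False


@dataclass
class ConfinementAnnotation:
    field_id: str
    channel: str
    track_id: int
    frames: np.ndarray  # the track's frame numbers
    states: np.ndarray  # per-frame {STATE_FREE, STATE_CONFINED, STATE_UNDEFINED}
    confined_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_classifiable(self) -> int:
        return int(np.sum(self.states != STATE_UNDEFINED))

    @property
    def n_confined(self) -> int:
        return int(np.sum(self.states == STATE_CONFINED))

    def state_at(self, frame: int) -> int:
        idx = np.searchsorted(self.frames, frame)
        if idx >= len(self.frames) or self.frames[idx] != frame:
            return STATE_UNDEFINED
        return int(self.states[idx])


def compute_tamsd(track: Track, dt_s: float = 1.0, max_lag_fraction: float = 0.25) -> MSDProfile:
    """Time-averaged MSD; lag pairs spanning a detection gap are excluded."""
    if track.n_localizations < 2:
        raise DataError(f"track {track.track_id}: need >= 2 localizations for TAMSD")
    if not 0 < max_lag_fraction <= 1:
        raise ConfigError("max_lag_fraction must be in (0, 1]")
    frames = track.frames
    span = int(frames[-1] - frames[0]) + 1
    max_lag = max(1, int(span * max_lag_fraction))
    # frame-indexed positions (NaN at holes)
    pos = np.full((span, 2), np.nan)
    pos[frames - frames[0]] = track.xy_um
    lags = np.arange(1, max_lag + 1)
    tamsd = np.full(len(lags), np.nan)
    n_pairs = np.zeros(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        ok = ~np.isnan(sq)
        n_pairs[i] = ok.sum()
        if n_pairs[i]:
            tamsd[i] = float(np.mean(sq[ok]))
    valid = n_pairs > 0
    return MSDProfile(
        lags_s=lags[valid] * dt_s,
        tamsd_um2=tamsd[valid],
        n_pairs=n_pairs[valid],
        track_n_frames=span,
    )


def estimate_d(
    profile: MSDProfile,
    n_fit_points: int = 4,
    min_track_frames: int = 100,
) -> MSDProfile | None:
    """Weighted linear fit of the first TAMSD points; ``D = slope / 4``.

    Returns ``None`` (a skip signal, not an error) when the underlying track
    is shorter than ``min_track_frames``. The intercept absorbs the static
    localization-noise variance. A negative fitted slope is clipped to 0 and
    flagged.
    """
    if profile.track_n_frames < min_track_frames:
        return None
    n = min(n_fit_points, len(profile.lags_s))
    if n < 2:
        return None
    x = profile.lags_s[:n]
    y = profile.tamsd_um2[:n]
    w = profile.n_pairs[:n].astype(float)
    coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
    d = float(coeffs[0] / 4.0)
    clipped = d < 0
    return MSDProfile(
        lags_s=profile.lags_s,
        tamsd_um2=profile.tamsd_um2,
        n_pairs=profile.n_pairs,
        track_n_frames=profile.track_n_frames,
        d_um2_s=max(d, 0.0),
        n_points_fit=n,
        d_clipped=clipped,
    )


def classify_confinement(
    track: Track,
    d_reference: float,
    dt_s: float,
    window_frames: int = 30,
    threshold_L: float = 3.16,
    min_confined_frames: int = 10,
) -> ConfinementAnnotation:
    """Sliding-window probability-level confinement classification.

    Frames whose index ``L`` exceeds ``threshold_L`` for at least
    ``min_confined_frames`` consecutive frames are confined; the first and
    last half-windows (and frames whose window is interrupted by a detection
    gap) are undefined.
    """
    if d_reference <= 0:
        raise ConfigError("d_reference must be > 0")
    if track.n_localizations < window_frames:
        raise DataError(
            f"track {track.track_id}: shorter than the confinement window"
        )
    frames = track.frames
    span = int(frames[-1] - frames[0]) + 1
    pos = np.full((span, 2), np.nan)
    pos[frames - frames[0]] = track.xy_um
    half = window_frames // 2
    t_window = window_frames * dt_s
    n = len(frames)
    states = np.full(n, STATE_UNDEFINED, dtype=np.int8)
    l_values = np.full(n, np.nan)
    for i in range(n):
        center = frames[i] - frames[0]
        lo = center - half
        hi = lo + window_frames
        if lo < 0 or hi > span:
            continue
        window = pos[lo:hi]
        if np.isnan(window).any():
            continue
        delta = window - window[0]
        r2 = float(np.max(delta[:, 0] ** 2 + delta[:, 1] ** 2))
        if r2 <= 0:
            l_values[i] = np.inf
            continue
        log_psi = 0.2048 - 2.5117 * d_reference * t_window / r2
        l_values[i] = max(0.0, -log_psi - 1.0) if log_psi < -1.0 else 0.0
    defined = ~np.isnan(l_values)
    high = defined & (l_values > threshold_L)
    states[defined] = STATE_FREE
    # sustained high-L runs (in index space; frames are near-contiguous here)
    i = 0
    intervals: list[tuple[int, int]] = []
    while i < n:
        if high[i]:
            j = i
            while j + 1 < n and high[j + 1]:
                j += 1
            if j - i + 1 >= min_confined_frames:
                states[i : j + 1] = STATE_CONFINED
                intervals.append((int(frames[i]), int(frames[j])))
            i = j + 1
        else:
            i += 1
    return ConfinementAnnotation(
        field_id=track.field_id,
        channel=track.channel,
        track_id=track.track_id,
        frames=frames.copy(),
        states=states,
        confined_intervals=intervals,
    )


def confinement_proportions(
    annotations: list[ConfinementAnnotation],
    groups: dict[str, str],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell confined-frame proportions and per-group median with bootstrap CI.

    ``groups`` maps each cell (field) id to its condition label; the bootstrap
    resampling unit is the cell.
    """
    per_cell: dict[str, list[int]] = {}
    for ann in annotations:
        acc = per_cell.setdefault(ann.field_id, [0, 0])
        acc[0] += ann.n_confined
        acc[1] += ann.n_classifiable
    rows = []
    for cell, (conf, tot) in sorted(per_cell.items()):
        if cell not in groups:
            raise DataError(f"cell {cell!r} has no group label")
        if tot == 0:
            raise DataError(f"cell {cell!r} has no classifiable frames")
        rows.append((cell, groups[cell], conf / tot))
    cells_df = pd.DataFrame(rows, columns=["cell", "group", "proportion"])
    labelled = set(cells_df["group"])
    for g in set(groups.values()):
        if g not in labelled:
            raise DataError(f"group {g!r} has no cells with annotations")
    rng = np.random.default_rng(seed)
    out = []
    for g, gdf in cells_df.groupby("group", sort=True):
        vals = gdf["proportion"].to_numpy()
        med = float(np.median(vals))
        boots = np.median(
            rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out.append((g, med, min(float(lo), med), max(float(hi), med), len(vals)))
    summary = pd.DataFrame(out, columns=["group", "median", "ci_lo", "ci_hi", "n_cells"])
    return summary, cells_df


def population_median_d(
    tracks,
    dt_s: float,
    n_fit_points: int = 4,
    min_track_frames: int = 100,
) -> float:
    """Median fitted D over qualifying tracks (>= ``min_track_frames``)."""
    ds = []
    for t in tracks:
        if t.n_localizations < 2:
            continue
        prof = compute_tamsd(t, dt_s=dt_s)
        fit = estimate_d(prof, n_fit_points=n_fit_points, min_track_frames=min_track_frames)
        if fit is not None:
            ds.append(fit.d_um2_s)
    if not ds:
        raise DataError(f"no track reached {min_track_frames} frames; cannot estimate D")
    return float(np.median(ds))
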