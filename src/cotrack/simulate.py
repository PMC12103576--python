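"""Ground-truthed synthetic data generators.

Generates dual-channel membrane trajectory fields with reversible 1:1 A-B
binding, static confinement zones, localization noise, a fixed inter-channel
offset, and detection dropouts; plus photobleaching intensity traces and
plate-reader BRET tables. Every generator is fully deterministic given its
seed, and returns the ground truth needed to use it as an oracle.

Model notes (declared defaults, not claims about any particular instrument):

* the field is a periodic (toroidal) rectangle, which keeps densities constant;
* free molecules take Gaussian steps with per-axis variance ``2*D*dt``;
* inside a static disk-shaped confinement zone the diffusion coefficient is
  multiplied by ``d_confined_factor`` and steps crossing the zone boundary are
  reflected, escaping with probability ``escape_prob`` per boundary hit;
* each free A-B pair closer than ``reaction_radius_um`` binds with a per-frame
  hazard ``h`` (see :func:`calibrate_binding_hazard`); on binding the B
  molecule snaps to a small contact offset from its A partner and then shares
  the A molecule's displacement exactly; pairs separate with per-frame
  probability ``1 - exp(-koff*dt)``, after which the pair diffuses apart from
  the contact position but cannot rebind for ``rebind_refractory_s`` — this
  keeps dissociation from being erased by instant in-place rebinding while the
  post-dissociation departure retains the same statistics as a random
  colocalization (the structure the downstream deconvolution assumes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .tracks import Track, TrackSet


@dataclass
class SimulationConfig:
    """Parameters of one simulated dual-channel field of view."""

    field_width_um: float = 10.0
    field_height_um: float = 10.0
    n_frames: int = 400
    dt_s: float = 0.033
    density_a_per_um2: float = 0.42
    density_b_per_um2: float = 0.59
    d_free_um2_s: float = 0.1
    d_bound_um2_s: float = 0.05
    kon_um2_per_molecule_s: float = 0.3
    koff_per_s: float = 0.64
    reaction_radius_um: float = 0.05
    confinement_zone_radius_um: float = 0.1
    confinement_area_fraction: float = 0.0
    d_confined_factor: float = 0.1
    escape_prob: float = 0.1
    loc_sigma_um: float = 0.02
    registration_residual_um: float = 0.02
    dropout_prob: float = 0.05
    split_gap_frames: int = 1
    contact_offset_um: float = 0.02
    rebind_refractory_s: float = 1.0
    binding_hazard: float | None = None
    poisson_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "field_width_um",
            "field_height_um",
            "dt_s",
            "density_a_per_um2",
            "density_b_per_um2",
            "reaction_radius_um",
            "confinement_zone_radius_um",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        nonneg = [
            "d_free_um2_s",
            "d_bound_um2_s",
            "kon_um2_per_molecule_s",
            "koff_per_s",
            "loc_sigma_um",
            "registration_residual_um",
            "contact_offset_um",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ["confinement_area_fraction", "dropout_prob", "escape_prob"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.d_confined_factor <= 1.0:
            raise ConfigError("d_confined_factor must be in (0, 1]")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.expected_count("A") < 1 or self.expected_count("B") < 1:
            raise ConfigError("expected molecule count (density * area) must be >= 1 per channel")
        if self.binding_hazard is not None and not 0.0 <= self.binding_hazard <= 1.0:
            raise ConfigError("binding_hazard must be in [0, 1]")
        if self.koff_per_s * self.dt_s > 0.5:
            warnings.warn(
                "koff*dt > 0.5: the time step is too coarse to resolve dissociation",
                stacklevel=2,
            )

    @property
    def area_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    def expected_count(self, channel: str) -> float:
        rho = self.density_a_per_um2 if channel == "A" else self.density_b_per_um2
        return rho * self.area_um2

    @property
    def movie_duration_s(self) -> float:
        return self.n_frames * self.dt_s


@dataclass
class SimulationGroundTruth:
    """Oracle record written by :func:`simulate_field`."""

    bound_intervals: list[tuple[int, int, int, int]]  # (a_mol, b_mol, start, end) inclusive
    confined_intervals: dict[str, list[tuple[int, int]]]  # "A:3" -> [(start, end), ...]
    n_molecules_a: int
    n_molecules_b: int
    realized_density_a: float
    realized_density_b: float
    true_event_rate_per_s_um2: float
    b_offset_um: tuple[float, float]
    track_molecules: dict[int, tuple[str, int]]  # track_id -> (channel, molecule index)
    wrapped_molecules: set[str]  # molecule keys whose true path crossed the torus seam
    n_frames: int
    dt_s: float

    def mean_bound_duration_s(self) -> float:
        if not self.bound_intervals:
            raise DataError("no bound intervals in ground truth")
        durs = [(e - s + 1) * self.dt_s for _, _, s, e in self.bound_intervals]
        return float(np.mean(durs))

    def mean_bound_duration_mle_s(self) -> float:
        """Censoring-corrected mean bound duration.

        Intervals reaching the last frame are right-censored; the exponential
        MLE of the mean is total bound time over the number of completed
        (dissociation-terminated) intervals.
        """
        if not self.bound_intervals:
            raise DataError("no bound intervals in ground truth")
        total = sum((e - s + 1) * self.dt_s for _, _, s, e in self.bound_intervals)
        completed = sum(1 for _, _, s, e in self.bound_intervals if e < self.n_frames - 1)
        if completed == 0:
            raise DataError("all bound intervals are censored")
        return float(total / completed)

    def bound_durations_frames(self) -> np.ndarray:
        return np.array([e - s + 1 for _, _, s, e in self.bound_intervals], dtype=int)

    def molecule_tracks(self, channel: str, mol: int) -> list[int]:
        return sorted(t for t, (ch, m) in self.track_molecules.items() if ch == channel and m == mol)

    def to_json(self, path) -> None:
        d = {
            "bound_intervals": [list(t) for t in self.bound_intervals],
            "confined_intervals": {k: [list(t) for t in v] for k, v in self.confined_intervals.items()},
            "n_molecules_a": self.n_molecules_a,
            "n_molecules_b": self.n_molecules_b,
            "realized_density_a": self.realized_density_a,
            "realized_density_b": self.realized_density_b,
            "true_event_rate_per_s_um2": self.true_event_rate_per_s_um2,
            "b_offset_um": list(self.b_offset_um),
            "track_molecules": {str(k): list(v) for k, v in self.track_molecules.items()},
            "wrapped_molecules": sorted(self.wrapped_molecules),
            "n_frames": self.n_frames,
            "dt_s": self.dt_s,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def default_hazard(config: SimulationConfig) -> float:
    """Dilute-limit first guess for the per-frame binding hazard.

    Assumes each in-range pair-frame is an independent binding opportunity:
    ``kon ~ h * pi * r^2 / dt``. Calibration refines this.
    """
    h = (
        config.kon_um2_per_molecule_s
        * config.dt_s
        / (np.pi * config.reaction_radius_um**2)
    )
    return float(min(h, 1.0))


def simulate_field(
    config: SimulationConfig,
    field_id: str = "field0",
) -> tuple[TrackSet, TrackSet, SimulationGroundTruth]:
    """Simulate one dual-channel field of view.

    Returns channel-A tracks, channel-B tracks (carrying the fixed per-field
    inter-channel offset), and the ground truth log.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, hgt = config.field_width_um, config.field_height_um
    n_frames, dt = config.n_frames, config.dt_s

    if config.poisson_counts:
        n_a = int(rng.poisson(config.expected_count("A")))
        n_b = int(rng.poisson(config.expected_count("B")))
    else:
        n_a = int(round(config.expected_count("A")))
        n_b = int(round(config.expected_count("B")))
    if n_a == 0 or n_b == 0:
        raise DataError("a channel has zero molecules; increase density or area")

    pos_a = rng.uniform([0, 0], [w, hgt], size=(n_a, 2))
    pos_b = rng.uniform([0, 0], [w, hgt], size=(n_b, 2))

    # static confinement zones
    zone_r = config.confinement_zone_radius_um
    n_zones = int(round(config.confinement_area_fraction * config.area_um2 / (np.pi * zone_r**2)))
    zones = rng.uniform([0, 0], [w, hgt], size=(n_zones, 2)) if n_zones else np.empty((0, 2))

    h = config.binding_hazard if config.binding_hazard is not None else default_hazard(config)
    if config.kon_um2_per_molecule_s == 0:
        h = 0.0
    p_off = 1.0 - np.exp(-config.koff_per_s * dt)

    partner_of_a = np.full(n_a, -1, dtype=int)  # B index or -1
    partner_of_b = np.full(n_b, -1, dtype=int)
    contact = np.zeros((n_b, 2))  # B minus A offset while bound
    refractory_frames = int(round(config.rebind_refractory_s / dt))
    refractory_until: dict[tuple[int, int], int] = {}  # (a, b) -> first frame allowed

    true_a = np.empty((n_frames, n_a, 2))
    true_b = np.empty((n_frames, n_b, 2))
    bound_log = np.full((n_frames, n_a), -1, dtype=int)
    inzone_a = np.zeros((n_frames, n_a), dtype=bool)
    inzone_b = np.zeros((n_frames, n_b), dtype=bool)
    cuts_a: list[set[int]] = [set() for _ in range(n_a)]  # frame f: break between f-1 and f
    cuts_b: list[set[int]] = [set() for _ in range(n_b)]

    def zone_index(pos: np.ndarray) -> np.ndarray:
        """Index of the first containing zone, or -1 (torus-aware distances)."""
        if n_zones == 0:
            return np.full(len(pos), -1, dtype=int)
        dx = np.abs(pos[:, None, 0] - zones[None, :, 0])
        dy = np.abs(pos[:, None, 1] - zones[None, :, 1])
        dx = np.minimum(dx, w - dx)
        dy = np.minimum(dy, hgt - dy)
        inside = dx**2 + dy**2 <= zone_r**2
        any_in = inside.any(axis=1)
        idx = np.where(any_in, inside.argmax(axis=1), -1)
        return idx

    def torus_delta(p: np.ndarray, q: np.ndarray) -> np.ndarray:
        d = p - q
        d[..., 0] -= w * np.round(d[..., 0] / w)
        d[..., 1] -= hgt * np.round(d[..., 1] / hgt)
        return d

    def wrap(pos: np.ndarray, mols: np.ndarray, cuts: list[set[int]], frame: int) -> np.ndarray:
        crossed = (pos[:, 0] < 0) | (pos[:, 0] >= w) | (pos[:, 1] < 0) | (pos[:, 1] >= hgt)
        for k in np.flatnonzero(crossed):
            cuts[mols[k]].add(frame)
        out = pos.copy()
        out[:, 0] %= w
        out[:, 1] %= hgt
        return out

    def diffuse(pos, bound_mask, channel_cuts, frame):
        """One diffusion step for the independently-moving molecules of one channel."""
        n = len(pos)
        zi = zone_index(pos)
        d_coef = np.where(bound_mask, config.d_bound_um2_s, config.d_free_um2_s)
        confined = zi >= 0
        d_coef = np.where(confined, d_coef * config.d_confined_factor, d_coef)
        step = rng.normal(size=(n, 2)) * np.sqrt(2.0 * d_coef * dt)[:, None]
        new = pos + step
        # boundary handling for molecules currently inside a zone
        if n_zones:
            for k in np.flatnonzero(confined):
                c = zones[zi[k]]
                delta = torus_delta(new[k], c)
                r = np.hypot(*delta)
                if r > zone_r:
                    if rng.random() >= config.escape_prob:
                        new[k] = c + delta * (max(2 * zone_r - r, 1e-9) / r)
        disp = new - pos
        return wrap(new, np.arange(n), channel_cuts, frame), disp

    def bind_free_pairs(frame: int) -> None:
        if h <= 0:
            return
        free_a = np.flatnonzero(partner_of_a < 0)
        free_b = np.flatnonzero(partner_of_b < 0)
        if len(free_a) == 0 or len(free_b) == 0:
            return
        delta = torus_delta(pos_a[free_a][:, None, :], pos_b[free_b][None, :, :])
        dist = np.hypot(delta[..., 0], delta[..., 1])
        ai, bi = np.nonzero(dist <= config.reaction_radius_um)
        if len(ai) == 0:
            return
        order = rng.permutation(len(ai))
        for k in order:
            a, b = free_a[ai[k]], free_b[bi[k]]
            if partner_of_a[a] >= 0 or partner_of_b[b] >= 0:
                continue
            if refractory_until.get((a, b), 0) > frame:
                continue
            if rng.random() < h:
                partner_of_a[a] = b
                partner_of_b[b] = a
                ang = rng.uniform(0, 2 * np.pi)
                off = config.contact_offset_um * np.array([np.cos(ang), np.sin(ang)])
                contact[b] = off
                pos_b[b] = wrap((pos_a[a] + off)[None, :], np.array([b]), cuts_b, frame)[0]

    for t in range(n_frames):
        if t > 0:
            # 1) dissociation in place; the pair enters a rebinding refractory
            # window so dissociation is observable rather than erased by an
            # immediate in-place rebinding
            bound_a = np.flatnonzero(partner_of_a >= 0)
            if len(bound_a):
                unbind = bound_a[rng.random(len(bound_a)) < p_off]
                for a in unbind:
                    b = partner_of_a[a]
                    partner_of_a[a] = -1
                    partner_of_b[b] = -1
                    refractory_until[(int(a), int(b))] = t + refractory_frames
            # 2) motion: A molecules always move themselves; bound B follows A
            a_bound_mask = partner_of_a >= 0
            pos_a, disp_a = diffuse(pos_a, a_bound_mask, cuts_a, t)
            b_free = np.flatnonzero(partner_of_b < 0)
            if len(b_free):
                zi = zone_index(pos_b[b_free])
                d_coef = np.where(zi >= 0, config.d_free_um2_s * config.d_confined_factor, config.d_free_um2_s)
                step = rng.normal(size=(len(b_free), 2)) * np.sqrt(2.0 * d_coef * dt)[:, None]
                new = pos_b[b_free] + step
                if n_zones:
                    for j, k in enumerate(b_free):
                        if zi[j] >= 0:
                            c = zones[zi[j]]
                            delta = torus_delta(new[j], c)
                            r = np.hypot(*delta)
                            if r > zone_r:
                                if rng.random() >= config.escape_prob:
                                    new[j] = c + delta * (max(2 * zone_r - r, 1e-9) / r)
                pos_b[b_free] = wrap(new, b_free, cuts_b, t)
            b_bound = np.flatnonzero(partner_of_b >= 0)
            if len(b_bound):
                for b in b_bound:
                    a = partner_of_b[b]
                    newp = pos_a[a] + contact[b]
                    pos_b[b] = wrap(newp[None, :], np.array([b]), cuts_b, t)[0]
            # 3) association
            bind_free_pairs(t)
        else:
            bind_free_pairs(0)
        true_a[t] = pos_a
        true_b[t] = pos_b
        bound_log[t] = partner_of_a
        inzone_a[t] = zone_index(pos_a) >= 0
        inzone_b[t] = zone_index(pos_b) >= 0

    # ---------------------------------------------------------------- truth
    bound_intervals = _intervals_from_partner_log(bound_log)
    confined_intervals: dict[str, list[tuple[int, int]]] = {}
    for mol in range(n_a):
        iv = _runs(inzone_a[:, mol])
        if iv:
            confined_intervals[f"A:{mol}"] = iv
    for mol in range(n_b):
        iv = _runs(inzone_b[:, mol])
        if iv:
            confined_intervals[f"B:{mol}"] = iv

    duration_s = config.movie_duration_s
    event_rate = len(bound_intervals) / duration_s / config.area_um2

    b_offset = rng.normal(0.0, config.registration_residual_um, size=2)

    # ---------------------------------------------------------------- emission
    track_molecules: dict[int, tuple[str, int]] = {}
    next_id = [0]

    def emit(true_pos, cuts, channel, offset) -> list[Track]:
        tracks = []
        n_mol = true_pos.shape[1]
        for mol in range(n_mol):
            xy = true_pos[:, mol, :] + offset
            if config.loc_sigma_um > 0:
                xy = xy + rng.normal(0.0, config.loc_sigma_um, size=xy.shape)
            present = rng.random(n_frames) >= config.dropout_prob
            frames = np.flatnonzero(present)
            if len(frames) == 0:
                continue
            intensity = rng.normal(1000.0, 20.0, size=len(frames))
            # segment boundaries: dropout gaps exceeding the split threshold, and seam cuts
            boundaries = [0]
            for i in range(1, len(frames)):
                gap = frames[i] - frames[i - 1]
                crossed_cut = any(frames[i - 1] < c <= frames[i] for c in cuts[mol])
                if gap > config.split_gap_frames or crossed_cut:
                    boundaries.append(i)
            boundaries.append(len(frames))
            for s, e in zip(boundaries[:-1], boundaries[1:]):
                tid = next_id[0]
                next_id[0] += 1
                track_molecules[tid] = (channel, mol)
                tracks.append(
                    Track(
                        field_id=field_id,
                        channel=channel,
                        track_id=tid,
                        frames=frames[s:e],
                        xy_um=xy[frames[s:e]],
                        intensity=intensity[s:e],
                    )
                )
        return tracks

    tracks_a = emit(true_a, cuts_a, "A", np.zeros(2))
    tracks_b = emit(true_b, cuts_b, "B", b_offset)

    wrapped = {f"A:{m}" for m in range(n_a) if cuts_a[m]} | {
        f"B:{m}" for m in range(n_b) if cuts_b[m]
    }

    truth = SimulationGroundTruth(
        bound_intervals=bound_intervals,
        confined_intervals=confined_intervals,
        n_molecules_a=n_a,
        n_molecules_b=n_b,
        realized_density_a=n_a / config.area_um2,
        realized_density_b=n_b / config.area_um2,
        true_event_rate_per_s_um2=event_rate,
        b_offset_um=(float(b_offset[0]), float(b_offset[1])),
        track_molecules=track_molecules,
        wrapped_molecules=wrapped,
        n_frames=n_frames,
        dt_s=dt,
    )
    ts_a = TrackSet(tracks_a, config.area_um2, dt, n_frames)
    ts_b = TrackSet(tracks_b, config.area_um2, dt, n_frames)
    return ts_a, ts_b, truth


def _intervals_from_partner_log(bound_log: np.ndarray) -> list[tuple[int, int, int, int]]:
    n_frames, n_a = bound_log.shape
    out = []
    for a in range(n_a):
        col = bound_log[:, a]
        t = 0
        while t < n_frames:
            if col[t] >= 0:
                b = col[t]
                start = t
                while t + 1 < n_frames and col[t + 1] == b:
                    t += 1
                out.append((a, int(b), start, t))
            t += 1
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            out.append((int(start), int(prev)))
            start = i
        prev = i
    out.append((int(start), int(prev)))
    return out


# ------------------------------------------------------------------ calibration


def truth_log_kon(truths: list[SimulationGroundTruth], duration_s: float, area_um2: float) -> float:
    """k_on implied by ground-truth binding-event logs.

    Normalized the same way as the pipeline estimator: events per unit time,
    per time-averaged A-molecule count, per B surface density.
    """
    events = sum(len(t.bound_intervals) for t in truths)
    denom = sum(duration_s * t.n_molecules_a * t.realized_density_b for t in truths)
    if denom == 0:
        raise DataError("cannot normalize k_on: zero molecules")
    return events / denom


def calibrate_binding_hazard(
    config: SimulationConfig,
    target_kon: float,
    n_reps: int = 6,
    seed: int = 0,
    rtol: float = 0.1,
    max_iter: int = 12,
) -> float:
    """Find the per-frame hazard whose truth-log k_on matches ``target_kon``.

    Damped fixed-point search on short calibration simulations, verified at
    the end against ``rtol``; deterministic given ``seed``.
    """
    if target_kon < 0:
        raise ConfigError("target_kon must be >= 0")
    if target_kon == 0:
        return 0.0

    def measure(hazard: float) -> float:
        truths = []
        for i in range(n_reps):
            cfg = replace(
                config,
                binding_hazard=hazard,
                kon_um2_per_molecule_s=target_kon,
                seed=seed * 100003 + i,
            )
            _, _, tr = simulate_field(cfg)
            truths.append(tr)
        return truth_log_kon(truths, config.movie_duration_s, config.area_um2)

    h = min(1.0, max(1e-6, default_hazard(replace(config, kon_um2_per_molecule_s=target_kon))))
    lo, hi = 0.0, None  # bracket on h: kon(lo) < target, kon(hi) > target
    for _ in range(max_iter):
        k = measure(h)
        if abs(k - target_kon) <= 0.3 * rtol * target_kon:
            return h
        if k < target_kon:
            lo = max(lo, h)
            if h >= 1.0:
                raise ConfigError(
                    f"target k_on {target_kon} unreachable: hazard bracket hit 1.0 "
                    f"(measured {k:.3g})"
                )
        else:
            hi = h if hi is None else min(hi, h)
        if k > 0:
            h_new = h * (target_kon / k) ** 0.8
        else:
            h_new = h * 4.0
        if hi is not None and not (lo < h_new < hi):
            h_new = 0.5 * (lo + hi)
        h = float(min(1.0, max(1e-8, h_new)))
    k = measure(h)
    if abs(k - target_kon) <= rtol * target_kon:
        return h
    raise ConfigError(
        f"hazard calibration did not converge in {max_iter} iterations; "
        f"bracket [{lo}, {hi}], last hazard {h} gave k_on {k:.3g} vs target {target_kon}"
    )


# ------------------------------------------------------------------ photobleaching


def simulate_photobleaching_traces(
    n_particles: int,
    size_distribution,
    unit_intensity: float = 1000.0,
    bleach_rate_per_s: float = 0.05,
    noise_sigma: float = 0.0,
    n_frames: int = 400,
    dt_s: float = 0.033,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-fluorophore bleaching traces.

    ``size_distribution[i]`` is the probability of ``i + 1`` fluorophores and
    must sum to 1 over at most 15 entries. Returns ``(traces, true_counts)``
    with ``traces`` of shape ``(n_particles, n_frames)``.
    """
    p = np.asarray(size_distribution, dtype=float)
    if len(p) > 15:
        raise ConfigError("size_distribution supports at most 15 fluorophores")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ConfigError("size_distribution must be nonnegative and sum to 1")
    if n_particles < 1:
        raise ConfigError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.choice(np.arange(1, len(p) + 1), size=n_particles, p=p)
    times = np.arange(n_frames) * dt_s
    traces = np.empty((n_particles, n_frames))
    for i, n in enumerate(counts):
        if bleach_rate_per_s > 0:
            bleach = rng.exponential(1.0 / bleach_rate_per_s, size=n)
        else:
            bleach = np.full(n, np.inf)
        alive = (bleach[:, None] > times[None, :]).sum(axis=0)
        traces[i] = unit_intensity * alive
    if noise_sigma > 0:
        traces = traces + rng.normal(0.0, noise_sigma, size=traces.shape)
    return traces, counts.astype(int)


# ------------------------------------------------------------------ BRET plates


def simulate_bret_plate(
    n_wells: int,
    baseline_level: float = 0.8,
    response_amplitude: float = 0.1,
    response_rate: float = 0.004,
    vehicle_drift: float = 0.0,
    noise_sigma: float = 0.0,
    n_pre_reads: int = 3,
    n_post_reads: int = 30,
    read_interval_s: float = 120.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-well BRET ratio time series.

    Wells alternate stimulated/vehicle. Pre-stimulation reads have negative
    times; the ligand is added at t = 0. ``vehicle_drift`` is a shared linear
    ratio drift (per second, post-stimulation) affecting all wells.
    """
    if n_pre_reads < 1:
        raise ConfigError("n_pre_reads must be >= 1")
    if n_wells < 2:
        raise ConfigError("need at least one stimulated and one vehicle well")
    rng = np.random.default_rng(seed)
    pre_times = -read_interval_s * np.arange(n_pre_reads, 0, -1)
    post_times = read_interval_s * np.arange(1, n_post_reads + 1)
    times = np.concatenate([pre_times, post_times])
    rows = []
    for wi in range(n_wells):
        condition = "stimulated" if wi % 2 == 0 else "vehicle"
        for t in times:
            ratio = baseline_level
            if t > 0:
                ratio += vehicle_drift * t
                if condition == "stimulated":
                    ratio += response_amplitude * (1.0 - np.exp(-response_rate * t))
            if noise_sigma > 0:
                ratio += rng.normal(0.0, noise_sigma)
            rows.append((f"W{wi:02d}", condition, float(t), float(ratio)))
    return pd.DataFrame(rows, columns=["well", "condition", "time_s", "bret_ratio"])


# ------------------------------------------------------------------ beads


def simulate_bead_pairs(
    n_beads: int,
    field_width_um: float,
    field_height_um: float,
    offset_um,
    noise_sigma_um: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fiducial coordinate pairs for channel registration.

    ``src`` is the channel-B view (true position + offset + noise), ``dst``
    the channel-A view (true position + noise).
    """
    if n_beads < 3:
        raise ConfigError("need >= 3 beads")
    rng = np.random.default_rng(seed)
    pos = rng.uniform([0, 0], [field_width_um, field_height_um], size=(n_beads, 2))
    noise = lambda: rng.normal(0.0, noise_sigma_um, size=(n_beads, 2)) if noise_sigma_um > 0 else 0.0
    src = pos + np.asarray(offset_um, dtype=float) + noise()
    dst = pos + noise()
    return src, dst
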