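"""Tests for null construction, deconvolution, rate estimation, and state calls."""

from dataclasses import replace

import numpy as np
import pytest

from cotrack.colocalization import ColocalizationEvent, DwellDistribution
from cotrack.diffusion import (
    STATE_CONFINED,
    STATE_FREE,
    STATE_UNDEFINED,
    ConfinementAnnotation,
)
from cotrack.errors import DataError
from cotrack.kinetics import (
    classify_interaction_state,
    convolve_with_null,
    deconvolve_dwells,
    estimate_koff,
    estimate_kon,
    null_distribution,
    true_event_count,
)
from cotrack.simulate import SimulationConfig, simulate_field
from cotrack.tracks import Track, TrackSet

DT = 0.033


def make_dist(counts, censored=None, kind="observed", dt=DT):
    counts = np.asarray(counts, dtype=float)
    if censored is None:
        censored = np.zeros_like(counts)
    return DwellDistribution(
        bin_width_s=dt,
        counts=counts,
        censored_counts=np.asarray(censored, dtype=float),
        n_events=int(counts.sum()),
        n_censored=int(np.sum(censored)),
        n_excluded=0,
        kind=kind,
    )


def geometric_counts(rate_per_s, n_events, size=400, dt=DT, start=1):
    p = 1 - np.exp(-rate_per_s * dt)
    d = np.arange(size, dtype=float)
    counts = np.zeros(size)
    counts[start:] = (1 - p) ** (d[start:] - start) * p
    return counts * n_events / counts.sum()


class TestNullDistribution:
    def test_far_separated_control_is_error(self):
        n = 20
        a = TrackSet(
            [Track("f0", "A", 0, np.arange(n), np.tile([1.0, 1.0], (n, 1)), np.ones(n))],
            100.0, DT, n,
        )
        b = TrackSet(
            [Track("f0", "B", 1, np.arange(n), np.tile([9.0, 9.0], (n, 1)), np.ones(n))],
            100.0, DT, n,
        )
        with pytest.raises(DataError, match="null"):
            null_distribution(a, b)

    def test_null_mass_is_short_lived(self):
        cfg = SimulationConfig(kon_um2_per_molecule_s=0.0, density_a_per_um2=0.4, seed=33)
        a, b, _ = simulate_field(cfg)
        null = null_distribution(a, b, max_gap_frames=2)
        frac_long = null.counts[10:].sum() / null.counts.sum()
        assert frac_long < 0.05

    def test_two_seeds_agree(self):
        def null_for(seed_base):
            counts = None
            for i in range(12):
                cfg = SimulationConfig(
                    kon_um2_per_molecule_s=0.0, density_a_per_um2=0.4, seed=seed_base + i
                )
                a, b, _ = simulate_field(cfg)
                d = null_distribution(a, b, max_gap_frames=2)
                counts = d.counts if counts is None else counts + d.counts
            return counts

        c1 = null_for(100)
        c2 = null_for(900)
        assert c1.sum() >= 2000 and c2.sum() >= 2000
        # Kolmogorov distance between the two empirical distributions
        cdf1 = np.cumsum(c1) / c1.sum()
        cdf2 = np.cumsum(c2) / c2.sum()
        assert np.max(np.abs(cdf1 - cdf2)) < 0.05


class TestDeconvolution:
    def test_delta_kernel_is_identity(self):
        observed = make_dist(geometric_counts(1.0, 1000))
        null_counts = np.zeros(len(observed.counts))
        null_counts[1] = 50  # all control events last one frame
        null = make_dist(null_counts, kind="null")
        dec = deconvolve_dwells(observed, null)
        # identity up to a one-bin shift: observed(n) = x(n-1)
        np.testing.assert_allclose(dec.counts[:-1], observed.counts[1:], rtol=1e-4, atol=0.05)

    def test_forward_convolve_then_invert(self):
        true = geometric_counts(0.64, 2000)
        null = make_dist(geometric_counts(2.5, 500, start=1), kind="null")
        observed_counts = convolve_with_null(true, null)
        observed = make_dist(observed_counts)
        dec = deconvolve_dwells(observed, null)
        tv = 0.5 * np.abs(dec.counts / dec.counts.sum() - true / true.sum()).sum()
        assert tv < 0.05

    def test_reconvolution_residual(self):
        true = geometric_counts(0.64, 2000)
        null = make_dist(geometric_counts(2.5, 500), kind="null")
        observed = make_dist(convolve_with_null(true, null))
        dec = deconvolve_dwells(observed, null)
        re = convolve_with_null(dec.counts, null)
        tv = 0.5 * np.abs(re / re.sum() - observed.counts / observed.counts.sum()).sum()
        assert tv < 0.02

    def test_nonnegative_output(self):
        rng = np.random.default_rng(0)
        observed = make_dist(rng.poisson(geometric_counts(0.8, 500) + 0.2))
        null = make_dist(geometric_counts(3.0, 300), kind="null")
        dec = deconvolve_dwells(observed, null)
        assert (dec.counts >= 0).all()
        assert dec.kind == "deconvolved"

    def test_zero_kernel_is_error(self):
        observed = make_dist(geometric_counts(1.0, 100))
        null = make_dist(np.zeros(400), kind="null")
        with pytest.raises(DataError, match="kernel"):
            deconvolve_dwells(observed, null)

    def test_mismatched_bin_width_is_error(self):
        observed = make_dist(geometric_counts(1.0, 100))
        null = make_dist(geometric_counts(2.0, 100), kind="null", dt=0.05)
        with pytest.raises(DataError):
            deconvolve_dwells(observed, null)


class TestKoff:
    def test_exact_exponential_self_fit(self):
        dist = make_dist(geometric_counts(1.0, 10_000, size=2000), kind="deconvolved")
        assert estimate_koff(dist, min_duration_frames=2) == pytest.approx(1.0, rel=0.01)

    def test_paper_reciprocal_relation(self):
        # koff = 0.64 /s corresponds to a mean dwell of 1.5625 s (printed ~1.57)
        dist = make_dist(geometric_counts(0.64, 10_000, size=3000), kind="deconvolved")
        koff = estimate_koff(dist, min_duration_frames=2)
        assert 1.0 / koff == pytest.approx(1.5625, rel=0.01)

    def test_too_few_events_is_error(self):
        dist = make_dist(geometric_counts(1.0, 10), kind="deconvolved")
        with pytest.raises(DataError, match="effective events"):
            estimate_koff(dist)

    def test_all_censored_is_error(self):
        counts = np.zeros(100)
        cens = np.zeros(100)
        cens[50] = 30
        dist = make_dist(counts, cens, kind="deconvolved")
        with pytest.raises(DataError):
            estimate_koff(dist)

    def test_censored_fit_beats_naive_fit_under_heavy_censoring(self):
        # movie length ~ 3x the mean dwell: ignoring censored exposure
        # overestimates koff, the censored MLE does not
        rng = np.random.default_rng(7)
        koff, t_max = 0.3, 13.2
        n = 5000
        durations = rng.exponential(1 / koff, size=n)
        starts = rng.uniform(0, t_max, size=n)
        observed = np.minimum(durations, t_max - starts)
        censored = durations > t_max - starts
        bins = np.round(observed / DT).astype(int).clip(1)
        size = bins.max() + 1
        counts = np.bincount(bins[~censored], minlength=size).astype(float)
        cens = np.bincount(bins[censored], minlength=size).astype(float)
        with_cens = estimate_koff(make_dist(counts, cens, kind="deconvolved"), 2)
        naive = estimate_koff(make_dist(counts, kind="deconvolved"), 2)
        assert with_cens == pytest.approx(koff, rel=0.1)
        assert naive > with_cens * 1.15


class TestKon:
    def _track_set(self, n_per_frame, area, n_frames=100):
        tracks = []
        for i in range(n_per_frame):
            tracks.append(
                Track("f0", "A", i, np.arange(n_frames),
                      np.tile([1.0 * i, 1.0], (n_frames, 1)), np.ones(n_frames))
            )
        return TrackSet(tracks, area, DT, n_frames)

    def test_arithmetic_example(self):
        # 10 events, T = 10 s, N_A = 10, rho_B = 0.1 /um^2 -> kon = 1.0
        a = self._track_set(10, area=100.0)
        b = self._track_set(10, area=100.0)  # 10 molecules in 100 um^2 = 0.1/um^2
        kon = estimate_kon(10, 10.0, a, b)
        assert kon == pytest.approx(1.0)

    def test_doubling_density_halves_kon(self):
        a = self._track_set(10, area=100.0)
        b1 = self._track_set(10, area=100.0)
        b2 = self._track_set(20, area=100.0)
        assert estimate_kon(10, 10.0, a, b1) == pytest.approx(
            2 * estimate_kon(10, 10.0, a, b2)
        )

    def test_area_invariance(self):
        # same densities on a larger field: kon unchanged for scaled events
        a1, b1 = self._track_set(10, 100.0), self._track_set(10, 100.0)
        a2, b2 = self._track_set(40, 400.0), self._track_set(40, 400.0)
        assert estimate_kon(10, 10.0, a1, b1) == pytest.approx(
            estimate_kon(40, 10.0, a2, b2)
        )

    def test_zero_density_is_error(self):
        a = self._track_set(10, 100.0)
        b = TrackSet([], 100.0, DT, 100)
        with pytest.raises(DataError):
            estimate_kon(10, 10.0, a, b)

    def test_true_event_count_includes_censored(self):
        counts = np.zeros(50)
        counts[5] = 10
        cens = np.zeros(50)
        cens[20] = 3
        cens[1] = 4  # below the minimum: excluded
        dist = make_dist(counts, cens, kind="deconvolved")
        assert true_event_count(dist, 2) == 13


class TestInteractionState:
    def _ann(self, states, track_id=0, channel="A"):
        n = len(states)
        return ConfinementAnnotation(
            "c0", channel, track_id, np.arange(n), np.asarray(states, np.int8)
        )

    def test_both_confined_every_frame(self):
        ann_a = {0: self._ann([STATE_CONFINED] * 20)}
        ann_b = {1: self._ann([STATE_CONFINED] * 20, 1, "B")}
        events = [ColocalizationEvent(0, 1, 5, 15, False)]
        summary, labels = classify_interaction_state(events, ann_a, ann_b)
        assert labels == ["co_confined"]
        assert summary.fraction_co_confined == 1.0

    def test_one_partner_free_not_co_confined(self):
        ann_a = {0: self._ann([STATE_CONFINED] * 20)}
        ann_b = {1: self._ann([STATE_FREE] * 20, 1, "B")}
        events = [ColocalizationEvent(0, 1, 5, 15, False)]
        summary, labels = classify_interaction_state(events, ann_a, ann_b)
        assert labels == ["mixed"]
        assert summary.fraction_co_confined == 0.0

    def test_both_free_co_diffusing(self):
        ann_a = {0: self._ann([STATE_FREE] * 20)}
        ann_b = {1: self._ann([STATE_FREE] * 20, 1, "B")}
        events = [ColocalizationEvent(0, 1, 0, 10, False)]
        _, labels = classify_interaction_state(events, ann_a, ann_b)
        assert labels == ["co_diffusing"]

    def test_unclassifiable_event_reported(self):
        ann_a = {0: self._ann([STATE_UNDEFINED] * 20)}
        ann_b = {1: self._ann([STATE_UNDEFINED] * 20, 1, "B")}
        events = [ColocalizationEvent(0, 1, 0, 10, False)]
        summary, labels = classify_interaction_state(events, ann_a, ann_b)
        assert labels == ["undefined"]
        assert summary.n_undefined == 1

    def test_fractions_bounded(self):
        ann_a = {0: self._ann([STATE_CONFINED] * 10 + [STATE_FREE] * 10)}
        ann_b = {1: self._ann([STATE_CONFINED] * 10 + [STATE_FREE] * 10, 1, "B")}
        events = [
            ColocalizationEvent(0, 1, 0, 9, False),
            ColocalizationEvent(0, 1, 12, 19, False),
        ]
        summary, _ = classify_interaction_state(events, ann_a, ann_b)
        assert 0 <= summary.fraction_co_confined <= 1
        assert summary.fraction_co_confined + summary.fraction_co_diffusing <= 1

    def test_sticky_zone_preset_orders_states(self):
        # with large sticky confinement zones most binding happens between
        # confined molecules: co-confinement dominates co-diffusion
        from cotrack.diffusion import classify_confinement
        from cotrack.colocalization import detect_colocalizations

        cfg = SimulationConfig(
            kon_um2_per_molecule_s=0.4,
            koff_per_s=0.3,
            reaction_radius_um=0.25,
            binding_hazard=0.5,
            confinement_area_fraction=0.3,
            confinement_zone_radius_um=0.15,
            escape_prob=0.01,
            dropout_prob=0.0,
            seed=17,
        )
        a, b, _ = simulate_field(cfg)
        ann_a, ann_b = {}, {}
        for ts, store in ((a, ann_a), (b, ann_b)):
            for t in ts.tracks:
                if t.n_localizations >= 30:
                    store[t.track_id] = classify_confinement(
                        t, d_reference=cfg.d_free_um2_s, dt_s=cfg.dt_s
                    )
        events = [
            e
            for e in detect_colocalizations(a, b, 0.15, max_gap_frames=2)
            if e.duration_frames >= 2
        ]
        summary, _ = classify_interaction_state(events, ann_a, ann_b)
        assert summary.n_events > 20
        assert summary.fraction_co_confined > summary.fraction_co_diffusing
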