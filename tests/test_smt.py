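"""Single-molecule trajectory analytics."""

import numpy as np
import pandas as pd
import pytest

from condenskit import simulate as sim, smt
from condenskit.errors import ParameterError, SchemaError
from condenskit.smt import TrajectorySet


def make_tracks(records, dt=0.02, prior=None):
    df = pd.DataFrame(records, columns=["track_id", "frame", "x", "y"])
    return TrajectorySet(df, frame_interval=dt, localization_error_prior=prior)


def straight_track(tid, n, step=0.1, start=(0.0, 0.0)):
    return [(tid, i, start[0] + i * step, start[1]) for i in range(n)]


class TestFiltering:
    def test_short_tracks_removed_with_count(self):
        recs = (straight_track(0, 5) + straight_track(1, 7)
                + straight_track(2, 12))
        filtered, removed = smt.filter_tracks(make_tracks(recs), min_points=7)
        assert removed == 1
        assert sorted(filtered.track_lengths()) == [7, 12]

    def test_empty_input_passes_through(self):
        empty = make_tracks([])
        filtered, removed = smt.filter_tracks(empty)
        assert removed == 0 and filtered.n_tracks == 0

    def test_survivor_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        recs = []
        lengths = 1 + rng.geometric(0.15, size=500)
        for tid, L in enumerate(lengths):
            recs.extend(straight_track(tid, int(L)))
        filtered, removed = smt.filter_tracks(make_tracks(recs), min_points=7)
        expected = int(np.sum(lengths >= 7))
        assert filtered.n_tracks == expected
        assert removed == 500 - expected

    def test_non_monotone_frames_rejected_with_track_named(self):
        recs = [(3, 0, 0, 0), (3, 2, 0, 0), (3, 1, 0, 0)]
        with pytest.raises(SchemaError, match="track 3"):
            make_tracks(recs)


class TestTrackDiffusion:
    def test_stationary_track_floored_at_minus_four(self):
        diff = smt.track_diffusion(make_tracks(straight_track(0, 6, step=0.0)))
        assert diff["logD"].iloc[0] == pytest.approx(-4.0)
        assert "floored" in diff["flags"].iloc[0]

    def test_ballistic_track_msd_is_quadratic_and_flagged(self):
        s, dt = 0.2, 0.02
        diff = smt.track_diffusion(make_tracks(straight_track(0, 6, step=s),
                                               dt=dt))
        for lag in (1, 2, 3):
            assert diff[f"msd_lag{lag}"].iloc[0] == pytest.approx((lag * s) ** 2)
        assert "superdiffusive" in diff["flags"].iloc[0]

    def test_short_tracks_skipped_with_reason(self):
        diff = smt.track_diffusion(make_tracks(straight_track(0, 3)))
        assert diff["skipped"].iloc[0] == "too_few_points"

    @pytest.mark.parametrize("d_true", [0.05, 0.5, 5.0])
    def test_estimator_unbiased_on_brownian_tracks(self, d_true):
        p = sim.SmtSimParams(n_molecules=2000, states=((d_true, 1.0),),
                             loc_error_sd=0.0, bleach_prob_per_frame=0.0,
                             n_frames=6, seed=int(d_true * 100))
        tracks, _ = sim.simulate_trajectories(p)
        diff = smt.track_diffusion(tracks)
        assert 0.9 < diff["D"].mean() / d_true < 1.1


class TestMobility:
    def test_all_mobile_at_unit_diffusion(self):
        diff = pd.DataFrame({"logD": np.zeros(10)})
        res = smt.classify_mobility(diff)
        assert res.fraction_mobile == 1.0

    def test_infinite_threshold_gives_zero_mobile(self):
        diff = pd.DataFrame({"logD": np.zeros(10)})
        res = smt.classify_mobility(diff, logd_threshold=np.inf)
        assert res.fraction_mobile == 0.0

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        diff = pd.DataFrame({"logD": rng.normal(size=101)})
        res = smt.classify_mobility(diff)
        assert res.fraction_mobile + res.fraction_immobile == 1.0

    def test_empty_table_reports_empty_status(self):
        res = smt.classify_mobility(pd.DataFrame({"logD": []}))
        assert res.status == "empty"


class TestInflection:
    def _hist(self, samples):
        counts, edges = np.histogram(samples, bins=60, range=(-4, 2))
        return counts, edges

    def test_bimodal_antimode_found_near_minus_half(self):
        rng = np.random.default_rng(3)
        samples = np.concatenate([rng.normal(-2.0, 0.4, 4000),
                                  rng.normal(0.6, 0.4, 5000)])
        counts, edges = self._hist(samples)
        thr, fallback = smt.find_inflection_threshold(counts, edges)
        assert not fallback
        assert thr == pytest.approx(-0.6, abs=0.35)

    def test_unimodal_profile_falls_back(self):
        rng = np.random.default_rng(4)
        counts, edges = self._hist(rng.normal(0.0, 0.4, 5000))
        thr, fallback = smt.find_inflection_threshold(counts, edges)
        assert fallback and thr == -0.5

    def test_symmetric_modes_give_central_threshold(self):
        rng = np.random.default_rng(5)
        samples = np.concatenate([rng.normal(-1.0, 0.3, 5000),
                                  rng.normal(1.0, 0.3, 5000)])
        counts, edges = self._hist(samples)
        thr, fallback = smt.find_inflection_threshold(counts, edges)
        assert not fallback
        assert thr == pytest.approx(0.0, abs=0.2)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            smt.find_inflection_threshold(np.ones(5), np.linspace(-4, 2, 6))


class TestJumpLengthModel:
    def test_pdf_cdf_closed_form_without_localization_error(self):
        d_coef, dt = 1.5, 0.02
        r = np.linspace(0, 2 * np.sqrt(d_coef * dt), 20001)
        pdf = smt.jump_length_pdf(r, d_coef, 0.0, dt)
        cdf = np.trapezoid(pdf, r)
        assert cdf == pytest.approx(1 - np.exp(-1), rel=1e-4)

    def test_histograms_integrate_to_one(self, two_state_tracks):
        tracks, _ = two_state_tracks
        disp = smt.collect_displacements(tracks, max_lags=2)
        for r in disp.values():
            edges = np.geomspace(min(2e-3, r.min() * 0.99),
                                 r.max() * 1.01, 81)
            counts, _ = np.histogram(r, bins=edges)
            dens = counts / (r.size * np.diff(edges))
            total = float(np.sum(dens * np.diff(edges)))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_single_state_data_flags_degenerate_two_state_fit(self):
        p = sim.SmtSimParams(n_molecules=800, states=((0.5, 1.0),),
                             loc_error_sd=0.0, seed=6)
        tracks, _ = sim.simulate_trajectories(p)
        fit = smt.fit_jump_length_model(tracks, n_states=2, sigma=0.0)
        degenerate_d = np.log10(fit.D_states_[1] / fit.D_states_[0]) < 0.3
        vanishing = fit.fractions_.min() < 0.05
        assert degenerate_d or vanishing

    def test_fit_loss_beats_brute_force_grid(self):
        p = sim.SmtSimParams(n_molecules=10, states=((0.01, 0.5), (2.0, 0.5)),
                             loc_error_sd=0.03, bleach_prob_per_frame=0.2,
                             n_frames=12, seed=8)
        tracks, _ = sim.simulate_trajectories(p)
        disp = smt.collect_displacements(tracks, max_lags=4)
        n_disp = sum(v.size for v in disp.values())
        assert n_disp <= 200  # small-sample regime for the oracle
        est = smt.JumpLengthMixture(n_states=2, sigma=0.03)
        est.fit(disp, tracks.frame_interval)
        grid_best = np.inf
        for ld1 in np.linspace(-3, 0, 10):
            for ld2 in np.linspace(-1, 1, 10):
                if ld2 <= ld1:
                    continue
                for f1 in np.linspace(0.1, 0.9, 9):
                    loss = est.evaluate_loss(
                        np.array([ld1, ld2]), np.array([f1, 1 - f1]), 0.03,
                        disp, tracks.frame_interval,
                    )
                    grid_best = min(grid_best, loss)
        assert est.loss_ <= grid_best * (1 + 1e-6) + 1e-12

    def test_minimum_displacement_count_enforced(self):
        p = sim.SmtSimParams(n_molecules=5, n_frames=8,
                             bleach_prob_per_frame=0.0, seed=0)
        tracks, _ = sim.simulate_trajectories(p)
        with pytest.raises(ParameterError, match="displacements"):
            smt.fit_jump_length_model(tracks)


class TestDwellTimes:
    def test_all_short_durations_give_zero_ratio_and_flag(self):
        sample = smt.DwellTimeSample(np.full(100, 0.5), np.zeros(100, bool),
                                     0.5)
        fit = smt.dwell_time_analysis(sample)
        assert fit.n_long_events == 0
        assert fit.long_to_short_ratio == 0.0
        assert fit.status != "ok" or fit.flags

    def test_zero_threshold_reports_undefined_ratio(self):
        sample = smt.DwellTimeSample(np.full(100, 0.5), np.zeros(100, bool),
                                     0.5)
        fit = smt.dwell_time_analysis(sample, threshold=0.0)
        assert np.isnan(fit.long_to_short_ratio)
        assert "undefined" in fit.status

    def test_too_few_events_refuses_fit_but_reports_counts(self):
        sample = smt.DwellTimeSample(np.array([0.5, 2.0, 1.5]),
                                     np.zeros(3, bool), 0.5)
        fit = smt.dwell_time_analysis(sample)
        assert np.isnan(fit.tau_long)
        assert fit.n_events == 3 and fit.n_long_events == 2
        assert "refused" in fit.status

    def test_extreme_censoring_flagged_unreliable(self):
        sample, _ = sim.simulate_dwell_events(200, 0.1, 10.0, 0.9, 0.5,
                                              max_obs_time=0.009, seed=1)
        fit = smt.dwell_time_analysis(sample)
        assert "unreliable_censoring" in fit.flags

    def test_mixture_recovery_within_fifteen_percent(self):
        sample, truth = sim.simulate_dwell_events(5000, 0.1, 10.0, 0.9, 0.5,
                                                  250.0, seed=3)
        fit = smt.dwell_time_analysis(sample)
        assert fit.tau_long == pytest.approx(10.0, rel=0.15)
        assert fit.tau_short == pytest.approx(0.9, rel=0.15)

    def test_track_lifetimes_used_as_durations(self):
        recs = (straight_track(0, 4, step=0.0)
                + straight_track(1, 10, step=0.0))
        tracks = make_tracks(recs, dt=0.5)
        fit = smt.dwell_time_analysis(tracks, min_events=1)
        assert fit.n_events == 2
        assert fit.n_long_events == 2  # 2.0 s and 5.0 s lifetimes
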