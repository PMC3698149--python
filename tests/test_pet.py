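"""Activity time-structure closed forms and isotope decomposition."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from gelrange.geometry import PetPhantomSpec
from gelrange.pet import (DEFAULT_ISOTOPES, ActivityFrames,
                          IrradiationTimeline, IsotopeSpec,
                          RankDeficientBasisError, activity_at_beam_end,
                          area_normalize, decay_over_delay,
                          fit_isotope_fractions, frame_average,
                          frame_average_factor, get_isotope,
                          laterally_integrate, sum_fitted_contributions,
                          washout_apply)
from gelrange.synthetic import (expected_initial_activity,
                                gen_activity_frames, gen_yield_profiles)

O15 = DEFAULT_ISOTOPES["O15"]
C11 = DEFAULT_ISOTOPES["C11"]
N13 = DEFAULT_ISOTOPES["N13"]


def numeric_buildup(rate, lam, t_beam):
    """Independent oracle: integrate the production/decay balance."""
    val, _ = quad(lambda s: rate * lam * math.exp(-lam * (t_beam - s)),
                  0.0, t_beam, epsabs=1e-14, epsrel=1e-14)
    return val


def numeric_frame_average(lam, t1, t2):
    val, _ = quad(lambda t: math.exp(-lam * t), t1, t2, epsabs=1e-14,
                  epsrel=1e-14)
    return val / (t2 - t1)


class TestTimeStructureClosedForms:
    def test_buildup_matches_integral_oracle(self):
        for iso in (O15, C11, N13):
            expected = numeric_buildup(1000.0, iso.lam, 215.0)
            assert activity_at_beam_end(1000.0, iso, 215.0) == pytest.approx(
                expected, rel=1e-12)

    def test_buildup_printed_timeline_value(self):
        # 15O over a 215 s delivery reaches ~71 % of saturation
        assert activity_at_beam_end(1.0, O15, 215.0) == pytest.approx(
            0.7111, abs=1e-3)

    def test_buildup_limits(self):
        assert activity_at_beam_end(5.0, O15, 1e7) == pytest.approx(5.0,
                                                                    rel=1e-9)
        t = 1e-4
        assert activity_at_beam_end(5.0, O15, t) == pytest.approx(
            5.0 * O15.lam * t, rel=1e-6)

    @pytest.mark.parametrize("iso, factor", [(O15, 0.3618), (C11, 0.9050)])
    def test_transport_delay_decay(self, iso, factor):
        assert decay_over_delay(1.0, iso, 176.0) == pytest.approx(
            math.exp(-iso.lam * 176.0), rel=1e-12)
        assert decay_over_delay(1.0, iso, 176.0) == pytest.approx(factor,
                                                                  abs=1e-3)

    def test_zero_delay_identity(self):
        assert decay_over_delay(3.3, O15, 0.0) == 3.3

    def test_frame_average_matches_integral_oracle(self):
        for iso in (O15, C11, N13):
            for t1, t2 in ((0.0, 1800.0), (0.0, 180.0), (900.0, 1080.0)):
                expected = numeric_frame_average(iso.lam, t1, t2)
                assert frame_average(1.0, iso, (t1, t2)) == pytest.approx(
                    expected, rel=1e-12)

    def test_frame_average_printed_timeline_value(self):
        assert frame_average(1.0, O15, (0.0, 1800.0)) == pytest.approx(
            0.0963, abs=1e-3)

    def test_frame_average_limits(self):
        # vanishing frame at acquisition start and the stable-isotope limit
        assert frame_average(2.0, O15, (0.0, 1e-9)) == pytest.approx(
            2.0, rel=1e-6)
        stable = IsotopeSpec("stable", 1e15)
        assert frame_average(2.0, stable, (0.0, 1800.0)) == pytest.approx(
            2.0, rel=1e-9)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            frame_average(1.0, O15, (100.0, 100.0))


class TestProfiles:
    def test_lateral_integration_conserves_total(self):
        rng = np.random.default_rng(0)
        vol = rng.random((20, 5, 7))
        profile = laterally_integrate(vol)
        assert profile.shape == (20,)
        assert profile.sum() == pytest.approx(vol.sum(), rel=1e-12)

    def test_single_voxel_becomes_delta(self):
        vol = np.zeros((10, 4, 4))
        vol[3, 1, 2] = 5.0
        profile = laterally_integrate(vol)
        assert profile[3] == 5.0 and profile.sum() == 5.0

    def test_area_normalize_two_bins(self):
        assert np.allclose(area_normalize([3.0, 1.0], 1.0), [0.75, 0.25])

    def test_area_normalize_idempotent_and_scale_invariant(self):
        p = np.array([1.0, 4.0, 2.0, 0.5])
        once = area_normalize(p, 0.5)
        assert np.allclose(area_normalize(once, 0.5), once)
        assert np.allclose(area_normalize(10.0 * p, 0.5), once)
        assert once.sum() * 0.5 == pytest.approx(1.0)

    def test_area_normalize_all_zero_rejected(self):
        with pytest.raises(ValueError):
            area_normalize(np.zeros(5), 1.0)


def frames_from_a0(a0: dict, timeline: IrradiationTimeline,
                   noise_rng=None, bin_volume_ml=10.0) -> ActivityFrames:
    """Frames built directly from known initial activities (Bq/ml)."""
    names = list(a0)
    n_bins = len(next(iter(a0.values())))
    bounds = timeline.frames
    values = np.zeros((len(bounds), n_bins))
    for f, (t1, t2) in enumerate(bounds):
        for name in names:
            values[f] += np.asarray(a0[name]) * frame_average_factor(
                name, t1, t2)
        if noise_rng is not None:
            dt = t2 - t1
            counts = noise_rng.poisson(values[f] * dt * bin_volume_ml)
            values[f] = counts / (dt * bin_volume_ml)
    return ActivityFrames(values=values, frame_bounds=bounds,
                          depth=np.arange(n_bins) + 0.5, bin_width=1.0,
                          bin_volume_ml=bin_volume_ml)


class TestIsotopeFit:
    timeline = IrradiationTimeline()

    def test_noiseless_two_isotope_recovery_exact(self):
        a0 = {"C11": np.array([30.0, 10.0, 0.0]),
              "O15": np.array([60.0, 0.0, 25.0])}
        frames = frames_from_a0(a0, self.timeline)
        fit = fit_isotope_fractions(frames, ["C11", "O15"])
        for name in a0:
            assert np.allclose(fit.a0[name], a0[name], rtol=1e-8, atol=1e-8)
        assert fit.converged

    def test_single_isotope_truth_others_near_zero(self):
        a0 = {"C11": np.array([100.0])}
        frames = frames_from_a0(a0, self.timeline)
        fit = fit_isotope_fractions(frames, ["C11", "O15", "N13"])
        assert fit.a0["C11"][0] == pytest.approx(100.0, rel=1e-6)
        assert fit.a0["O15"][0] == pytest.approx(0.0, abs=1e-6)
        assert fit.a0["N13"][0] == pytest.approx(0.0, abs=1e-6)

    def test_indistinguishable_half_lives_rejected(self):
        a0 = {"C11": np.array([50.0])}
        frames = frames_from_a0(a0, self.timeline)
        twin = IsotopeSpec("N13b", 598.0 * (1.0 + 1e-9))
        with pytest.raises(RankDeficientBasisError):
            fit_isotope_fractions(frames, [get_isotope("N13"), twin])
        with pytest.raises(RankDeficientBasisError):
            fit_isotope_fractions(frames, [get_isotope("N13"),
                                           get_isotope("N13")])

    def test_more_isotopes_than_frames_rejected(self):
        a0 = {"C11": np.array([50.0])}
        short = IrradiationTimeline(frame_boundaries=(0.0, 900.0, 1800.0))
        frames = frames_from_a0(a0, short)
        with pytest.raises(ValueError):
            fit_isotope_fractions(frames, ["C11", "O15", "N13"])

    def test_sum_of_contributions_matches_static_average(self):
        a0 = {"C11": np.array([30.0, 5.0]), "O15": np.array([60.0, 1.0]),
              "N13": np.array([10.0, 2.0])}
        frames = frames_from_a0(a0, self.timeline)
        fit = fit_isotope_fractions(frames, ["C11", "O15", "N13"])
        combined = sum_fitted_contributions(fit, self.timeline)
        static = np.zeros(2)
        for name, prof in a0.items():
            static += prof * frame_average_factor(name, 0.0,
                                                  self.timeline.acquisition)
        assert np.allclose(combined, static, rtol=1e-8)

    def test_generator_roundtrip_recovers_configured_mix(self):
        phantom = PetPhantomSpec()
        yields = gen_yield_profiles(phantom, 150.0)
        frames = gen_activity_frames(yields, self.timeline, noiseless=True)
        truth = expected_initial_activity(yields, self.timeline, 10.0)
        fit = fit_isotope_fractions(frames, ["C11", "O15", "N13"])
        for name, expected in truth.items():
            mask = expected > 0
            assert np.allclose(fit.a0[name][mask], expected[mask], rtol=1e-8)


class TestSignalComposition:
    def test_o15_share_shrinks_from_a0_to_frame_average(self):
        # with the 215/176/1800 s timeline the short-lived 15O contributes
        # less to the frame-averaged signal than to the initial activity
        timeline = IrradiationTimeline()
        a0 = {"O15": 60.0, "C11": 40.0}
        share_a0 = a0["O15"] / sum(a0.values())
        avg = {n: a0[n] * frame_average_factor(n, 0.0, timeline.acquisition)
               for n in a0}
        share_avg = avg["O15"] / sum(avg.values())
        assert share_avg < share_a0


class TestWashout:
    def test_confined_medium_identity(self):
        profile = np.array([1.0, 2.0])
        out, iso = washout_apply(profile, "O15", "confined", 0.01)
        assert out is profile
        assert iso.half_life == O15.half_life

    def test_zero_rate_identity(self):
        _, iso = washout_apply(np.ones(2), "O15", "perfused", 0.0)
        assert iso.half_life == O15.half_life

    def test_perfused_rate_equal_to_lambda_halves_half_life(self):
        _, iso = washout_apply(np.ones(2), "O15", "perfused", O15.lam)
        assert iso.half_life == pytest.approx(O15.half_life / 2.0, rel=1e-12)

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError):
            washout_apply(np.ones(2), "O15", "vacuum", 0.0)


class TestTimeline:
    def test_default_framing_covers_acquisition(self):
        tl = IrradiationTimeline()
        assert len(tl.frames) == 10
        assert tl.frame_boundaries[0] == 0.0
        assert tl.frame_boundaries[-1] == tl.acquisition

    def test_invalid_timelines_rejected(self):
        with pytest.raises(ValueError):
            IrradiationTimeline(beam_on=-1.0)
        with pytest.raises(ValueError):
            IrradiationTimeline(frame_boundaries=(0.0, 900.0))  # short cover
        with pytest.raises(ValueError):
            IrradiationTimeline(frame_boundaries=(0.0, 900.0, 900.0, 1800.0))
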