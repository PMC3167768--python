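"""Forward recruitment model, limb/trial fitting, and error summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from peepopt.recruitment_model import (FitConfig, LimbFit, LungModelConfig,
                                       ThresholdDistribution, TrialFit,
                                       fit_error_summary, fit_limb_mean,
                                       fit_trial, forward_volume,
                                       recruited_fraction)
from peepopt.waveform_io import PVLoop


def _erf_cdf(z: float) -> float:
    """Independent normal-CDF oracle via the error function."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestRecruitedFraction:
    def test_half_recruited_at_the_mean(self):
        dist = ThresholdDistribution(mean=25.0, sd=10.0)
        assert recruited_fraction(25.0, dist) == pytest.approx(0.5)

    def test_three_sigma_against_erf_oracle(self):
        dist = ThresholdDistribution(mean=20.0, sd=5.0)
        assert recruited_fraction(35.0, dist) == pytest.approx(
            _erf_cdf(3.0), abs=1e-9)
        assert _erf_cdf(3.0) == pytest.approx(0.99865, abs=1e-5)

    def test_example_patient_fraction_at_peep_20(self):
        """Inflation distribution (mean 27.12, sd 15) at 20 cmH2O."""
        dist = ThresholdDistribution(mean=27.12, sd=15.0)
        expected = _erf_cdf((20.0 - 27.12) / 15.0)
        assert recruited_fraction(20.0, dist) == pytest.approx(expected)
        assert expected == pytest.approx(0.3175, abs=5e-4)

    @settings(deadline=None, max_examples=60)
    @given(mean=st.floats(-10, 60), sd=st.floats(0.5, 40),
           p1=st.floats(-20, 80), p2=st.floats(-20, 80))
    def test_monotone_and_bounded(self, mean, sd, p1, p2):
        dist = ThresholdDistribution(mean=mean, sd=sd)
        f1, f2 = recruited_fraction(p1, dist), recruited_fraction(p2, dist)
        assert 0.0 <= f1 <= 1.0
        if p1 < p2:
            assert f1 <= f2

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            ThresholdDistribution(mean=10.0, sd=0.0)


class TestForwardVolume:
    def test_half_of_tlc_at_the_mean(self):
        cfg = LungModelConfig()   # 144000 units x 0.01 ml = 1440 ml
        dist = ThresholdDistribution(mean=25.0, sd=10.0)
        assert forward_volume(25.0, dist, cfg) == pytest.approx(720.0)

    def test_saturates_at_tlc(self):
        cfg = LungModelConfig()
        dist = ThresholdDistribution(mean=25.0, sd=10.0)
        assert forward_volume(200.0, dist, cfg) == pytest.approx(1440.0)

    def test_discrete_enumeration_matches_continuum(self):
        """144000-unit brute-force enumeration vs the continuum CDF."""
        cfg = LungModelConfig()
        dist = ThresholdDistribution(mean=27.12, sd=15.0)
        pressures = np.linspace(-5, 60, 27)
        cont = forward_volume(pressures, dist, cfg)
        disc = forward_volume(pressures, dist, cfg, discrete=True)
        assert np.max(np.abs(cont - disc)) <= cfg.unit_volume_ml

    def test_monotone_in_pressure(self):
        cfg = LungModelConfig()
        dist = ThresholdDistribution(mean=20.0, sd=7.0)
        p = np.linspace(-10, 60, 200)
        v = forward_volume(p, dist, cfg)
        assert np.all(np.diff(v) >= 0)
        assert v.min() >= 0 and v.max() <= cfg.tlc_ml


class TestFitLimbMean:
    def _limb(self, mean, sd, tlc, n=20, lo=5, hi=40, noise=0.0, rng=None):
        p = np.linspace(lo, hi, n)
        v = tlc * ndtr((p - mean) / sd)
        if noise > 0:
            v = v + rng.normal(0, noise, n)
        return p, v

    def test_noise_free_self_consistency(self):
        p, v = self._limb(25.0, 10.0, 1500.0)
        fit = fit_limb_mean((p, v), 10.0, 1500.0)
        assert fit.distribution.mean == pytest.approx(25.0, abs=0.1)
        assert fit.abs_error_ml < 0.1

    def test_agrees_with_brute_force_grid(self, rng):
        """Optimiser vs exhaustive 0.01-cmH2O grid on random loops."""
        for _ in range(6):
            mean = rng.uniform(10, 40)
            sd = rng.uniform(4, 20)
            tlc = rng.uniform(1000, 2500)
            p, v = self._limb(mean, sd, tlc, noise=8.0, rng=rng)
            fit = fit_limb_mean((p, v), sd, tlc)
            grid = np.arange(0.0, 60.0, 0.01)
            errs = np.mean(np.abs(
                tlc * ndtr((p[None, :] - grid[:, None]) / sd) - v), axis=1)
            best = grid[int(np.argmin(errs))]
            assert fit.distribution.mean == pytest.approx(best, abs=0.011)

    def test_degenerate_limb_fails(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_limb_mean(([10.0, 10.0, 10.0], [1.0, 2.0, 3.0]), 5.0, 1000.0)

    def test_monte_carlo_bias_and_rmse(self, rng):
        """At 10 ml volume noise the fitted mean is unbiased (<0.5 cmH2O
        over 100 seeds) and RMSE shrinks monotonically as noise -> 0."""
        mean, sd, tlc = 25.0, 10.0, 1500.0
        rmses = []
        for noise in (10.0, 5.0, 2.0, 0.0):
            errs = []
            for _ in range(100):
                p, v = self._limb(mean, sd, tlc, noise=noise, rng=rng)
                fit = fit_limb_mean((p, v), sd, tlc)
                errs.append(fit.distribution.mean - mean)
            errs = np.asarray(errs)
            if noise == 10.0:
                assert abs(errs.mean()) < 0.5
            rmses.append(float(np.sqrt(np.mean(errs ** 2))))
        assert all(a >= b for a, b in zip(rmses, rmses[1:]))


def _loops_from_truth(peeps, top, tcp, sd_i, sd_d, tlc, span=300.0):
    loops = []
    for k, peep in enumerate(peeps):
        v_lo = tlc * ndtr((peep - tcp[k]) / sd_d)
        v = np.linspace(v_lo, min(v_lo + span, 0.98 * tlc), 25)
        from scipy.special import ndtri
        p_inf = top[k] + sd_i * ndtri(np.clip(v / tlc, 1e-9, 1 - 1e-9))
        p_def = tcp[k] + sd_d * ndtri(np.clip(v / tlc, 1e-9, 1 - 1e-9))
        loops.append(PVLoop(peep=peep, inflation_p=p_inf, inflation_v=v,
                            deflation_p=p_def[::-1], deflation_v=v[::-1]))
    return loops


class TestFitTrial:
    def test_noise_free_parameter_recovery(self):
        """Generating (means, SDs, TLC) recovered from exact model loops."""
        peeps = [10.0, 15.0, 20.0, 25.0, 27.0]
        top = [30.97, 28.07, 27.12, 26.41, 26.18]
        tcp = [15.57, 17.68, 19.88, 22.43, 23.39]
        loops = _loops_from_truth(peeps, top, tcp, 15.0, 7.0, 1440.0)
        trial = fit_trial(loops, auto_peep=10.0, trial_id="exact")
        assert trial.inflation_sd == pytest.approx(15.0, abs=1.0)
        assert trial.deflation_sd == pytest.approx(7.0, abs=1.0)
        assert trial.tlc_ml == pytest.approx(1440.0, rel=0.02)
        for (peep, mean), want in zip(trial.top_means, top):
            assert mean == pytest.approx(want, abs=0.5)
        for (peep, mean), want in zip(trial.tcp_means, tcp):
            assert mean == pytest.approx(want, abs=0.5)

    def test_loops_below_auto_peep_are_excluded(self):
        peeps = [0.0, 5.0, 10.0, 15.0, 20.0]
        top = [33.0, 31.0, 30.0, 28.0, 27.0]
        tcp = [11.0, 13.0, 15.5, 17.5, 20.0]
        loops = _loops_from_truth(peeps, top, tcp, 15.0, 7.0, 1440.0)
        trial = fit_trial(loops, auto_peep=10.0)
        assert trial.peeps == [10.0, 15.0, 20.0]

    def test_single_loop_fails(self):
        loops = _loops_from_truth([10.0], [30.0], [15.0], 15.0, 7.0, 1440.0)
        with pytest.raises(ValueError, match="insufficient"):
            fit_trial(loops, auto_peep=0.0)

    def test_json_round_trip(self, tmp_path, twin_pipeline):
        trial = twin_pipeline["trial"]
        path = tmp_path / "fit.json"
        trial.save_json(path)
        back = TrialFit.load_json(path)
        assert back == trial

    def test_fit_table_layout(self, twin_pipeline):
        table = twin_pipeline["trial"].to_table()
        assert list(table.index) == [10.0, 15.0, 20.0, 25.0, 27.0]
        for col in ("inflation_mean", "inflation_error_ml",
                    "inflation_error_pct", "deflation_mean",
                    "deflation_error_ml", "deflation_error_pct"):
            assert col in table.columns

    def test_percent_error_falls_with_peep_while_ml_flat(self, rng):
        """Equal ml noise at every level yields a falling percentage,
        because limb volumes grow with PEEP (the denominator grows)."""
        peeps = [10.0, 15.0, 20.0, 25.0]
        top = [31.0, 29.0, 27.5, 26.5]
        tcp = [15.0, 17.0, 19.5, 22.0]
        loops = _loops_from_truth(peeps, top, tcp, 15.0, 7.0, 1440.0)
        pct = np.zeros(len(peeps))
        ml = np.zeros(len(peeps))
        n_seeds = 20
        for _ in range(n_seeds):
            for k, l in enumerate(loops):
                v = l.inflation_v + rng.normal(0, 10, l.inflation_v.size)
                fit = fit_limb_mean((l.inflation_p, v), 15.0, 1440.0,
                                    peep=l.peep)
                pct[k] += fit.pct_error / n_seeds
                ml[k] += fit.abs_error_ml / n_seeds
        assert all(a > b for a, b in zip(pct, pct[1:]))
        assert np.ptp(ml) / ml.mean() < 0.5   # ml errors roughly flat


class TestErrorSummary:
    def _trial_with_errors(self, errors):
        fits = tuple(
            LimbFit(peep=10.0 + 5 * i,
                    distribution=ThresholdDistribution(
                        mean=30.0 - i, sd=15.0, limb=limb),
                    abs_error_ml=e, pct_error=e / 3.0)
            for i, e in enumerate(errors) for limb in ("inflation",
                                                       "deflation"))
        return TrialFit(trial_id="t", inflation_sd=15.0, deflation_sd=7.0,
                        tlc_ml=1440.0, auto_peep=0.0, limb_fits=fits)

    def test_single_fit_summary(self):
        summary = fit_error_summary([self._trial_with_errors([5.0])])
        assert summary.loc["inflation", "error_ml_median"] == 5.0
        assert summary.loc["inflation", "error_ml_iqr_low"] == 5.0
        assert summary.loc["inflation", "error_ml_iqr_high"] == 5.0

    def test_pooled_median(self):
        summary = fit_error_summary(
            [self._trial_with_errors([1.0, 2.0, 3.0, 4.0, 5.0])])
        assert summary.loc["deflation", "error_ml_median"] == 3.0

    def test_deflation_percent_error_below_inflation(self, rng):
        """With equal volume noise, the deflation limb (larger volumes,
        tighter SD) fits with a smaller percentage error — the ordering the
        error summary is designed to expose."""
        trials = []
        for t in range(10):
            peeps = [10.0, 15.0, 20.0, 25.0]
            top = [31.0 - 0.1 * t, 29.0, 27.5, 26.5]
            tcp = [15.0, 17.0, 19.5, 22.0]
            loops = _loops_from_truth(peeps, top, tcp, 15.0, 7.0, 1440.0)
            noisy = []
            for l in loops:
                noisy.append(PVLoop(
                    peep=l.peep,
                    inflation_p=l.inflation_p,
                    inflation_v=np.maximum(
                        l.inflation_v + rng.normal(0, 10, l.inflation_v.size),
                        0.0),
                    deflation_p=l.deflation_p,
                    deflation_v=np.maximum(
                        l.deflation_v + rng.normal(0, 10, l.deflation_v.size),
                        0.0)))
            fits = []
            for l in noisy:
                fits.append(fit_limb_mean(
                    (l.inflation_p, l.inflation_v), 15.0, 1440.0,
                    peep=l.peep, kind="inflation"))
                fits.append(fit_limb_mean(
                    (l.deflation_p[::-1], l.deflation_v[::-1]), 7.0, 1440.0,
                    peep=l.peep, kind="deflation"))
            trials.append(TrialFit(
                trial_id=f"t{t}", inflation_sd=15.0, deflation_sd=7.0,
                tlc_ml=1440.0, auto_peep=0.0, limb_fits=tuple(fits)))
        summary = fit_error_summary(trials)
        assert (summary.loc["deflation", "error_pct_median"]
                < summary.loc["inflation", "error_pct_median"])
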