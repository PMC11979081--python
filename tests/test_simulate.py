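"""Generator: beat shape, trace assembly, cohorts, ground-truth contracts."""
import numpy as np
import pytest
from scipy import stats as sps

import stumpwave as sw
from stumpwave.exceptions import ValidationError
from stumpwave.simulate import (
    _artifact_template,
    _descent_shape,
    analytic_features,
    derived_asymptote,
    generate_beat,
    generate_cohort,
    generate_trace,
    sample_segments_for_group,
)

from conftest import FS, clean_params, template_beat


class TestBeatShape:
    def test_amplitude_endpoints_exact(self):
        beat = generate_beat(clean_params(sbp=120, dbp=80), FS)
        assert beat.max() == pytest.approx(120.0, abs=1e-12)
        assert beat[0] == pytest.approx(80.0, abs=1e-12)

    def test_diastolic_log_slope_matches_tau(self):
        # With an explicit zero asymptote the diastole is a pure exponential:
        # the least-squares slope of log(P) must equal -1/tau.
        p = clean_params(tau=1.2, asymptote=0.0)
        beat = generate_beat(p, FS)
        n_notch = int(round(p.notch_fraction * p.period * FS))
        dia = beat[n_notch:]
        t = np.arange(dia.size) / FS
        slope = np.polyfit(t, np.log(dia), 1)[0]
        assert slope == pytest.approx(-1.0 / 1.2, abs=1e-6)

    def test_piecewise_junctions_continuous(self):
        # Analytic continuity at the upstroke top and at the notch.
        p = clean_params(notch_fraction=0.35)
        C, D, w = _descent_shape(p)
        t_up = p.upstroke_fraction * p.period
        t_n = p.notch_fraction * p.period
        assert C + D == pytest.approx(p.sbp, abs=1e-9)
        assert C + D * np.cos(w * (t_n - t_up)) == pytest.approx(
            p.notch_pressure, abs=1e-9
        )

    def test_descent_arrives_steeper_than_diastole(self):
        # The notch must be a positive curvature spike: the slope jumps up.
        p = clean_params()
        beat = template_beat(p)
        n_notch = int(round(p.notch_fraction * p.period * FS))
        slope_before = (beat[n_notch - 1] - beat[n_notch - 2]) * FS
        slope_after = (beat[n_notch + 1] - beat[n_notch]) * FS
        assert slope_before < slope_after < 0

    def test_foot_continuity_with_derived_asymptote(self):
        # Default asymptote: the diastolic exponential lands on DBP at cycle
        # end, so consecutive cycles join continuously.
        p = clean_params(tau=0.7)
        a = derived_asymptote(p)
        t_dia = (1 - p.notch_fraction) * p.period
        p_end = a + (p.notch_pressure - a) * np.exp(-t_dia / p.tau)
        assert p_end == pytest.approx(p.dbp, abs=1e-12)

    def test_diastolic_area_identity_zero_asymptote(self):
        # integral P dt = tau * (P_start - P_end) for a zero-asymptote decay.
        p = clean_params(tau=1.0, asymptote=0.0)
        beat = generate_beat(p, FS)
        n_notch = int(round(p.notch_fraction * p.period * FS))
        dia = beat[n_notch:]
        area = np.trapezoid(dia, dx=1.0 / FS)
        expected = p.tau * (dia[0] - dia[-1])
        assert area == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(sbp=90, notch_pressure=98),       # sbp <= notch
            dict(notch_pressure=70, dbp=80),        # notch <= dbp
            dict(upstroke_fraction=0.5, notch_fraction=0.4),
            dict(tau=-1.0),
            dict(noise_sd=-0.1),
            dict(artifact_rate=1.0),
            dict(asymptote=85.0),                   # asymptote >= dbp
            dict(asymptote=-5.0),                   # explicit asymptote < 0
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValidationError):
            clean_params(**kw)


class TestAnalyticFeatures:
    def test_matches_high_resolution_integration(self):
        # Oracle: trapezoidal integration of the template at 10 kHz, with
        # the heart rate chosen so piece boundaries fall on grid points and
        # the cycle closed at its known end-diastolic value (= DBP).
        p = clean_params(tau=1.3, heart_rate=75.0)
        hi_fs = 10_000.0
        beat = np.append(template_beat(p, fs=hi_fs), p.dbp)
        feats = analytic_features(p)
        t_n = int(round(p.notch_fraction * p.period * hi_fs))
        dt = 1.0 / hi_fs
        area_sys = np.trapezoid(beat[: t_n + 1], dx=dt)
        area_dia = np.trapezoid(beat[t_n:], dx=dt)
        assert feats.area_sys == pytest.approx(area_sys, rel=1e-6)
        assert feats.area_dia == pytest.approx(area_dia, rel=1e-6)
        assert feats.mbp == pytest.approx(
            np.trapezoid(beat, dx=dt) / p.period, rel=1e-6
        )

    def test_basic_panel_values(self):
        p = clean_params()
        f = analytic_features(p)
        assert (f.sbp, f.dbp, f.pp) == (120.0, 80.0, 40.0)
        assert f.inc_bp == p.notch_pressure
        assert f.t_sys + f.t_dia == pytest.approx(p.period)
        assert f.area_total == pytest.approx(f.area_sys + f.area_dia)


class TestTraceGeneration:
    def test_60s_at_100hz_gives_6000_samples(self):
        trace, _ = generate_trace(clean_params(), duration=60.0, sampling_rate=100.0)
        assert trace.n == 6000

    def test_hr60_60s_gives_60_beat_feet(self):
        _, truth = generate_trace(
            clean_params(heart_rate=60.0), duration=60.0, sampling_rate=100.0
        )
        assert truth.n_beats == 60

    def test_seeded_determinism_bitwise(self):
        p = sw.BeatModelParams(seed=7, noise_sd=1.5, artifact_rate=0.1)
        t1, g1 = generate_trace(p, 30.0, 100.0)
        t2, g2 = generate_trace(p, 30.0, 100.0)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.beat_start_indices, g2.beat_start_indices)
        assert np.array_equal(g1.artifact_flags, g2.artifact_flags)

    def test_duration_shorter_than_cycle_rejected(self):
        with pytest.raises(ValidationError):
            generate_trace(clean_params(heart_rate=60.0), duration=0.5)

    def test_truth_invariants(self):
        p = sw.BeatModelParams(seed=3, artifact_rate=0.2)
        _, truth = generate_trace(p, 30.0, 100.0)
        assert np.all(np.diff(truth.beat_start_indices) > 0)
        assert truth.notch_indices.size == truth.n_beats
        assert truth.artifact_flags.size == truth.n_beats
        assert np.all(truth.notch_indices > truth.beat_start_indices)

    def test_artifact_correlates_below_gate(self):
        tmpl = template_beat(clean_params())
        art = _artifact_template(tmpl)
        r = np.corrcoef(art, tmpl)[0, 1]
        assert r < 0.95


class TestCohort:
    def test_default_group_sizes(self):
        recs = generate_cohort(sw.default_cohort_params(seed=0))
        counts = [sum(r.cow_group == g for r in recs) for g in range(1, 6)]
        assert tuple(counts) == (12, 12, 31, 18, 5)

    def test_default_pp_group_means(self):
        params = sw.default_cohort_params()
        assert tuple(g.pp_mean for g in params.ica_groups) == (
            23.4, 27.7, 18.9, 12.2, 11.7,
        )

    def test_drawn_sbp_mean_matches_configured_distribution(self):
        # Monte-Carlo vs the exact truncated-normal means (scipy oracle).
        params = sw.default_cohort_params(group_sizes=(500, 0, 0, 0, 0))
        draws = []
        for rep in range(10):
            recs = generate_cohort(
                sw.default_cohort_params(group_sizes=(500, 0, 0, 0, 0), seed=rep)
            )
            draws.extend(r.ica_features.sbp for r in recs)
        draws = np.asarray(draws)
        expected = params.ica_groups[0].expected_sbp_mean()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_tau_distribution_identical_across_groups(self):
        params = sw.default_cohort_params()
        assert len({(g.tau_mean, g.tau_sd) for g in params.ica_groups}) == 1

    def test_cohort_determinism(self):
        a = sw.records_to_frame(generate_cohort(sw.default_cohort_params(seed=11)))
        b = sw.records_to_frame(generate_cohort(sw.default_cohort_params(seed=11)))
        assert a.equals(b)

    def test_all_groups_zero_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(sw.default_cohort_params(group_sizes=(0,) * 5))

    def test_backflow_probs_validated(self):
        with pytest.raises(ValidationError):
            sw.default_cohort_params(
                backflow_probs=((0.5, 0.4, 0.2),) * 5  # does not sum to 1
            )

    def test_segment_samples_classify_to_their_group(self):
        rng = np.random.default_rng(0)
        for group in range(1, 6):
            for _ in range(10):
                states = sample_segments_for_group(group, rng)
                assert sw.classify_cow(states) == group

    def test_trace_mode_attaches_paired_recordings(self):
        params = sw.default_cohort_params(
            group_sizes=(1, 0, 1, 0, 0), mode="traces", duration=10.0, seed=2
        )
        recs = generate_cohort(params)
        assert len(recs) == 2
        for r in recs:
            assert r.ica_trace.channel == sw.Channel.ICA_STUMP
            assert r.radial_trace.channel == sw.Channel.RADIAL
            assert r.ica_trace.n == 1000
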