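"""Piecewise power-law model: evaluation, segment fits, breakpoint search."""

import itertools

import numpy as np
import pytest

from releasekin import (
    MultiphasicFit,
    PhaseSegment,
    ReleaseProfile,
    detect_breakpoints,
    eval_multiphasic,
    fit_multiphasic,
    phase_report,
)
from releasekin.exceptions import (
    DataError,
    DomainError,
    ParameterError,
    PartitionError,
)
from releasekin.synthetic import ReleaseGeneratorSpec, generate_release_profile

TWO_PHASE = ((0.36, 0.23, 5.0), (0.17, 0.73, 14.0))


def _two_segment_fit():
    segments = [
        PhaseSegment("I_II", k=0.1, n=0.5, t_start=0.0, t_end=4.0,
                     q_end=0.2, r_squared=1.0),
        PhaseSegment("III", k=0.05, n=1.0, t_start=4.0, t_end=10.0,
                     q_end=0.5, r_squared=1.0),
    ]
    return MultiphasicFit(segments=segments, breakpoints=[4.0], overall_sse=0.0)


class TestEval:
    def test_boundary_belongs_to_left_segment(self):
        fit = _two_segment_fit()
        assert eval_multiphasic(fit, [4.0])[0] == pytest.approx(0.2)  # 0.1 * sqrt(4)

    def test_interior_points_and_zero(self):
        fit = _two_segment_fit()
        q = eval_multiphasic(fit, [0.0, 9.0])
        assert q[0] == 0.0
        assert q[1] == pytest.approx(0.45)  # 0.05 * 9

    def test_beyond_range(self):
        fit = _two_segment_fit()
        with pytest.raises(DomainError):
            eval_multiphasic(fit, [11.0])
        q = eval_multiphasic(fit, [12.0], extrapolate=True)
        assert q[0] == pytest.approx(0.05 * 12)

    def test_empty_segment_list_rejected(self):
        with pytest.raises(DataError):
            MultiphasicFit(segments=[], breakpoints=[], overall_sse=0.0)


def _noiseless_profile(times):
    spec = ReleaseGeneratorSpec(
        segments=TWO_PHASE, sampling_times=tuple(times),
        noise_sd=0.0, clamp_to_unit=False,
    )
    return generate_release_profile(spec)


class TestFit:
    def test_noiseless_two_phase_recovery(self, two_phase_times):
        profile = _noiseless_profile(two_phase_times)
        fit = fit_multiphasic(profile, breakpoints=[5.0], n_phases=2)
        for segment, (k, n, _) in zip(fit.segments, TWO_PHASE):
            assert segment.k == pytest.approx(k, rel=1e-6)
            assert segment.n == pytest.approx(n, rel=1e-6)
        assert fit.breakpoint_mode == "user_supplied"
        assert fit.overall_sse == pytest.approx(0.0, abs=1e-15)

    def test_auto_breakpoint_matches_truth(self, two_phase_times):
        profile = _noiseless_profile(two_phase_times)
        fit = fit_multiphasic(profile, breakpoints="auto", n_phases=2)
        assert fit.breakpoints == [5.0]
        assert fit.breakpoint_mode == "auto"

    def test_partition_covers_every_positive_observation(self, two_phase_times):
        profile = _noiseless_profile(two_phase_times)
        fit = fit_multiphasic(profile, breakpoints=[5.0], n_phases=2)
        assert sum(s.n_obs for s in fit.segments) == np.sum(profile.times > 0)
        assert fit.segments[0].t_start == 0.0
        assert fit.segments[-1].t_end == profile.times.max()

    def test_q_end_nondecreasing_and_observed(self, two_phase_times):
        profile = _noiseless_profile(two_phase_times)
        fit = fit_multiphasic(profile, breakpoints=[5.0], n_phases=2)
        q_ends = [s.q_end for s in fit.segments]
        assert q_ends == sorted(q_ends)
        # q_end is the observed value at the last observation of the segment
        assert fit.segments[-1].q_end == profile.q[-1]

    def test_degenerate_single_power_law(self):
        t = np.linspace(0.5, 20.0, 24)
        profile = ReleaseProfile(t, 0.08 * t**0.55, q_tolerance=0.1)
        fit = fit_multiphasic(profile, breakpoints="auto", n_phases=2)
        single = 0.0  # single-phase SSE is zero for exact power-law data
        assert fit.overall_sse <= single + 1e-12
        # the two fitted exponents agree with the generating one
        for segment in fit.segments:
            assert segment.n == pytest.approx(0.55, abs=1e-6)

    def test_errors(self, two_phase_times):
        profile = _noiseless_profile(two_phase_times)
        with pytest.raises(ParameterError):
            fit_multiphasic(profile, breakpoints=[9.0, 5.0], n_phases=3)
        with pytest.raises(ParameterError):
            fit_multiphasic(profile, breakpoints=[99.0], n_phases=2)
        with pytest.raises(PartitionError):
            # breakpoint right before the last observation leaves < 3 points
            fit_multiphasic(profile, breakpoints=[13.5], n_phases=2)
        with pytest.raises(DataError):
            fit_multiphasic(
                ReleaseProfile([1.0, 2.0, 3.0], [0.1, 0.2, 0.3]), [2.0], 2
            )


class TestDetect:
    def test_matches_exhaustive_enumeration(self):
        """Auto search agrees with scoring every admissible partition via the
        public user-supplied-breakpoint path (independent enumeration)."""
        times = np.linspace(0.5, 14.0, 15)
        spec = ReleaseGeneratorSpec(
            segments=TWO_PHASE, sampling_times=tuple(times),
            noise_sd=0.01, clamp_to_unit=False, seed=12,
        )
        profile = generate_release_profile(spec)
        auto = detect_breakpoints(profile, n_phases=2, min_points=3)
        best_sse, best_bp = np.inf, None
        for bp in times[2:-3]:  # every candidate leaving >= 3 points per side
            fit = fit_multiphasic(profile, breakpoints=[float(bp)], n_phases=2)
            if fit.overall_sse < best_sse:
                best_sse, best_bp = fit.overall_sse, float(bp)
        assert auto == [best_bp]
        auto_fit = fit_multiphasic(profile, breakpoints=auto, n_phases=2)
        assert auto_fit.overall_sse <= best_sse + 1e-12

    def test_three_phase_detection(self):
        times = np.concatenate(
            [np.linspace(0.5, 5.0, 10), np.linspace(5.75, 14.0, 12),
             np.linspace(14.5, 20.0, 12)]
        )
        spec = ReleaseGeneratorSpec(
            segments=((0.359, 0.2348, 5.0), (0.1682, 0.7328, 14.0),
                      (0.7807, 0.0829, 20.0)),
            sampling_times=tuple(times), noise_sd=0.0, clamp_to_unit=False,
        )
        profile = generate_release_profile(spec)
        assert detect_breakpoints(profile, n_phases=3) == [5.0, 14.0]

    def test_pure_power_law_argmin_property(self):
        t = np.linspace(1.0, 12.0, 12)
        profile = ReleaseProfile(t, 0.05 * t**0.6)
        auto = detect_breakpoints(profile, n_phases=2)
        best = fit_multiphasic(profile, breakpoints=auto, n_phases=2).overall_sse
        for bp in t[2:-3]:
            sse = fit_multiphasic(profile, [float(bp)], 2).overall_sse
            assert best <= sse + 1e-12

    def test_no_admissible_partition(self):
        profile = ReleaseProfile([1.0, 2.0, 3.0, 4.0], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(PartitionError):
            detect_breakpoints(profile, n_phases=2, min_points=3)


class TestReport:
    def test_two_segment_report(self):
        report = phase_report(_two_segment_fit())
        assert list(report["phase"]) == ["I_II", "III"]
        assert list(report.columns[:6]) == [
            "phase", "k", "n", "r_squared", "t_end_days", "q_end",
        ]

    def test_three_segment_labels_and_final_q(self):
        times = np.concatenate(
            [np.linspace(0.5, 5.0, 8), np.linspace(6.0, 14.0, 8),
             np.linspace(15.0, 20.0, 6)]
        )
        spec = ReleaseGeneratorSpec(
            segments=((0.359, 0.2348, 5.0), (0.1682, 0.7328, 14.0),
                      (0.7807, 0.0829, 20.0)),
            sampling_times=tuple(times), noise_sd=0.0, clamp_to_unit=True,
        )
        profile = generate_release_profile(spec)
        fit = fit_multiphasic(profile, breakpoints=[5.0, 14.0], n_phases=3)
        report = phase_report(fit)
        assert list(report["phase"]) == ["I_II", "III", "IV"]
        # complete release: observed terminal fraction reaches 1.00 (clamped)
        assert report["q_end"].iloc[-1] == pytest.approx(1.0, abs=0.01)
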