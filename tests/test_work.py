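"""Strain differentiation, work integrals and global aggregation."""

import numpy as np
import pytest

from pslwork import (
    IncompleteSegmentationError,
    InsufficientDataError,
    LVPressureCurve,
    SegmentWork,
    StrainTrace,
    aggregate_global,
    segment_work,
    strain_rate,
    subject_work,
)
from pslwork.work import segment_work_matrix


def constant_pressure(events, value=100.0):
    t = np.linspace(events.t_mvc, events.t_mvo, 501)
    t = np.union1d(t, [events.t_avo, events.t_avc])
    return LVPressureCurve(
        times=t, pressures=np.full_like(t, value), events=events, sbp=value
    )


def linear_systolic_trace(events, peak=-15.0, n=181, segment_id=1):
    """Linear shortening 0 -> peak over systole, flat through IVR."""
    t = np.union1d(np.linspace(events.t_mvc, events.t_mvo, n), [events.t_avc])
    eps = np.where(
        t <= events.t_avc, peak * (t - events.t_mvc) / (events.t_avc - events.t_mvc),
        peak,
    )
    return StrainTrace(segment_id=segment_id, times=t, strain=eps)


def smooth_random_trace(events, rng, segment_id=1):
    """Smooth sinusoid mixture, zero at cycle start, |strain| < 50%."""
    T = events.t_mvo
    t = np.linspace(0.0, T, 160)
    a = rng.uniform(5.0, 22.0)
    b = rng.uniform(-3.0, 3.0)
    c = rng.uniform(-2.0, 2.0)
    eps = (
        -a * 0.5 * (1.0 - np.cos(np.pi * t / T))
        + b * np.sin(2 * np.pi * t / T)
        + c * np.sin(4 * np.pi * t / T)
    )
    return StrainTrace(segment_id=segment_id, times=t, strain=eps)


class TestStrainRate:
    def test_linear_strain_gives_constant_rate(self):
        t = np.linspace(0, 1, 101)
        tr = StrainTrace(1, t, -10.0 * t)
        np.testing.assert_allclose(strain_rate(tr), -10.0, atol=1e-9)

    def test_constant_strain_gives_zero_rate(self):
        t = np.linspace(0, 1, 51)
        tr = StrainTrace(1, t, np.full_like(t, -7.5))
        np.testing.assert_allclose(strain_rate(tr), 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.linspace(0, 1, 1001)  # 1 kHz
        tr = StrainTrace(1, t, -5.0 * np.sin(2 * np.pi * t))
        expected = -10.0 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(strain_rate(tr) - expected)) < 1e-3

    def test_too_few_samples_rejected(self):
        tr = StrainTrace(1, np.array([0.0, 0.1]), np.array([0.0, -1.0]))
        with pytest.raises(InsufficientDataError):
            strain_rate(tr)


class TestSegmentWork:
    def test_constant_pressure_linear_strain_exact(self, events):
        """With constant P, net work is P times the strain excursion."""
        p = constant_pressure(events, 100.0)
        res = segment_work(linear_systolic_trace(events, -15.0), p, events)
        assert res.work_index == pytest.approx(1500.0, abs=1e-8)
        assert res.constructive == pytest.approx(1500.0, abs=1e-8)
        assert res.wasted == pytest.approx(0.0, abs=1e-10)

    def test_pure_systolic_lengthening_is_wasted(self, events):
        p = constant_pressure(events, 100.0)
        res = segment_work(linear_systolic_trace(events, +15.0), p, events)
        assert res.constructive == pytest.approx(0.0, abs=1e-10)
        assert res.wasted == pytest.approx(1500.0, abs=1e-8)

    def test_post_systolic_shortening_creates_wasted_work(
        self, events, pressure_curve
    ):
        """2% shortening during IVR counts as wasted under the phase rules."""
        t = np.union1d(np.linspace(0, events.t_mvo, 200),
                       [events.t_avo, events.t_avc])
        eps = np.where(
            t <= events.t_avc,
            -15.0 * 0.5 * (1 - np.cos(np.pi * np.clip(
                (t - events.t_avo) / (events.t_avc - events.t_avo), 0, 1))),
            -15.0 - 2.0 * np.sin(
                np.pi * (t - events.t_avc) / (events.t_mvo - events.t_avc)
            ),
        )
        tr = StrainTrace(1, t, eps)
        res = segment_work(tr, pressure_curve, events)
        assert res.wasted > 0
        fine = segment_work(tr, pressure_curve, events, n_grid=2000 * 16)
        assert res.wasted == pytest.approx(fine.wasted, rel=5e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_refinement_oracle_on_random_smooth_traces(
        self, events, pressure_curve, seed
    ):
        """Default-grid integrals agree with 16x-refined quadrature to 0.5%."""
        rng = np.random.default_rng(seed)
        tr = smooth_random_trace(events, rng)
        res = segment_work(tr, pressure_curve, events)
        fine = segment_work(tr, pressure_curve, events, n_grid=2000 * 16)
        scale = fine.constructive + fine.wasted
        assert abs(res.constructive - fine.constructive) <= 5e-3 * scale
        assert abs(res.wasted - fine.wasted) <= 5e-3 * scale
        assert abs(res.work_index - fine.work_index) <= 5e-3 * scale

    def test_decomposition_identity_and_nonnegativity(self, events, pressure_curve):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tr = smooth_random_trace(events, rng)
            res = segment_work(tr, pressure_curve, events, n_grid=400)
            assert res.work_index == res.constructive - res.wasted  # exact
            assert res.constructive >= 0.0
            assert res.wasted >= 0.0

    def test_pressure_scale_linearity(self, events, pressure_curve):
        rng = np.random.default_rng(7)
        tr = smooth_random_trace(events, rng)
        k = 1.7
        scaled = LVPressureCurve(
            times=pressure_curve.times,
            pressures=pressure_curve.pressures * k,
            events=events,
            sbp=pressure_curve.sbp * k,
            template=pressure_curve.template,
        )
        r1 = segment_work(tr, pressure_curve, events, n_grid=500)
        r2 = segment_work(tr, scaled, events, n_grid=500)
        assert r2.work_index == pytest.approx(k * r1.work_index, rel=1e-12)
        assert r2.constructive == pytest.approx(k * r1.constructive, rel=1e-12)
        assert r2.wasted == pytest.approx(k * r1.wasted, rel=1e-12)

    def test_domain_mismatch_rejected(self, events, pressure_curve):
        from pslwork import DomainError

        t = np.linspace(0.0, events.t_avc, 100)  # stops before MVO
        tr = StrainTrace(1, t, -10.0 * t / events.t_avc)
        with pytest.raises(DomainError):
            segment_work(tr, pressure_curve, events)


class TestAggregateGlobal:
    @staticmethod
    def _works(values):
        return [
            SegmentWork(i + 1, wi, cw, ww)
            for i, (wi, cw, ww) in enumerate(values)
        ]

    def test_identical_segments_mean(self):
        works = self._works([(1500.0, 1520.0, 20.0)] * 17)
        res = aggregate_global(works, [-18.0] * 17)
        assert res.gwi == pytest.approx(1500.0)
        assert res.gls == pytest.approx(-18.0)

    def test_efficiency_from_cw_ww(self):
        works = self._works([(1900.0, 1950.0, 50.0)] * 17)
        res = aggregate_global(works, [-18.0] * 17)
        assert res.gwe == pytest.approx(97.5)

    def test_permutation_invariance_and_mean_oracle(self):
        rng = np.random.default_rng(3)
        vals = [(float(a), float(a + b), float(b)) for a, b in
                zip(rng.uniform(800, 2500, 17), rng.uniform(0, 120, 17))]
        peaks = list(rng.uniform(-25, -10, 17))
        res = aggregate_global(self._works(vals), peaks)
        assert res.gwi == pytest.approx(np.mean([v[0] for v in vals]), rel=1e-12)
        perm = rng.permutation(17)
        shuffled = [self._works(vals)[i] for i in perm]
        res2 = aggregate_global(shuffled, peaks)
        assert res2.gwi == pytest.approx(res.gwi, rel=1e-12)
        assert res2.gcw == pytest.approx(res.gcw, rel=1e-12)
        assert res2.gww == pytest.approx(res.gww, rel=1e-12)

    def test_missing_segment_rejected(self):
        works = self._works([(1000.0, 1000.0, 0.0)] * 17)[:16]
        with pytest.raises(IncompleteSegmentationError):
            aggregate_global(works, [-18.0] * 17)

    def test_gls_weights(self):
        works = self._works([(1000.0, 1000.0, 0.0)] * 17)
        peaks = [-10.0] * 16 + [-27.0]
        w = [1.0] * 16 + [2.0]
        res = aggregate_global(works, peaks, weights=w)
        assert res.gls == pytest.approx((16 * -10.0 + 2 * -27.0) / 18.0)


class TestSubjectLevel:
    def test_ideal_contraction_has_full_efficiency(self, events, pressure_curve):
        """Monotone systolic shortening + IVR relengthening wastes nothing."""
        rng = np.random.default_rng(11)
        t = np.union1d(np.linspace(0, events.t_mvo, 150),
                       [events.t_avo, events.t_avc])
        traces = []
        for seg in range(1, 18):
            a = rng.uniform(14.0, 22.0)
            x = np.clip((t - events.t_avo) / (events.t_avc - events.t_avo), 0, 1)
            y = np.clip((t - events.t_avc) / (events.t_mvo - events.t_avc), 0, 1)
            eps = -a * 0.5 * (1 - np.cos(np.pi * x)) + np.where(
                t > events.t_avc, 0.15 * a * 0.5 * (1 - np.cos(np.pi * y)), 0.0
            )
            traces.append(StrainTrace(seg, t, eps))
        res = subject_work(traces, pressure_curve, events)
        assert res.gww == pytest.approx(0.0, abs=1e-9)
        assert res.gwe == 100.0
        assert res.gwi > 0 and res.gcw > 0

    def test_peak_strain_reduction_reduces_work_monotonically(
        self, events, pressure_curve
    ):
        def make(scale):
            t = np.union1d(np.linspace(0, events.t_mvo, 150),
                           [events.t_avo, events.t_avc])
            x = np.clip((t - events.t_avo) / (events.t_avc - events.t_avo), 0, 1)
            traces = [
                StrainTrace(s, t, -scale * (14 + 0.3 * s) * 0.5 * (1 - np.cos(np.pi * x)))
                for s in range(1, 18)
            ]
            return subject_work(traces, pressure_curve, events)

        full, mid, low = make(1.0), make(0.85), make(0.7)
        assert abs(full.gls) > abs(mid.gls) > abs(low.gls)
        assert full.gwi > mid.gwi > low.gwi
        assert full.gcw > mid.gcw > low.gcw

    def test_matrix_path_matches_per_trace_path(self, events, pressure_curve):
        rng = np.random.default_rng(5)
        traces = [smooth_random_trace(events, rng, segment_id=s)
                  for s in range(1, 18)]
        strain = np.vstack([tr.strain for tr in traces])
        wi, cw, ww = segment_work_matrix(
            strain, traces[0].times, pressure_curve, events, n_grid=700
        )
        for i, tr in enumerate(traces):
            single = segment_work(tr, pressure_curve, events, n_grid=700)
            assert single.work_index == pytest.approx(float(wi[i]), rel=1e-12)
            assert single.wasted == pytest.approx(float(ww[i]), abs=1e-12)
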