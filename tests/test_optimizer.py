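"""Design matrix, sweeps, and continuous optimization machinery.

CFD-free: the expensive coverage evaluation is replaced by analytic test
objectives; the end-to-end CFD optimization lives in the acceptance suite.
"""

import numpy as np
import pytest

from microtrench.optimizer import (CoverageEvaluator, DesignSpace,
                                   SweepRecord, enumerate_design_matrix,
                                   optimize_continuous, run_sweep,
                                   width_asymptote_study)


class AnalyticEvaluator:
    """Quadratic bowl objective with a known interior maximizer."""

    def __init__(self, h0=0.79e-3, w0=1.6e-3, a0=51.8, fmax=0.8):
        self.h0, self.w0, self.a0, self.fmax = h0, w0, a0, fmax
        self.cache = {}
        self.errors = {}
        self.n_calls = 0
        self.clear_height = 0.508e-3

    def key(self, h, w, a):
        return (round(h, 12), round(w, 12), round(a, 9))

    def __call__(self, h, w, a):
        key = self.key(h, w, a)
        if key in self.cache:
            return self.cache[key]
        self.n_calls += 1
        f = self.fmax - (((h - self.h0) / 3e-3) ** 2
                         + ((w - self.w0) / 3e-3) ** 2
                         + ((a - self.a0) / 88.0) ** 2)
        self.cache[key] = f
        return f


class TestDesignMatrix:
    def test_three_levels_give_27_labeled_designs(self):
        recs = enumerate_design_matrix(levels_per_variable=3)
        assert len(recs) == 27
        labels = {r.label for r in recs}
        expected = {f"H{i}A{j}W{k}" for i in (1, 2, 3) for j in (1, 2, 3)
                    for k in (1, 2, 3)}
        assert labels == expected          # complete, no missing cell

    def test_single_level_matrix(self):
        recs = enumerate_design_matrix(levels_per_variable=1)
        assert len(recs) == 1 and recs[0].label == "H1A1W1"

    def test_mixed_levels_are_lexicographic(self):
        recs = enumerate_design_matrix(levels_per_variable=(2, 3, 4))
        assert len(recs) == 24
        assert [r.label for r in recs[:5]] == [
            "H1A1W1", "H1A1W2", "H1A1W3", "H1A1W4", "H1A2W1"]
        # index 1 is the smallest level of each variable
        assert recs[0].height < recs[-1].height
        assert recs[0].draft_angle_deg < recs[-1].draft_angle_deg

    def test_levels_respect_bounds(self):
        space = DesignSpace()
        for rec in enumerate_design_matrix(space, 3):
            assert space.height_bounds[0] <= rec.height <= space.height_bounds[1]
            assert space.draft_angle_bounds[0] <= rec.draft_angle_deg \
                <= space.draft_angle_bounds[1]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DesignSpace(height_bounds=(2e-3, 1e-3))


class TestRunSweep:
    def test_sweep_fills_records_and_caches(self):
        ev = AnalyticEvaluator()
        recs = enumerate_design_matrix(levels_per_variable=2)
        run_sweep(recs, ev)
        assert all(r.f is not None and r.error is None for r in recs)
        # duplicate sweep is served from cache bit-identically
        before = [r.f for r in recs]
        calls = ev.n_calls
        run_sweep(recs, ev)
        assert ev.n_calls == calls
        assert [r.f for r in recs] == before

    def test_sweep_order_invariance(self):
        recs1 = enumerate_design_matrix(levels_per_variable=2)
        recs2 = list(reversed(enumerate_design_matrix(levels_per_variable=2)))
        run_sweep(recs1, AnalyticEvaluator())
        run_sweep(recs2, AnalyticEvaluator())
        by_label1 = {r.label: r.f for r in recs1}
        by_label2 = {r.label: r.f for r in recs2}
        assert by_label1 == by_label2

    def test_all_failed_sweep_raises(self):
        class FailingEvaluator(AnalyticEvaluator):
            def __call__(self, h, w, a):
                key = self.key(h, w, a)
                self.errors[key] = "boom"
                self.cache[key] = 0.0
                return 0.0
        with pytest.raises(RuntimeError, match="failed"):
            run_sweep(enumerate_design_matrix(levels_per_variable=2),
                      FailingEvaluator())


class TestOptimizeContinuous:
    def test_recovers_analytic_maximizer(self):
        space = DesignSpace()
        ev = AnalyticEvaluator()
        res = optimize_continuous(space, ev, budget=250, seed=3)
        # within 1% of each bound's range
        assert abs(res.best_height - ev.h0) < 0.01 * 2.99e-3
        assert abs(res.best_width - ev.w0) < 0.01 * 2.99e-3
        assert abs(res.best_draft_angle_deg - ev.a0) < 0.01 * 86.0
        assert res.best_f == pytest.approx(ev.fmax, abs=1e-4)

    def test_seeded_runs_identical(self):
        traces = []
        for _ in range(2):
            res = optimize_continuous(DesignSpace(), AnalyticEvaluator(),
                                      budget=80, seed=11)
            traces.append(res.trace)
        assert traces[0] == traces[1]

    def test_best_f_is_max_of_trace_and_reproducible(self):
        ev = AnalyticEvaluator()
        res = optimize_continuous(DesignSpace(), ev, budget=60, seed=5)
        assert res.best_f == max(t[3] for t in res.trace)
        # re-evaluating the best design reproduces best_f bit-exactly
        assert ev(res.best_height, res.best_width,
                  res.best_draft_angle_deg) == res.best_f

    def test_trace_within_bounds(self):
        space = DesignSpace()
        res = optimize_continuous(space, AnalyticEvaluator(), budget=60,
                                  seed=7)
        for h, w, a, _ in res.trace:
            assert space.height_bounds[0] - 1e-15 <= h <= space.height_bounds[1] + 1e-15
            assert space.draft_angle_bounds[0] - 1e-12 <= a \
                <= space.draft_angle_bounds[1] + 1e-12


class TestWidthAsymptote:
    def test_requires_increasing_widths(self):
        with pytest.raises(ValueError, match="increasing"):
            width_asymptote_study(2.5e-3, [2e-3, 1e-3],
                                  evaluator=AnalyticEvaluator())

    def test_requires_trench_height(self):
        with pytest.raises(ValueError, match="h_total"):
            width_asymptote_study(0.2e-3, [1e-3, 2e-3],
                                  evaluator=AnalyticEvaluator())

    def test_single_width_degenerate_curve(self):
        class Saturating(AnalyticEvaluator):
            def __call__(self, h, w, a):
                self.n_calls += 1
                return 1.0 - np.exp(-w / 1e-3)
        out = width_asymptote_study(2.5e-3, [1e-3], evaluator=Saturating())
        assert out["f"] and "f_asymptote" not in out

    def test_geometric_extrapolation_of_saturating_curve(self):
        class Saturating(AnalyticEvaluator):
            def __call__(self, h, w, a):
                self.n_calls += 1
                return 0.9 - 0.5 * 0.5 ** (w / 1e-3)
        # equally spaced widths make the decrements exactly geometric
        out = width_asymptote_study(2.5e-3, [1e-3, 2e-3, 3e-3, 4e-3],
                                    evaluator=Saturating())
        incs = out["increments"]
        assert all(b < a for a, b in zip(incs[:-1], incs[1:]))
        assert out["f_asymptote"] == pytest.approx(0.9, abs=0.01)


def test_evaluator_records_failures_as_zero():
    ev = CoverageEvaluator(resolution="sweep")
    # an unmeshable/invalid design must score zero, not raise
    f = ev(-1.0, 1e-3, 45.0)
    assert f == 0.0
    assert ev.errors
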