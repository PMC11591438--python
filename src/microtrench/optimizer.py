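"""Design-space exploration and optimization of trench geometry.

Three layers:

* :func:`enumerate_design_matrix` — the full-factorial H x A x W matrix with
  labels ``H{i}A{j}W{k}`` (index 1 = smallest level of each variable);
* :func:`run_sweep` — evaluate a batch of designs (mesh -> solve -> f) with
  per-design failure capture and hash-based caching;
* :func:`optimize_continuous` — derivative-free bounded maximization of the
  coverage objective f: a deterministic 3-level factorial scan seeds
  multi-start bounded Nelder-Mead refinements.

All evaluations share one :class:`CoverageEvaluator`, which rebuilds the
channel around each design (entrance/exit flats scale with total height so
the outflow recirculation stays inside the domain) and caches results, so a
reported best f is reproduced bit-exactly by re-evaluating its parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flow import FlowConditions, solve_steady_flow
from .geometry import BLOOD, ChannelSpec, FluidProperties, TrenchDesign, \
    make_trench_design
from .meshing import generate_mesh
from .wss import WSSBandThresholds, coverage_objective, wall_shear_stress

__all__ = [
    "DesignSpace",
    "SweepRecord",
    "OptimizationResult",
    "CoverageEvaluator",
    "enumerate_design_matrix",
    "run_sweep",
    "optimize_continuous",
    "width_asymptote_study",
]

#: Default clear channel height (m) above the patterned floor.
DEFAULT_CLEAR_HEIGHT = 0.508e-3


@dataclass(frozen=True)
class DesignSpace:
    """Bounds of the trapezoidal design space.

    Heights/widths span 0.01-3 mm.  The draft angle (from vertical) is
    searched on [2, 88] degrees: the closed interval would include the
    degenerate zero-thickness-fin limit at 0 deg (with d = 0) and an
    unbounded opening width as alpha -> 90 deg, so a small numerical margin
    is kept at both ends.  ``average_interval`` is resolution metadata for
    reporting, not a constraint.
    """

    height_bounds: tuple[float, float] = (0.01e-3, 3.0e-3)   # m
    width_bounds: tuple[float, float] = (0.01e-3, 3.0e-3)    # m
    draft_angle_bounds: tuple[float, float] = (2.0, 88.0)    # deg from vertical
    average_interval: tuple[float, float, float] = (0.1e-3, 0.1e-3, 0.3)

    def __post_init__(self):
        for name in ("height_bounds", "width_bounds", "draft_angle_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")

    def levels(self, n: int = 3):
        """n evenly spaced levels per variable (height, angle, width)."""
        h = np.linspace(*self.height_bounds, n)
        a = np.linspace(*self.draft_angle_bounds, n)
        w = np.linspace(*self.width_bounds, n)
        return h, a, w


@dataclass
class SweepRecord:
    """One design evaluation in a sweep."""

    label: str
    height: float
    width: float
    draft_angle_deg: float
    f: float | None = None
    error: str | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class OptimizationResult:
    best_height: float
    best_width: float
    best_draft_angle_deg: float
    best_f: float
    trace: list          # (h, w, alpha_deg, f) per evaluation, in order
    n_evaluations: int
    termination: str

    @property
    def best_design(self) -> TrenchDesign:
        return make_trench_design("trapezoidal", self.best_height,
                                  self.best_width, self.best_draft_angle_deg,
                                  0.0, 3)


class CoverageEvaluator:
    """Meshes, solves and scores a trapezoidal design; caches by parameters.

    Failures (non-convergence, meshing errors) are recorded and scored
    f = 0 so a sweep or optimizer can continue around them.
    """

    def __init__(self, fluid: FluidProperties = BLOOD,
                 conditions: FlowConditions | None = None,
                 thresholds: WSSBandThresholds = WSSBandThresholds(),
                 clear_height: float = DEFAULT_CLEAR_HEIGHT,
                 resolution: str = "sweep", gap: float = 0.0,
                 n_trenches: int = 3, max_iter: int = 40):
        self.fluid = fluid
        self.conditions = conditions or FlowConditions(target_bulk_wss=600.0)
        self.thresholds = thresholds
        self.clear_height = clear_height
        self.resolution = resolution
        self.gap = gap
        self.n_trenches = n_trenches
        self.max_iter = max_iter
        self.cache: dict = {}
        self.n_calls = 0
        self.errors: dict = {}

    def channel_for(self, design: TrenchDesign) -> ChannelSpec:
        h_total = self.clear_height + design.height
        return ChannelSpec(self.clear_height,
                           entrance_length=max(1.5e-3, h_total),
                           exit_length=max(2.0e-3, 2.0 * h_total))

    def key(self, h, w, alpha):
        return (round(h, 12), round(w, 12), round(alpha, 9))

    def __call__(self, h: float, w: float, alpha: float) -> float:
        key = self.key(h, w, alpha)
        if key in self.cache:
            return self.cache[key]
        self.n_calls += 1
        try:
            design = make_trench_design("trapezoidal", h, w, alpha, self.gap,
                                        self.n_trenches)
            mesh = generate_mesh(design, self.channel_for(design),
                                 self.resolution)
            flow = solve_steady_flow(mesh, self.fluid, self.conditions,
                                     max_iter=self.max_iter)
            f = coverage_objective(wall_shear_stress(flow), self.thresholds).f
        except Exception as exc:   # failed evaluation scores zero
            self.errors[key] = f"{type(exc).__name__}: {exc}"
            f = 0.0
        self.cache[key] = f
        return f


def enumerate_design_matrix(space: DesignSpace | None = None,
                            levels_per_variable=3) -> list[SweepRecord]:
    """Full-factorial design matrix with labels H{i}A{j}W{k}.

    ``levels_per_variable`` may be an int (same level count for all three
    variables) or a (n_height, n_angle, n_width) tuple.  Labels are emitted
    in lexicographic order of (i, j, k), index 1 = smallest value.
    """
    space = space or DesignSpace()
    if isinstance(levels_per_variable, int):
        nh = na = nw = levels_per_variable
    else:
        nh, na, nw = levels_per_variable
    hs = np.linspace(*space.height_bounds, nh) if nh > 1 else \
        np.array([space.height_bounds[0]])
    as_ = np.linspace(*space.draft_angle_bounds, na) if na > 1 else \
        np.array([space.draft_angle_bounds[0]])
    ws = np.linspace(*space.width_bounds, nw) if nw > 1 else \
        np.array([space.width_bounds[0]])
    out = []
    for i, h in enumerate(hs, 1):
        for j, a in enumerate(as_, 1):
            for k, w in enumerate(ws, 1):
                out.append(SweepRecord(label=f"H{i}A{j}W{k}", height=float(h),
                                       width=float(w),
                                       draft_angle_deg=float(a)))
    return out


def run_sweep(designs: list[SweepRecord],
              evaluator: CoverageEvaluator | None = None) -> list[SweepRecord]:
    """Evaluate every design in place; failures are recorded per design.

    Raises only if *every* design fails.
    """
    ev = evaluator or CoverageEvaluator()
    n_fail = 0
    for rec in designs:
        f = ev(rec.height, rec.width, rec.draft_angle_deg)
        key = ev.key(rec.height, rec.width, rec.draft_angle_deg)
        rec.f = f
        rec.error = ev.errors.get(key)
        if rec.error is not None:
            n_fail += 1
    if designs and n_fail == len(designs):
        details = "; ".join(f"{r.label}: {r.error}" for r in designs[:5])
        raise RuntimeError(f"all {len(designs)} sweep designs failed ({details} ...)")
    return designs


def optimize_continuous(space: DesignSpace | None = None,
                        evaluator: CoverageEvaluator | None = None,
                        budget: int = 90, seed: int = 0,
                        n_starts: int = 2) -> OptimizationResult:
    """Maximize f over the bounded design space.

    Deterministic under a fixed seed: a 3-level factorial scan (27
    evaluations) ranks starting points, then bounded Nelder-Mead refines the
    ``n_starts`` best distinct ones with the remaining budget.  The trace
    records every evaluation in call order.
    """
    from scipy.optimize import minimize

    space = space or DesignSpace()
    ev = evaluator or CoverageEvaluator()
    trace: list[tuple] = []

    lo = np.array([space.height_bounds[0], space.width_bounds[0],
                   space.draft_angle_bounds[0]])
    hi = np.array([space.height_bounds[1], space.width_bounds[1],
                   space.draft_angle_bounds[1]])

    def fx(x):
        h, w, a = np.clip(x, lo, hi)
        f = ev(h, w, a)
        trace.append((float(h), float(w), float(a), float(f)))
        return f

    # phase 1: deterministic factorial scan
    matrix = enumerate_design_matrix(space, 3)
    for rec in matrix:
        if len(trace) >= budget:
            break
        fx(np.array([rec.height, rec.width, rec.draft_angle_deg]))
    scan = sorted(trace, key=lambda t: -t[3])
    starts = []
    for h, w, a, f in scan:
        if all(abs(h - s[0]) + abs(w - s[1]) > 1e-6 or abs(a - s[2]) > 1e-6
               for s in starts):
            starts.append((h, w, a))
        if len(starts) >= n_starts:
            break
    termination = "budget exhausted"
    scale = hi - lo
    for h, w, a in starts:
        remaining = budget - len(trace)
        if remaining <= 4:
            break
        x0 = (np.array([h, w, a]) - lo) / scale
        # explicit simplex: bound-corner starts otherwise degenerate
        simplex = [x0]
        for i in range(3):
            v = x0.copy()
            v[i] = v[i] + 0.08 if v[i] + 0.08 <= 1.0 else v[i] - 0.08
            simplex.append(v)
        res = minimize(lambda x: -fx(x * scale + lo), x0,
                       method="Nelder-Mead",
                       bounds=[(0.0, 1.0)] * 3,
                       options={"maxfev": remaining, "xatol": 0.01,
                                "fatol": 5e-4,
                                "initial_simplex": np.array(simplex)})
        if res.status == 0:
            termination = "converged"

    if not trace:
        raise RuntimeError("optimization budget exhausted before any evaluation")
    best = max(trace, key=lambda t: t[3])
    return OptimizationResult(
        best_height=best[0], best_width=best[1], best_draft_angle_deg=best[2],
        best_f=best[3], trace=trace, n_evaluations=ev.n_calls,
        termination=termination)


def width_asymptote_study(h_total: float, widths,
                          evaluator: CoverageEvaluator | None = None,
                          draft_angle_deg: float = 45.0) -> dict:
    """f versus trench width at fixed *total* channel height.

    Fully developed wall shear scales as 1/h_total, so as the trench widens
    toward a parallel plate of height ``h_total`` the objective approaches an
    asymptote; the study reports the (w, f) curve, the increments between
    successive widths, and a geometric-extrapolation estimate of the
    asymptote when three or more widths are given.
    """
    ev = evaluator or CoverageEvaluator(n_trenches=1)
    widths = list(widths)
    if any(b >= a for a, b in zip(widths[1:], widths[:-1])):
        raise ValueError("widths must be strictly increasing")
    h = h_total - ev.clear_height
    if h <= 0:
        raise ValueError("h_total must exceed the clear channel height")
    fs = [ev(h, w, draft_angle_deg) for w in widths]
    out = {"widths": widths, "f": fs, "h_trench": h,
           "increments": [b - a for a, b in zip(fs[:-1], fs[1:])]}
    if len(fs) >= 3:
        d1, d2 = fs[-2] - fs[-3], fs[-1] - fs[-2]
        if abs(d1) > 1e-12 and abs(d2) < abs(d1):
            r = d2 / d1
            out["f_asymptote"] = min(1.0, max(0.0, fs[-1] + d2 * r / (1.0 - r)))
        else:
            out["f_asymptote"] = fs[-1]
    return out
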