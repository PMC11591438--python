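"""Wall shear stress extraction and the projected-coverage objective.

The objective f is the fraction of the wetted floor, *projected onto the
floor plane*, whose WSS magnitude lies strictly inside the
endothelial-viability band (default 10-50 dyn/cm^2):

    f = (projected length with lower < tau < upper) / (total projected length)

Each boundary sample contributes its |dx| (the floor-plane projection of its
surface element), so vertical sidewalls contribute nothing to either the
numerator or the denominator, while a trapezoidal sidewall contributes
h*tan(alpha).  By default f is evaluated over the patterned region only
(first trench leading edge to last trailing edge); the entrance/exit flats
would otherwise dilute f by an arbitrary amount of flat run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import PA_TO_DYN_CM2, FlowField

__all__ = [
    "WSSBandThresholds",
    "WSSProfile",
    "CoverageResult",
    "wall_shear_stress",
    "classify_band",
    "coverage_objective",
]

_PATTERNED = ("sidewall-down", "trench-floor", "sidewall-up", "partition-top")


@dataclass(frozen=True)
class WSSBandThresholds:
    """Viability band (dyn/cm^2); classification is strict on both ends."""

    lower: float = 10.0
    upper: float = 50.0

    def __post_init__(self):
        if not 0 < self.lower < self.upper:
            raise ValueError(f"need 0 < lower < upper, got {self.lower}, {self.upper}")


def classify_band(tau, thresholds: WSSBandThresholds):
    """'below' / 'in' / 'above' with strict inequalities: in iff lo < tau < up.

    tau at exactly a threshold is out of band (below at the lower threshold,
    above at the upper one).  Accepts scalars or arrays.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.where(tau <= thresholds.lower, "below",
                   np.where(tau >= thresholds.upper, "above", "in"))
    return out if out.ndim else str(out)


@dataclass
class WSSProfile:
    """WSS sampled along the wetted boundary, inlet to outlet.

    Arrays are per boundary quadrature sample; ``weight_dx`` is the |dx|
    projection weight of the sample (weights within one profile segment sum
    to that segment's |dx|), ``weight_arc`` the true arc-length weight.
    """

    arc: np.ndarray          # arc-length position (m)
    x: np.ndarray            # streamwise position (m)
    seg_class: np.ndarray    # segment class per sample (str)
    seg_id: np.ndarray       # profile segment index per sample
    tau: np.ndarray          # |WSS| in dyn/cm^2
    weight_dx: np.ndarray    # (m)
    weight_arc: np.ndarray   # (m)

    def class_mean(self, cls: str) -> float:
        """Arc-length-weighted mean tau over samples of one class (dyn/cm^2)."""
        m = self.seg_class == cls
        if not m.any():
            raise ValueError(f"no samples of class {cls!r}")
        return float(np.sum(self.tau[m] * self.weight_arc[m])
                     / np.sum(self.weight_arc[m]))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "arc_m": self.arc, "x_m": self.x, "class": self.seg_class,
            "segment": self.seg_id, "tau_dyn_cm2": self.tau,
            "weight_dx_m": self.weight_dx,
        })


def wall_shear_stress(flow: FlowField, mesh=None, npts: int = 2) -> WSSProfile:
    """Evaluate tau = |t . (grad u + grad u^T) . n| * mu along the wetted floor.

    ``npts`` Gauss points per boundary edge (2 by default); the flow must
    be converged (a non-converged field is refused).
    """
    if not flow.converged:
        raise ValueError("flow field is not converged; refusing WSS extraction")
    mesh = mesh or flow.mesh
    space = flow.space
    mu = flow.fluid.viscosity
    edges = mesh.wetted_edges
    geo = space.edge_geometry(edges[:, :2], npts=npts)
    conn2 = space.q2_conn[geo["elems"]]                      # (k,9)
    ue = flow.velocity[conn2]                                # (k,9,2)
    grad = np.einsum("kia,kpib->kpab", ue, geo["dN2"])       # (k,npts,2,2)
    sym = grad + np.swapaxes(grad, 2, 3)
    t, n = geo["tangent"], geo["normal"]
    trac = np.einsum("ka,kpab,kb->kp", t, sym, n) * mu       # tangential traction
    tau = np.abs(trac) * PA_TO_DYN_CM2

    segs = mesh.profile.segments
    seg_id = edges[:, 2]
    cls = np.array([segs[i].cls for i in seg_id])
    w_arc = geo["weights"]                                   # (k,npts)
    tx = np.abs(t[:, 0])
    tx[tx < 1e-12] = 0.0      # snap vertical edges to exactly zero projection
    w_dx = w_arc * tx[:, None]
    x = geo["xy"][..., 0]

    # arc-length coordinate: cumulative edge lengths in traversal order
    from .fem import GAUSS2, GAUSS3
    L = geo["length"]
    arc0 = np.concatenate([[0.0], np.cumsum(L)[:-1]])
    gp = {1: np.array([0.0]), 2: GAUSS2[0], 3: GAUSS3[0]}[npts]
    pts = 0.5 * (gp + 1.0)                    # fractions along each edge
    arc = arc0[:, None] + L[:, None] * pts[None, :]

    k, npts = tau.shape
    rep = lambda a: np.repeat(a, npts)
    return WSSProfile(
        arc=arc.ravel(), x=x.ravel(), seg_class=rep(cls), seg_id=rep(seg_id),
        tau=tau.ravel(), weight_dx=w_dx.ravel(), weight_arc=w_arc.ravel(),
    )


@dataclass
class CoverageResult:
    """Projected-coverage objective and its band decomposition (lengths in m)."""

    f: float
    length_in: float
    length_below: float
    length_above: float
    total_projected: float
    by_class: dict = field(default_factory=dict)
    thresholds: WSSBandThresholds = field(default_factory=WSSBandThresholds)

    def to_dict(self) -> dict:
        return {
            "f": self.f, "length_in_m": self.length_in,
            "length_below_m": self.length_below, "length_above_m": self.length_above,
            "total_projected_m": self.total_projected,
            "thresholds_dyn_cm2": [self.thresholds.lower, self.thresholds.upper],
            "by_class": {k: dict(v) for k, v in self.by_class.items()},
        }


def coverage_objective(wss: WSSProfile,
                       thresholds: WSSBandThresholds = WSSBandThresholds(),
                       region: str = "patterned") -> CoverageResult:
    """Evaluate f over ``region``: 'patterned' (default), 'all', or a tuple
    of segment classes.  Raises on zero total projected length (e.g. a
    region made only of vertical sidewalls)."""
    if region == "patterned":
        classes = _PATTERNED
    elif region == "all":
        classes = None
    else:
        classes = tuple(region)
    sel = np.ones(len(wss.tau), dtype=bool) if classes is None else \
        np.isin(wss.seg_class, classes)
    if not sel.any():
        raise ValueError(f"no boundary samples in region {region!r}")
    tau, w, cl = wss.tau[sel], wss.weight_dx[sel], wss.seg_class[sel]
    total = float(w.sum())
    if total <= 1e-12 * float(wss.weight_arc[sel].sum()):
        raise ValueError("zero total projected length in the evaluation region")
    band = classify_band(tau, thresholds)
    l_in = float(w[band == "in"].sum())
    l_lo = float(w[band == "below"].sum())
    l_hi = float(w[band == "above"].sum())
    by_class = {}
    for c in np.unique(cl):
        m = cl == c
        by_class[str(c)] = {
            "in": float(w[m & (band == "in")].sum()),
            "below": float(w[m & (band == "below")].sum()),
            "above": float(w[m & (band == "above")].sum()),
        }
    return CoverageResult(f=l_in / total, length_in=l_in, length_below=l_lo,
                          length_above=l_hi, total_projected=total,
                          by_class=by_class, thresholds=thresholds)
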