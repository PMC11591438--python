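"""Parametric microtrench channel geometry.

A blood-wetted surface is patterned with a row of trenches (grooves) cut into
the floor of a parallel-plate channel.  Two families are supported:

* ``vertical`` trenches — rectangular recesses with upright sidewalls
  (draft angle alpha = 0), separated by partitions of width ``d``;
* ``trapezoidal`` trenches — sidewalls inclined by a draft angle ``alpha``
  measured *from vertical*, so the opening at the floor plane is wider than
  the trench floor by ``2 * h * tan(alpha)``.  The included opening angle of
  the trench is ``theta = 2 * alpha``.  With ``d = 0`` adjacent trenches share
  a knife-edge apex (vanishing wall thickness).

Coordinates: x runs streamwise from the inlet, y points up from the
un-trenched floor plane, so trench floors sit at ``y = -h`` and the top wall
at ``y = clear_height``.  All lengths are SI metres internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FluidProperties",
    "BLOOD",
    "ChannelSpec",
    "TrenchDesign",
    "Segment",
    "WettedProfile",
    "make_trench_design",
    "build_wetted_profile",
    "SEGMENT_CLASSES",
]

#: Boundary segment classes, in the order they can appear along the floor.
SEGMENT_CLASSES = (
    "entrance-flat",
    "sidewall-down",
    "trench-floor",
    "sidewall-up",
    "partition-top",
    "exit-flat",
)


class GeometryError(ValueError):
    """Invalid geometric parameter; the message names the offending field."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity mu in Pa*s.
    density : float
        Mass density rho in kg/m^3.
    """

    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise GeometryError(f"viscosity must be > 0, got {self.viscosity}")
        if not self.density > 0:
            raise GeometryError(f"density must be > 0, got {self.density}")


#: Whole blood modelled as a homogeneous Newtonian fluid (3.5 cP, 1050 kg/m^3).
BLOOD = FluidProperties(viscosity=3.5e-3, density=1050.0)


@dataclass(frozen=True)
class ChannelSpec:
    """Parallel-plate channel above the patterned floor.

    ``clear_height`` is the gap between the un-trenched floor plane and the
    top wall; ``entrance_length`` / ``exit_length`` are the flat runs before
    the first and after the last trench opening.
    """

    clear_height: float
    entrance_length: float
    exit_length: float

    def __post_init__(self) -> None:
        if not self.clear_height > 0:
            raise GeometryError(f"clear_height must be > 0, got {self.clear_height}")
        if self.entrance_length < 0:
            raise GeometryError("entrance_length must be >= 0")
        if self.exit_length < 0:
            raise GeometryError("exit_length must be >= 0")


@dataclass(frozen=True)
class TrenchDesign:
    """Parametric trench row: kind, depth h, opening width w, draft angle,
    partition gap d and trench count.

    ``width`` is the trench width measured at the *floor* of the trench; the
    opening at the y = 0 plane is ``top_width = w + 2 h tan(alpha)``.
    """

    kind: str
    height: float
    width: float
    draft_angle_deg: float
    gap: float
    n_trenches: int

    @property
    def draft_angle_rad(self) -> float:
        return math.radians(self.draft_angle_deg)

    @property
    def included_angle_deg(self) -> float:
        """Included opening angle theta = 2 * alpha (degrees)."""
        return 2.0 * self.draft_angle_deg

    @property
    def top_width(self) -> float:
        """Opening width at the floor plane: w + 2 h tan(alpha)."""
        return self.width + 2.0 * self.height * math.tan(self.draft_angle_rad)

    @property
    def pitch(self) -> float:
        """Streamwise period: opening width plus partition gap."""
        return self.top_width + self.gap

    @property
    def patterned_extent(self) -> float:
        """Streamwise span from first leading edge to last trailing edge."""
        return self.n_trenches * self.top_width + (self.n_trenches - 1) * self.gap


def make_trench_design(
    kind: str,
    height: float,
    width: float,
    draft_angle_deg: float = 0.0,
    gap: float = 0.0,
    n_trenches: int = 3,
) -> TrenchDesign:
    """Validate and build a :class:`TrenchDesign`.

    Raises
    ------
    GeometryError
        On non-positive dimensions, a reentrant draft angle (alpha >= 90),
        or a zero-thickness fin (vertical trenches with d = 0 and n > 1).
    """
    if kind not in ("vertical", "trapezoidal"):
        raise GeometryError(f"kind must be 'vertical' or 'trapezoidal', got {kind!r}")
    if not height > 0:
        raise GeometryError(f"height must be > 0, got {height}")
    if not width > 0:
        raise GeometryError(f"width must be > 0, got {width}")
    if not 0.0 <= draft_angle_deg < 90.0:
        raise GeometryError(
            f"draft_angle must satisfy 0 <= alpha < 90 deg (reentrant otherwise), "
            f"got {draft_angle_deg}"
        )
    if kind == "vertical" and draft_angle_deg != 0.0:
        raise GeometryError("draft_angle must be 0 for kind='vertical'")
    if gap < 0:
        raise GeometryError(f"gap must be >= 0, got {gap}")
    if not (isinstance(n_trenches, int) and n_trenches >= 1):
        raise GeometryError(f"n_trenches must be an integer >= 1, got {n_trenches}")
    if kind == "vertical" and gap == 0.0 and n_trenches > 1:
        raise GeometryError(
            "gap=0 with vertical sidewalls and n_trenches>1 leaves a zero-thickness "
            "fin between trenches; use gap > 0 or a trapezoidal design"
        )
    return TrenchDesign(kind, height, width, draft_angle_deg, gap, n_trenches)


@dataclass(frozen=True)
class Segment:
    """One straight piece of the wetted floor boundary.

    ``normal`` is the unit normal pointing into the fluid; because the
    boundary is traversed inlet -> outlet with the fluid on the left, it is
    the +90 degree rotation of the traversal direction.
    """

    cls: str
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def length(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    @property
    def dx(self) -> float:
        """Streamwise extent |delta x| — the floor-plane projection weight."""
        return abs(self.x1 - self.x0)

    @property
    def normal(self) -> tuple[float, float]:
        dx, dy = self.x1 - self.x0, self.y1 - self.y0
        ln = math.hypot(dx, dy)
        return (-dy / ln, dx / ln)


@dataclass(frozen=True)
class WettedProfile:
    """Ordered polyline of the patterned floor boundary, inlet to outlet."""

    segments: tuple[Segment, ...]
    clear_height: float

    @property
    def total_extent(self) -> float:
        return self.segments[-1].x1 - self.segments[0].x0

    @property
    def patterned_x0(self) -> float:
        """x of the first trench leading edge (start of first non-flat seg)."""
        for s in self.segments:
            if s.cls not in ("entrance-flat", "exit-flat"):
                return s.x0
        return self.segments[0].x0

    @property
    def patterned_x1(self) -> float:
        for s in reversed(self.segments):
            if s.cls not in ("entrance-flat", "exit-flat"):
                return s.x1
        return self.segments[-1].x1

    def projected_length(self, classes: tuple[str, ...] | None = None) -> float:
        """Sum of |delta x| over segments, optionally filtered by class."""
        return sum(s.dx for s in self.segments if classes is None or s.cls in classes)

    def mirrored(self) -> "WettedProfile":
        """Profile reflected about the streamwise mid-plane (for symmetry checks)."""
        xm = 0.5 * (self.segments[0].x0 + self.segments[-1].x1)
        swap = {"sidewall-down": "sidewall-up", "sidewall-up": "sidewall-down",
                "entrance-flat": "exit-flat", "exit-flat": "entrance-flat"}
        segs = [
            Segment(swap.get(s.cls, s.cls), 2 * xm - s.x1, s.y1, 2 * xm - s.x0, s.y0)
            for s in reversed(self.segments)
        ]
        return WettedProfile(tuple(segs), self.clear_height)


def build_wetted_profile(design: TrenchDesign | None, channel: ChannelSpec) -> WettedProfile:
    """Trace the floor boundary of the patterned channel, inlet to outlet.

    ``design=None`` gives the flat control channel (a single flat segment,
    classed entrance-flat).
    """
    segs: list[Segment] = []
    x = 0.0
    if design is None:
        total = channel.entrance_length + channel.exit_length
        if total <= 0:
            total = 10.0 * channel.clear_height
        segs.append(Segment("entrance-flat", 0.0, 0.0, total, 0.0))
        return WettedProfile(tuple(segs), channel.clear_height)

    h, w = design.height, design.width
    run = h * math.tan(design.draft_angle_rad)  # horizontal run of each sidewall
    if channel.entrance_length > 0:
        segs.append(Segment("entrance-flat", x, 0.0, x + channel.entrance_length, 0.0))
        x += channel.entrance_length
    for t in range(design.n_trenches):
        segs.append(Segment("sidewall-down", x, 0.0, x + run, -h))
        x += run
        segs.append(Segment("trench-floor", x, -h, x + w, -h))
        x += w
        segs.append(Segment("sidewall-up", x, -h, x + run, 0.0))
        x += run
        if t < design.n_trenches - 1 and design.gap > 0:
            segs.append(Segment("partition-top", x, 0.0, x + design.gap, 0.0))
            x += design.gap
    if channel.exit_length > 0:
        segs.append(Segment("exit-flat", x, 0.0, x + channel.exit_length, 0.0))
    return WettedProfile(tuple(segs), channel.clear_height)
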