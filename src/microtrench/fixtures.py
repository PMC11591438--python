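"""Canned scenario presets.

Each fixture is a fully specified :class:`~microtrench.config.RunConfig` for
one of the canonical study scenarios:

* ``frendl-vertical`` — deep vertical trenches (700 um x 400 um, partitions
  100 um) under a 600 dyn/cm^2 bulk shear, the configuration that first
  demonstrated EC sheltering in pyrolytic carbon;
* ``pilot-theta60/90/120`` — trapezoidal pilot trio, fixed h = 150 um,
  w = 110 um, included opening angle theta = 2*alpha in {60, 90, 120} deg;
* ``poc-45deg-120dyn`` — the embossed 45-deg proof-of-concept channel at a
  120 dyn/cm^2 bulk shear (pilot h/w reused: the embossed channel's exact
  dimensions are not published);
* ``flat-control`` — un-patterned channel; coverage is decided entirely by
  whether the bulk WSS lies in the viability band.
"""

from __future__ import annotations

from .config import RunConfig
from .flow import FlowConditions
from .geometry import BLOOD, ChannelSpec, make_trench_design

__all__ = ["FIXTURE_NAMES", "make_fixture"]

_CLEAR = 0.508e-3


def _channel(trench_height: float) -> ChannelSpec:
    h_total = _CLEAR + trench_height
    return ChannelSpec(_CLEAR, entrance_length=max(1.5e-3, h_total),
                       exit_length=max(2.0e-3, 2.0 * h_total))


def _cfg(design, channel, bulk, deposition=None, region="patterned") -> RunConfig:
    return RunConfig(design=design, channel=channel, fluid=BLOOD,
                     flow=FlowConditions(target_bulk_wss=bulk),
                     deposition=deposition, region=region)


def _frendl() -> RunConfig:
    design = make_trench_design("vertical", 700e-6, 400e-6, 0.0, 100e-6, 3)
    dep = {"coating_map": {"sidewall-down": "collagen",
                           "trench-floor": "collagen",
                           "sidewall-up": "collagen"},
           "default_coating": "inert", "t_end": 3000.0, "n_steps": 40}
    return _cfg(design, _channel(design.height), 600.0, dep)


def _pilot(theta: float) -> RunConfig:
    design = make_trench_design("trapezoidal", 150e-6, 110e-6, theta / 2.0,
                                0.0, 3)
    return _cfg(design, _channel(design.height), 600.0)


FIXTURES = {
    "frendl-vertical": _frendl,
    "pilot-theta60": lambda: _pilot(60.0),
    "pilot-theta90": lambda: _pilot(90.0),
    "pilot-theta120": lambda: _pilot(120.0),
    "poc-45deg-120dyn": lambda: _cfg(
        make_trench_design("trapezoidal", 150e-6, 110e-6, 45.0, 0.0, 3),
        _channel(150e-6), 120.0),
    "flat-control": lambda: _cfg(None, ChannelSpec(_CLEAR, 1.5e-3, 2.0e-3),
                                 600.0, region="all"),
}

FIXTURE_NAMES = tuple(sorted(FIXTURES))


def make_fixture(name: str) -> RunConfig:
    """Build the named preset; raises KeyError listing the known fixtures."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(FIXTURE_NAMES)}") from None
    return factory()
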