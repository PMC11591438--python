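"""Collagen- vs endothelial-coated trenches under the same flow.

Runs the reduced activated-platelet transport model for 50 minutes of
physical time over the vertical-trench geometry twice — once with reactive
collagen trench interiors, once with a quiescent endothelial lining — and
compares the deposited platelet mass inside the trenches.
"""
import numpy as np

from microtrench import (assign_reactivity, generate_mesh, make_fixture,
                         simulate_deposition, solve_steady_flow)
from microtrench.deposition import deposited_mass_on_edges

cfg = make_fixture("frendl-vertical")
mesh = generate_mesh(cfg.design, cfg.channel, "sweep")
flow = solve_steady_flow(mesh, cfg.fluid, cfg.flow)

inside = ("sidewall-down", "trench-floor", "sidewall-up")
masses = {}
for coating in ("collagen", "endothelial"):
    ra = assign_reactivity(mesh, {c: coating for c in inside}, "inert")
    state = simulate_deposition(flow, ra, t_end=3000.0, n_steps=40)
    cls = np.array([mesh.profile.segments[i].cls
                    for i in mesh.wetted_edges[:, 2]])
    masses[coating] = deposited_mass_on_edges(state, flow,
                                              np.isin(cls, inside))
    print(f"{coating:12s}: {masses[coating]:.3e} platelets per unit depth "
          f"(budget closes to {state.conservation_error():.1e})")
print(f"contrast    : collagen/EC = {masses['collagen']/masses['endothelial']:.0f}x")
# An endothelialized trench accumulates orders of magnitude fewer platelets
# than a collagen-coated one — the motivation for sheltering EC in trenches.
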