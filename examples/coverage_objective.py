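"""Score a trapezoidal trench design by in-band projected coverage.

Builds the included-angle-90-degree pilot trench array (h = 150 um,
w = 110 um, 45-degree draft), solves the flow at 600 dyn/cm^2 bulk shear
and evaluates the fraction f of the projected patterned surface whose WSS
lies strictly inside the endothelial viability band 10-50 dyn/cm^2.
"""
from microtrench import (coverage_objective, generate_mesh, make_fixture,
                         solve_steady_flow, wall_shear_stress)

cfg = make_fixture("pilot-theta90")
mesh = generate_mesh(cfg.design, cfg.channel, "coarse")
flow = solve_steady_flow(mesh, cfg.fluid, cfg.flow)
cov = coverage_objective(wall_shear_stress(flow), cfg.thresholds)

print(f"projected length of patterned region: {cov.total_projected*1e3:.3f} mm")
print(f"in-band      : {cov.length_in*1e3:.3f} mm")
print(f"below 10     : {cov.length_below*1e3:.3f} mm")
print(f"above 50     : {cov.length_above*1e3:.3f} mm")
print(f"coverage f   : {cov.f:.3f}")
# f is the design objective: the share of floor-plane-projected surface an
# endothelial monolayer could occupy without seeing damaging shear.
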