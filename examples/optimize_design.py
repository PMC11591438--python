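"""Small bounded optimization of trench height, width and draft angle.

Runs the factorial-scan + Nelder-Mead search with a reduced evaluation
budget (each evaluation is a full CFD solve, so this still takes a couple
of minutes) and prints the best design found and its coverage.
"""
from microtrench import CoverageEvaluator, optimize_continuous

ev = CoverageEvaluator(resolution="sweep")
res = optimize_continuous(evaluator=ev, budget=35, seed=1)

print(f"evaluations : {res.n_evaluations}")
print(f"best f      : {res.best_f:.3f}")
print(f"best design : h = {res.best_height*1e3:.3f} mm, "
      f"w = {res.best_width*1e3:.3f} mm, "
      f"alpha = {res.best_draft_angle_deg:.1f} deg")
# The search tends toward micro-grooves at the lower size bound, whose
# floors sit naturally inside the 10-50 dyn/cm2 band at this bulk shear.
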