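"""The osmotic scaling law: which surface growth keeps the pressure constant?

The lumen pressure of a secreting spherical monolayer follows
Pi(t) ~ (integral of A) / A^(3/2).  Solving for the power law A(t) = t^p
that makes Pi time-constant gives p = 2: cell numbers growing slower than
t^2 (e.g. linearly) predict rupture-driven size oscillations, faster growth
(e.g. exponential) predicts none.
"""

from organoidyn import classify_growth, constant_pressure_exponent, make_growth_curve

p_star = constant_pressure_exponent()
print(f"constant-pressure exponent p* = {p_star:.4f}  (analytic value: 2)")

for mode, kwargs in (
    ("exponential", {"rate": 0.05}),
    ("linear", {"slope": 2.0}),
):
    curve, _ = make_growth_curve(mode=mode, n0=9.0, **kwargs)
    print(f"{mode:>11s} cell-count growth -> {classify_growth(curve)}")
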