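"""Closed-form chelal geometry and lever-force proxies for one specimen.

Builds a plausible set of chelal measurements for a mid-sized astigmatan
mite and prints the derived mechanical quantities.
"""

from chelamorph import (
    ChelalMeasures,
    classify_lever,
    curvature_b,
    force_estimates,
    tip_diameter,
    velocity_ratio,
)

m = ChelalMeasures(
    L1U=85.0, L2M=170.0,      # lever arms, µm: VR = 0.5
    CHI=150.0, CLI=370.0,     # cheliceral height and reach, µm
    W=25.0,                   # digit depth at end of tooth row, µm
    kerf=4.0, thick=6.0,      # sawn-groove width and digit thickness, µm
    alpha=95.0,               # lever design angle, degrees
    tip_angle=52.0, distal_angle=100.0,
    x_ie=90.0, e_index=10,
)

vr = velocity_ratio(m)
f = force_estimates(m)
d_tip = tip_diameter(m.tip_angle)  # at delta = 1 µm behind the point
b = curvature_b(m.W, d_tip)

print(f"velocity ratio VR = L1U/L2M          : {vr:.3f}")
print(f"input forces  F1P (pennate), F1C     : {f.F1P:.0f}, {f.F1C:.0f} (arb.)")
print(f"output force  F2AV = VR * F1AV       : {f.F2AV:.0f} (arb.)")
print(f"tip diameter 2*tan(tip_angle/2)      : {d_tip:.3f} µm at δ=1")
print(f"ventral curvature b = W/(W - d_tip)  : {b:.3f}")
print(f"lever class at α = {m.alpha}°          : {classify_lever(m.alpha)}")
print()
print("VR < 1 trades speed for force (a crushing chela); b near 1 means a")
print("nearly straight venter, larger b a more strongly curved one.")
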