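"""How the shadow slope depends on the assumed attenuation-curve shape.

The Gaussian fixtures anchor peak heights at the measured coefficients, but
peak widths are a modelling choice.  The survival-vs-depth slope depends on
the *off-peak* attenuation across the 300-400 nm band, so this script
sweeps the Gaussian width and reports the fitted slope for an optically
thick start (0.1 M, 1 m lake) and the optically thin case (0.1 mM, 5 m).
"""

import cyanoshade as cs
from cyanoshade import synthetic

print("width (nm)   0.1 M slope (d/m, 1 m lake)   0.1 mM slope (d/m, 5 m lake)")
for width in (30.0, 45.0, 60.0):
    curves = (
        synthetic.ferrocyanide_curve(width=width),
        synthetic.nitroprusside_curve(width=width),
    )
    thick = cs.run(cs.LakeConfig(depth=1.0), curves=curves).shadow_slope().slope
    thin = cs.run(
        cs.LakeConfig(depth=5.0, initial_ferrocyanide=1e-4), curves=curves
    ).shadow_slope().slope
    print(f"{width:8.0f}   {thick:18.1f}   {thin:25.3f}")

# the optically thick slope moves only logarithmically with the band optical
# depth, while the optically thin slope is directly proportional to how much
# of the band the curve actually covers - hence far more shape-sensitive.
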