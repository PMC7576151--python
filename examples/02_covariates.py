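"""Engineer raster habitat covariates and screen them for collinearity.

Distance to natural vegetation, moving-window densities (0.5 and 1.5 km
radii), terrain ruggedness (TRI), patch contiguity — then the pairwise
Pearson screen that decides which variables may share a model.
"""

import habmosaic as hm
import habmosaic.synth as synth

scape = synth.make_landscape(synth.SimConfig(nrows=80, ncols=80, seed=7))
stack = hm.build_stack(scape)
flagged = hm.correlation_screen(stack, threshold=0.7)

print("covariates:", ", ".join(stack.names))
for name in ("dist_natural", "wetland_density", "tri", "natural_contiguity"):
    v = stack.rasters[name].values
    print(f"{name:20s} min={v.min():8.3f} max={v.max():8.3f}")
print("\nflagged |r| >= 0.7 pairs (kept out of the same model):")
for a, b, r in flagged:
    print(f"  {a} ~ {b}: r = {r:.2f}")
# A high |r| pair would enter the step-wise selection, which keeps the
# member with the larger percent contribution.
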