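"""Cross-validate, evaluate with five accuracy measures, build a consensus.

Ten-fold cross-validation of the Maxent model, per-fold AUC / Boyce / TSS /
sensitivity / specificity against the fold's own background sample, then
the consensus: average the continuous surfaces and binarize at the mean of
the per-fold max-sensitivity+specificity thresholds.
"""

import numpy as np

import habmosaic as hm
import habmosaic.synth as synth

cfg = synth.SimConfig(nrows=80, ncols=80, n_animals=12, seed=7)
scape = synth.make_landscape(cfg)
fixes = synth.simulate_telemetry(scape, cfg)
kept, _ = hm.screen_fixes(fixes)
kept = hm.subsample_all(kept, 5)
xy = np.array([[f.x, f.y] for f in kept])

stack = hm.build_stack(scape)
hm.correlation_screen(stack)
variables = ["forage", "cover", "human_pressure", "wetland_density"]

folds = hm.cross_validate(xy, stack, k=5, seed=3, n_background=3000,
                          variables=variables)
surfaces, thresholds = [], []
print("fold   AUC  Boyce   TSS  sens  spec  threshold")
for i, fold in enumerate(folds):
    surface = hm.predict_maxent(fold.model, stack.subset(variables))
    rep = hm.evaluate_fold(surface, fold.test_presence_xy,
                           fold.background_xy[:1000], fold=i)
    print(f"{i:3d}  {rep.auc:.3f}  {rep.boyce:.2f}  {rep.tss:.2f} "
          f"{rep.sensitivity:.2f}  {rep.specificity:.2f}  {rep.threshold:.3f}")
    surfaces.append(surface)
    thresholds.append(rep.threshold)

consensus = hm.consensus_output(surfaces, thresholds, scale="state")
area = hm.area_km2(consensus.binary)
print(f"\nconsensus threshold (mean of folds): {consensus.threshold:.3f}")
print(f"habitat identified: {area:.1f} km^2 "
      f"({100 * area / (consensus.binary.values.size * consensus.binary.cell_area_km2()):.0f}% of extent)")
# TSS = sensitivity + specificity - 1; values near 1 mean the binary map
# separates presences from background almost perfectly.
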