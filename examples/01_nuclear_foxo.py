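"""Nuclear FOXO quantification on a synthetic two-channel fat-body stack.

Builds two scenes differing only in nuclear FOXO level (a normal-food
group and a high-sugar-diet group with 1.5x nuclear signal), segments
nuclei from the lamin rims, reconstructs 3D masks, measures mean FOXO
voxel intensity per nucleus, and compares the groups with a two-sided
Wilcoxon rank-sum test — nuclei, not flies, are the statistical unit.
"""

import numpy as np

from flyquant import foxo, synth

groups = {}
for diet, foxo_level, seed in (("NF", 110.0, 1), ("HSD", 165.0, 2)):
    spec = synth.NucleiSceneSpec(n_nuclei=10, nuclear_foxo=foxo_level, seed=seed)
    lamin, foxo_stack, truth = synth.generate_nuclei_stack(spec)
    labels, _, t = foxo.segment_nuclei_2d(lamin)
    masks = foxo.reconstruct_nuclei_3d(lamin, labels, threshold=t)
    meas = foxo.measure_nuclear_intensity(foxo_stack, masks)
    groups[diet] = meas
    print(f"{diet}: {len(meas)} nuclei segmented (threshold {t:.0f} a.u., "
          f"true level {foxo_level:.0f})")
    print(f"    mean nuclear FOXO {np.mean([m.mean_intensity for m in meas]):.1f} a.u., "
          f"mean volume {np.mean([m.volume_um3 for m in meas]):.1f} um^3")

res = foxo.compare_nuclear_foxo(groups["HSD"], groups["NF"])
print(f"Wilcoxon rank-sum (HSD vs NF): W = {res.statistic:.0f}, "
      f"p = {res.p_value:.2e}")
print("A small p means nuclear FOXO accumulation differs between diets —")
print("the readout used as a proxy for reduced insulin signalling.")
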