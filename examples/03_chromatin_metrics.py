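"""DNA density and coefficient of variation as compaction readouts.

On a simulated nucleus, damage foci seeded in heterochromatin read out a
higher DNA density than foci in euchromatin, and the in-ROI CV drops as
chromatin relaxes.
"""

import numpy as np

from chromodyn import (
    control_kinetics,
    dna_density,
    edge_roi,
    roi_stats,
    synth_nucleus,
    synth_timelapse,
)

nucleus = synth_nucleus(shape=(192, 192), n_blobs=60, seed=0)
frame = nucleus.chromatin_density_map  # noiseless counterstain rates

het = nucleus.heterochromatin_mask
eu = nucleus.nucleus_mask & ~het
d_het = dna_density(frame, nucleus.nucleus_mask, het)
d_eu = dna_density(frame, nucleus.nucleus_mask, eu)
print(f"DNA density at heterochromatin foci: {d_het:.3f}")
print(f"DNA density at euchromatin foci:     {d_eu:.3f}")
print("Higher density = damage sitting in more compact chromatin.\n")

roi = edge_roi(nucleus)
sim = synth_timelapse(nucleus, control_kinetics(), roi, seed=0)
region = roi.mask(nucleus.nucleus_mask.shape) & nucleus.nucleus_mask
dna = sim.stack.channel("dna")
for label, i in [("first post-bleach", 5), ("last frame", 54)]:
    mu, sigma, cv = roi_stats(dna[i], region)
    print(f"{label:>18} (t={sim.stack.time_s[i]:6.1f} s): "
          f"ROI mean = {mu:5.2f}, sd = {sigma:5.2f}, CV = {cv:.3f}")
print("Falling mean and CV signal chromatin relaxation inside the "
      "irradiated region.")
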