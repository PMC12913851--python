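"""Simulate a ground-truthed micro-irradiation time-lapse.

Builds a textured nucleus, places an irradiation ROI at its edge, and
generates a two-channel photon-count movie: a damage marker recruiting to
foci and a DNA counterstain relaxing inside the ROI.
"""

import numpy as np

from chromodyn import (
    AcquisitionSchedule,
    control_kinetics,
    edge_roi,
    make_schedule,
    synth_nucleus,
    synth_timelapse,
)

schedule = AcquisitionSchedule()  # 5 pre @ 1.3 s, 2 bleach @ 1.3 s, 50 post @ 3 s
time_s = make_schedule(schedule)
print(f"{len(time_s)} frames; first post-bleach at t = {time_s[5]:.1f} s, "
      f"last at t = {time_s[-1]:.1f} s (t = 0 is bleach onset)")

nucleus = synth_nucleus(shape=(192, 192), n_blobs=60, seed=0)
roi = edge_roi(nucleus)
sim = synth_timelapse(nucleus, control_kinetics(), roi, schedule=schedule, seed=0)

region = roi.mask(nucleus.nucleus_mask.shape) & nucleus.nucleus_mask
dna = sim.stack.channel("dna")
dmg = sim.stack.channel("damage")
print(f"ROI {roi.width}x{roi.height} px intersects the nucleus in {region.sum()} px")
print(f"{len(sim.foci_yx)} damage foci; "
      f"{np.mean([nucleus.heterochromatin_mask[y, x] for y, x in sim.foci_yx]):.0%} "
      "seeded in heterochromatin (damage_bias=0.9)")
for label, i in [("last pre-bleach", 4), ("first post-bleach", 5), ("last frame", 54)]:
    print(f"  {label:>18} (t={sim.stack.time_s[i]:6.1f} s): "
          f"ROI counterstain mean {dna[i][region].mean():5.2f} counts, "
          f"damage mean {dmg[i][region].mean():5.2f} counts")
print("The counterstain mean falls after the bleach (chromatin relaxation) "
      "while the damage channel rises (marker recruitment).")
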