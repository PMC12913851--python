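"""Full pipeline on both experimental conditions.

Simulates a control cell (fast recruitment, full chromatin relaxation)
and a PARP-inhibited cell (slow recruitment, trapped marker, suppressed
relaxation), runs segmentation -> ICCS -> density/CV -> kinetics on each,
and contrasts the per-frame metrics and fitted constants.
"""

import numpy as np

from chromodyn import run_demo

for condition in ("control", "parp_inhibited"):
    report, comparison = run_demo(seed=3, condition=condition, shape=(160, 160))
    m = report.metrics
    post = m[m.time_s > 0]
    early = post.head(5)
    late = post.tail(5)
    print(f"--- {condition} ---")
    print(f"  f1 (coloc. with heterochromatin): "
          f"{np.nanmean(early.f1):+.2f} early -> {np.nanmean(late.f1):+.2f} late")
    print(f"  DNA density at foci:              "
          f"{np.nanmean(early.dna_density):.2f} early -> {np.nanmean(late.dna_density):.2f} late")
    print(f"  normalized counterstain mean:     "
          f"{np.nanmean(early.dna_mean_norm):.2f} early -> {np.nanmean(late.dna_mean_norm):.2f} late")
    print(f"  normalized CV:                    "
          f"{np.nanmean(early.cv_norm):.2f} early -> {np.nanmean(late.cv_norm):.2f} late")
    for row in comparison.itertuples():
        fitted = f"{row.fitted_s:.1f} s" if row.fit_success else "no decay (flat trace)"
        print(f"  {row.parameter:>16}: true {row.true_s:5.1f} s, fitted {fitted}")
    print()

print("Control metrics fall over time (relaxation, marker redistribution); "
      "inhibited metrics stay flat and recruitment is slower — the "
      "flat-trace decay fits correctly refuse to report a constant.")
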