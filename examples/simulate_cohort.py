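"""Generate a small synthetic carotid cohort and inspect its ground truth.

Each subject is a carotid bifurcation (CCA splitting into ICA and ECA)
with a known wall model WT = b0 + b1*WSS + b2*D + b3*WSS*D + noise.
"""

import numpy as np

from wallmap import CohortConfig, generate_cohort

config = CohortConfig(n_subjects=4, seed=7)
subjects = generate_cohort(config, with_velocity=False)

print(f"generated {len(subjects)} subjects, beta_true = {config.beta_true}")
for s in subjects:
    wt = s.truth_maps["wt"].values
    wss = s.truth_maps["wss"].values
    d = s.truth_maps["diameter"].values
    print(
        f"{s.subject_id}: {s.lumen.n_vertices} vertices | "
        f"WT {wt.min():.2f}-{wt.max():.2f} mm | "
        f"WSS {wss.min():.2f}-{wss.max():.2f} Pa | "
        f"D {np.median(d):.2f} mm (median)"
    )

# The printed ranges are per-vertex ground truth: wall thickness in mm,
# wall shear stress in Pa (higher in the narrower, faster daughter
# branches), and the local vessel diameter in mm.
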