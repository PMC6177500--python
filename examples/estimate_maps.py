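"""Estimate the three per-vertex maps for one synthetic subject and
compare them with the generator's ground truth.

Wall thickness comes from lumen-to-outer-wall surface distance, the
diameter map from the lumen centerline, and wall shear stress from the
velocity volume via wall-normal smoothing-spline gradients.
"""

import numpy as np

from wallmap import (
    CohortConfig,
    compute_centerline,
    compute_diameter_map,
    compute_wall_thickness,
    compute_wss_map,
    generate_cohort,
)

subject = generate_cohort(CohortConfig(n_subjects=2, seed=3), with_velocity=True)[0]

wt = compute_wall_thickness(subject.lumen, subject.outer_wall)
centerline = compute_centerline(subject.lumen)
dmap = compute_diameter_map(subject.lumen, centerline)
wss = compute_wss_map(subject.lumen, subject.velocity, dmap)


def report(name, est, truth, unit):
    ok = np.isfinite(est)
    err = np.abs(est[ok] - truth[ok])
    print(
        f"{name}: median estimate {np.median(est[ok]):.3f} {unit}, "
        f"median |error| vs truth {np.median(err):.3f} {unit} "
        f"({ok.sum()}/{len(est)} vertices estimated)"
    )


report("WT ", wt.values, subject.truth_maps["wt"].values, "mm")
report("D  ", dmap.values, subject.truth_maps["diameter"].values, "mm")
report("WSS", wss.values, subject.truth_maps["wss"].values, "Pa")

# Median errors are a fraction of the mesh resolution (WT, D) and a few
# percent of the Poiseuille closed form (WSS); vertices on the artificial
# inlet/outlet caps are excluded from the WSS map.
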