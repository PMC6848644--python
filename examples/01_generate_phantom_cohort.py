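"""Generate a synthetic midbrain cohort and inspect the planted disease effect.

Builds 10 healthy-control and 10 Parkinson phantoms (0.43 mm pixels, midbrain
on two consecutive slices, two SNpc crescents) and prints the planted
hyperintense SNpc area per group.  The PD effect is a reduced hyperintense
extent, so the PD group mean should be clearly below the HC mean.
"""

import numpy as np

from nigraseg import PhantomParams, generate_cohort

params = PhantomParams(seed=1)
manifest, subjects = generate_cohort(params, n_hc=10, n_pd=10)

px_area = params.pixel_spacing[0] * params.pixel_spacing[1]
areas = {"HC": [], "PD": []}
for s in subjects:
    areas[s.record.group].append(s.n_hyper_pixels * px_area)

print(f"cohort: {manifest.group_counts()}")
for group in ("HC", "PD"):
    a = np.asarray(areas[group])
    print(f"{group}: planted hyperintense area {a.mean():5.1f} +/- {a.std(ddof=1):4.1f} mm^2")
print(
    "\nThe planted areas are the ground truth the threshold statistic should\n"
    "recover; the PD mean is lower because fewer SNpc pixels are rendered\n"
    "hyperintense (extent 0.55 vs 0.95)."
)
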