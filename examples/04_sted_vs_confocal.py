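"""Compare event detection at STED-like vs confocal-like resolution.

The same ground-truth vesicles are rendered twice: with a wide PSF
(sigma = 2.5 px, confocal-like) and a narrow one (sigma = 0.6 px,
STED-like). Suprathreshold 26-connected components are counted as events;
narrow-PSF rendering resolves merged blobs into individual vesicles.
"""

from dataclasses import replace

import numpy as np

import vesidist as vd

conf_spec = vd.SyntheticCellSpec(
    spatial_model="bimodal", membrane_weight=0.5, psf_sigma=2.5, seed=17
)
sted_spec = replace(conf_spec, psf_sigma=0.6)

conf, truth = vd.generate_cell(conf_spec)
sted, _ = vd.generate_cell(sted_spec)

theta_c = vd.fit_background(conf, n_sigma=10).theta
theta_s = vd.fit_background(sted, n_sigma=10).theta
n_conf = vd.count_events(conf, theta_c)
n_sted = vd.count_events(sted, theta_s)

print(f"ground-truth vesicles: {len(truth)}")
print(f"confocal-like rendering (psf 2.5 px): {n_conf} detected events")
print(f"STED-like rendering     (psf 0.6 px): {n_sted} detected events")
print()
print("Wide-PSF blur merges nearby vesicles into single blobs; the narrow PSF")
print("recovers counts much closer to the ground truth. Per-event integrated")
print("intensities are available via intensity_distribution(per_event=True).")

hist = vd.intensity_distribution(sted, theta_s, per_event=True)
print(f"STED-like per-event integrated excess: median = {float(np.median(hist.values)):.0f} counts")
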