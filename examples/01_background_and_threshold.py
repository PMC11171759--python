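"""Fit the Gaussian camera background of a stack and derive the threshold.

Generates one synthetic cell (EEA1-like puncta over Gaussian detector
background), estimates the background (mu, sigma) from the intensity
histogram mode and left tail, and prints the binarization threshold
theta = mu + n_sigma * sigma at the confocal default n_sigma = 10.
"""

import vesidist as vd

stack, _ = vd.generate_cell(vd.SyntheticCellSpec(seed=1))
model = vd.fit_background(stack, n_sigma=10)

print(f"simulated background:  mu = 1861.63, sigma = 147.70")
print(f"estimated background:  mu = {model.mu:.2f}, sigma = {model.sigma:.2f}")
print(f"threshold theta = mu + 10 sigma = {model.theta:.2f}")
print(f"fraction of pixels <= theta: {model.background_fraction:.1%}")
print()
print("The estimator reads the histogram peak (mode) for mu and the spread of")
print("the left tail for sigma, so the bright vesicle signal in the right tail")
print("does not bias either; ~99% of pixels are background at this threshold.")
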