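"""Simulate one fluorescence acquisition and flat-field it.

Builds a control-group scene (leaf blob, white PTFE panel, dark frame) on the
25-band 603-870 nm grid, applies (raw - dark) / (white - dark), and checks
the leaf mask recovered by Otsu thresholding against the generator's truth.
"""

import numpy as np

from fluocube import SimConfig, flat_field, generate_scene, make_mask

cfg = SimConfig(seed=1)
scene = generate_scene("Cg", cfg, seed=1)
cal = flat_field(scene.raw, scene.white, scene.dark)
mask = make_mask(cal, band_wl=673.0, method="otsu")

agree = (mask.values == scene.mask_truth.values).mean()
leaf = cal.data[mask.values]
print(f"scene {scene.scene_id}: {scene.raw.shape[0]}x{scene.raw.shape[1]} pixels, "
      f"{scene.raw.n_bands} bands")
print(f"mask: {mask.n_true} leaf pixels (threshold {mask.source['threshold']:.3f} "
      f"on the {mask.source['band_wl_used']:g} nm band), "
      f"{100 * agree:.1f}% agreement with ground truth")
print(f"calibrated leaf intensity: mean {leaf.mean():.3f}, max {leaf.max():.3f}")
print("Calibrated values are dimensionless reflectance-like intensities in ~[0, 1];")
print("the peak band sits near 673 nm where chlorophyll fluorescence is strongest.")
peak_band = int(np.argmax(leaf.mean(axis=0)))
print(f"brightest band: {cal.wavelengths[peak_band]:g} nm")
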