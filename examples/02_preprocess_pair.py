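"""Preprocess one RGB-D pair into model inputs.

Depth is clamped at 380 mm (everything farther is non-plant scene),
normalized to [0, 1], and jet-encoded to three channels so a
color-convolutional branch can consume it: blue = near, red = far,
missing pixels stay deep blue.  Both modalities are center cropped.
"""

import numpy as np

import canopymass as cm

rng = np.random.default_rng(1)
scene, center_id = cm.scene.make_neighborhood_scene(
    rng, center_mass_g=8.0, image_size=(96, 72), mm_per_pixel=4.25
)
sample = cm.render_scene(scene, center_id, rng)
pair = cm.preprocess_pair(sample, crop_size=64)

print("raw depth range:", sample.depth.min(), "-", sample.depth.max(), "(0.1 mm units)")
print("model inputs:", pair.rgb_norm.shape, pair.depth_jet.shape, pair.rgb_norm.dtype)
for v, label in [(0.0, "near/missing"), (0.5, "mid"), (1.0, "far/background")]:
    r, g, b = cm.jet_encode(np.array([v]))[0]
    print(f"jet({v:.1f}) = ({r:.2f}, {g:.2f}, {b:.2f})  <- {label}")

# train-time augmentation: one shared rotation; color jitter on RGB only
aug = cm.augment_pair(pair, np.random.default_rng(2))
print("augmented shapes unchanged:", aug.rgb_norm.shape, aug.depth_jet.shape)
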