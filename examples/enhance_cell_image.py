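"""Tune the neighborhood contrast stretch on a low-contrast cell image.

Builds a synthetic 64x64 blood-smear-like canvas with its intensity range
compressed to 20%, then lets differential evolution pick the transform
parameters (alpha, beta, gamma, delta) that maximize the edge/entropy
objective F on the intensity channel.
"""

import numpy as np

from hemopipe import (
    CellImageSpec,
    EnhancementConfig,
    enhance_rgb,
    enhancement_objective,
    make_cell_image,
    rgb_to_hsi,
)

image = make_cell_image(CellImageSpec(size=(64, 64), contrast=0.2, seed=7))
_, _, intensity = rgb_to_hsi(image)
before = enhancement_objective(intensity)

cfg = EnhancementConfig(window=3, pop_size=30, iterations=50)
enhanced, params, history = enhance_rgb(image, cfg, seed=7)
_, _, enhanced_i = rgb_to_hsi(enhanced)
after = enhancement_objective(enhanced_i)

print(f"input image objective      F = {before.objective:.3f} "
      f"(G={before.gradient_sum:.1f}, n_e={before.edge_count}, H={before.entropy:.2f})")
print(f"enhanced image objective   F = {after.objective:.3f} "
      f"(G={after.gradient_sum:.1f}, n_e={after.edge_count}, H={after.entropy:.2f})")
print(f"tuned parameters: alpha={params.alpha:.3f} beta={params.beta:.3f} "
      f"gamma={params.gamma:.3f} delta={params.delta:.3f}")
print(f"DE best-F trajectory: {history[0]:.3f} -> {history[-1]:.3f} over {len(history) - 1} iterations")
print(f"intensity range stretched from {np.ptp(intensity):.2f} to {np.ptp(enhanced_i):.2f}")
# A higher F means more edge pixels, stronger gradients and a richer intensity
# histogram - i.e. cell boundaries that were nearly invisible now stand out.
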