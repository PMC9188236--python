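"""Compute LPQ descriptors and see what they respond to.

The descriptor histograms local 8-bit phase codes; it ignores absolute
intensity (positive affine invariance) but reacts strongly to texture
orientation and scale — exactly the cues that differ between wood species
in micrographs.
"""

import numpy as np

from woodid.lpq import LPQConfig, lpq_descriptor

yy, xx = np.mgrid[0:128, 0:128].astype(float)
horizontal = 0.5 + 0.4 * np.sin(2 * np.pi * 0.1 * xx)
vertical = 0.5 + 0.4 * np.sin(2 * np.pi * 0.1 * yy)
brighter = 0.25 + 0.5 * horizontal          # same texture, different exposure

cfg = LPQConfig(window_size=7)
d_h = lpq_descriptor(horizontal, cfg)
d_v = lpq_descriptor(vertical, cfg)
d_b = lpq_descriptor(brighter, cfg)

print(f"histogram length: {len(d_h)}, sums to {d_h.sum():.6f}")
print(f"L1 distance horizontal vs vertical grating: {np.abs(d_h - d_v).sum():.3f}")
print(f"L1 distance same texture, exposure changed: {np.abs(d_h - d_b).sum():.3f}")

# Expected: the orientation change moves the histograms far apart (L1 well
# above 0.5) while the exposure change leaves the descriptor exactly
# unchanged (L1 = 0.000) — the property that makes LPQ robust to slide
# digitisation differences.
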