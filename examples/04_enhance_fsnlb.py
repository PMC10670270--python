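"""Derive optimized display parameters and apply window leveling and FSNLB.

The display window and blending band are parameterized from a measured
infarct attenuation distribution (mean 29.6 HU, SD 3.1 HU): level/centre =
rounded mean, width/delta = rounded 2 x SD.
"""

import numpy as np

from rssi_nwu import PhantomSpec, generate_phantom
from rssi_nwu.enhance import FSNLBParams, apply_window, derive_window_params, fsnlb
from rssi_nwu.images import VolumeImage

half = 3.1 / np.sqrt(2.0)
window = derive_window_params([29.6 - half, 29.6 + half])
print(f"optimized window level/width: {window.level:.0f}/{window.width:.0f} HU")

bundle = generate_phantom(PhantomSpec(seed=3))
les = bundle.truth_lesion_mask_ct.boolean()
con = bundle.truth_contralateral_mask_ct.boolean()

display = apply_window(bundle.ct, window)
print(f"windowed display: lesion mean {display.data[les].mean():.2f}, "
      f"contralateral mean {display.data[con].mean():.2f} (0 = black, 1 = white)")
# The narrow derived window spreads the 29.6-vs-33.3 HU contrast over almost
# the full grayscale - that is the visually dominant effect.

params = FSNLBParams(center=window.level, delta=window.width, slope=5.0)
identity = fsnlb(bundle.ct, FSNLBParams(slope=0.0))
print(f"FSNLB slope 0 leaves the volume bit-identical: "
      f"{np.array_equal(identity.data, bundle.ct.data)}")

# FSNLB's mechanism is in-band low-frequency contrast amplification: two
# plateaus one HU either side of the band centre gain ~1.8x contrast.
slab = np.full((40, 16, 16), params.center - 1.0)
slab[20:] = params.center + 1.0
out = fsnlb(VolumeImage(slab, np.eye(4), "CT"), params)
print(f"plateau pair at centre +/- 1 HU: contrast 2.00 -> "
      f"{out.data[35, 8, 8] - out.data[5, 8, 8]:.2f} HU")

# At a 0.35 cm^3 lesion the low-pass mixes lesion and surrounding tissue, so
# the mask-mean lesion/contralateral difference is NOT amplified - display
# windowing, not blending, carries the improvement for lesions this small.
enhanced = fsnlb(bundle.ct, params)
d_in = bundle.ct.data[con].mean() - bundle.ct.data[les].mean()
d_out = enhanced.data[con].mean() - enhanced.data[les].mean()
print(f"mask-mean lesion/contralateral difference at 0.35 cm^3: "
      f"{d_in:.2f} -> {d_out:.2f} HU (partial-volume limited)")
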