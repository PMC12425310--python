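"""NDVI, MSAVI and EVI from reflectance grids.

Uses a miniature 2x2 reflectance scene: a vegetated cell, bare soil,
water, and one cloud-masked (nodata) cell, and prints the three indices.
"""

import numpy as np

from agbkrige import evi, msavi, ndvi

#                 vegetated  soil     water   masked
nir = np.array([[0.45, 0.25], [0.05, np.nan]])
red = np.array([[0.08, 0.20], [0.04, 0.10]])
blue = np.array([[0.03, 0.08], [0.06, 0.05]])

print("NDVI:\n", np.round(ndvi(nir, red), 3))
print("MSAVI:\n", np.round(msavi(nir, red), 3))
print("EVI:\n", np.round(evi(nir, red, blue), 3))

# Dense vegetation scores high (NDVI ~0.7), soil near 0.1, water slightly
# negative-to-low; the nodata NIR cell propagates NaN through all three
# indices instead of producing infinities.
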