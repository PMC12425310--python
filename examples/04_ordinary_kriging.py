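"""Ordinary kriging of scattered residuals.

Five residual values are interpolated to a few target locations; the
printed weights show the OK hallmarks: they sum to one, concentrate on
nearby points, and collapse to the datum at a data location when the
nugget is zero.
"""

import numpy as np
import pandas as pd

from agbkrige import VariogramModel, krige_points

points = pd.DataFrame({
    "x": [2.0, 8.0, 5.0, 1.0, 9.0],
    "y": [2.0, 2.0, 8.0, 9.0, 9.0],
    "residual": [4.0, -2.0, 1.5, 0.5, -3.0],   # Mg/ha
})
vgm = VariogramModel("spherical", nugget=0.0, partial_sill=4.0, range_=8.0)

targets = np.array([[5.0, 5.0],    # center of the cloud
                    [2.0, 2.0],    # exactly on a datum
                    [50.0, 50.0]])  # far outside the data

preds, variances, weights = krige_points(points, vgm, targets,
                                         return_weights=True)
for t, p, v, w in zip(targets, preds, variances, weights):
    print(f"target {t}: prediction {p:6.2f} Mg/ha, "
          f"kriging variance {v:5.2f}, weight sum {w.sum():.6f}")
    print("  weights:", np.round(w, 3))

# At the datum the prediction reproduces 4.0 exactly with zero variance
# (zero nugget -> exact interpolation). Far from all data the weights
# even out and the variance approaches the total sill.
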