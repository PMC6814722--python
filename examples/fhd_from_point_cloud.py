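"""Compute a foliage-height-diversity grid from a simulated lidar cloud.

Simulates a classified point cloud over a strip of cells spanning SCI
classes 2, 8, and 14, normalizes vegetation returns to height above
ground (k-nearest-neighbor inverse-distance-squared interpolation of the
ground returns), filters noise above 70 m, and computes per-cell Shannon
FHD on 1 m vertical bins. Measured FHD is compared with the profile
model's closed-form binned entropy.
"""

import numpy as np

from forestintegrity import (
    CanopyProfileModel, GridSpec, RasterLayer,
    generate_point_cloud, normalize_heights, filter_points, compute_fhd,
    expected_fhd,
)
from forestintegrity.grids import NODATA_BYTE

classes = [2, 8, 14]
spec = GridSpec(500_000, 8_000_000, 30.0, len(classes), 4, crs_id=32722)
vals = np.repeat(np.asarray(classes, dtype=np.uint8)[:, None], 4, axis=1)
truth = RasterLayer(spec, vals, NODATA_BYTE, "sci")

model = CanopyProfileModel(saturate=True)
cloud = generate_point_cloud(truth, model, seed=3)
print(f"simulated {len(cloud):,} returns "
      f"({int(cloud.ground.sum()):,} ground, {int(cloud.vegetation.sum()):,} vegetation)")

normalized = filter_points(normalize_heights(cloud, k=6))
grid = compute_fhd(normalized, spec, density_min=10.0)
print(f"valid cells (density >= 10 pts/m^2): {int(grid.valid.sum())}/{grid.valid.size}")

print("class  mean measured FHD   closed-form FHD")
for i, k in enumerate(classes):
    measured = grid.fhd.values[i][grid.valid[i]].mean()
    print(f"  {k:2d}        {measured:.3f}             {expected_fhd(model, k):.3f}")
print("FHD is the Shannon entropy of the 1 m vertical return profile; it "
      "rises with structural complexity.")
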