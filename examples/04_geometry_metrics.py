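"""Ensemble geometry metrics: overlaps, sphericity, calibration.

Shows the projected circle-overlap machinery on planted point clouds, the
convex-hull sphericity, and how model medians in sigma units are calibrated
against experimental medians in nm (the published locus calibration is
44 nm per sigma).
"""
import numpy as np

from laminafold.metrics import (calibrate_length, circle_intersection_area,
                                map_correlation, projected_overlap,
                                sphericity, three_body_overlap)
from laminafold import synth

rng = np.random.default_rng(0)

# two gaussian blobs, partially overlapping in projection
a = rng.normal(size=(400, 3))
b = rng.normal(size=(400, 3)) + [1.5, 0.5, 0.0]
print(f"projected overlap (z axis) : {projected_overlap(a, b):.3f}")
print(f"three-body overlap         : "
      f"{three_body_overlap(a, b, b + [0, 2.0, 0]):.3f}")

# the printed two-circle intersection case R1=R2=1, d=1
a12 = circle_intersection_area(1.0, 1.0, 1.0)
print(f"lens area R1=R2=1, d=1     : {a12:.4f} "
      f"(overlap {a12 / (2 * np.pi - a12):.4f})")

cube = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                dtype=float)
print(f"cube sphericity            : {sphericity(cube):.4f} "
      f"(closed form {(np.pi / 6) ** (1 / 3):.4f})")

print(f"length calibration         : "
      f"{calibrate_length([2.0, 4.0], [88.0, 176.0]):.1f} nm/sigma")

# model-vs-experiment map comparison on a synthetic pair
m = synth.make_block_contact_map(60, [20, 40])
noisy = np.abs(m * (1 + 0.1 * rng.normal(size=m.shape)))
r, rp = map_correlation(m, 0.5 * (noisy + noisy.T))
print(f"map Pearson r / distance-corrected r': {r:.3f} / {rp:.3f}")
# r compares raw contact frequencies above 100 kb separation; r' first
# removes the mean distance decay from both maps, which is the harder test.
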