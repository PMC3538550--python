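"""Level-of-detail classification and base-pair picking on a long strand.

The bounding-sphere hierarchy over the base-pair anchors answers two
interactive queries without scanning every pair: which display model
(atomic / ribbon / line) each part of the strand deserves at a given
viewer distance, and which base pair a mouse ray hits.
"""

import numpy as np

from dnaxis import (build_dna, build_hierarchy, classify_lod,
                    interpolate_points, pick_base_pair)

# a 3,400-bp wiggly strand
rng = np.random.default_rng(3)
steps = rng.normal(size=(40, 3))
for i in range(1, len(steps)):
    steps[i] = steps[i - 1] + 0.4 * steps[i]
    steps[i] /= np.linalg.norm(steps[i])
beads = np.vstack([[0, 0, 0], np.cumsum(300.0 * steps, axis=0)])
model = build_dna(interpolate_points(beads))
root = build_hierarchy(model.frames)
print(f"base pairs: {model.n_base_pairs}")

viewpoint = model.frames.origins[0] + [0.0, 0.0, 300.0]
ranges = classify_lod(root, viewpoint, near=500.0, far=2500.0)
print(f"viewpoint 300 Å above the 5' end -> {len(ranges)} ranges:")
for lo, hi, cls in ranges[:6]:
    print(f"  pairs {lo:5d}-{hi:5d}: {cls}")
if len(ranges) > 6:
    print(f"  ... {len(ranges) - 6} more ranges")

# a ray aimed at base pair 1700 from far away
target = model.frames.origins[1699]
origin = target + np.array([2000.0, 500.0, -900.0])
direction = (target - origin) / np.linalg.norm(target - origin)
hit = pick_base_pair(root, origin, direction, hit_radius=1.5)
print(f"ray aimed at pair 1700 picks: {hit}")
miss = pick_base_pair(root, origin, -direction, hit_radius=1.5)
print(f"the opposite ray picks:       {miss}")
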