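"""Interactive-style seed similarity maps.

Correlating every brain voxel against a seed placed in healthy tissue gives
a map near 1 everywhere except the perfusion deficit; re-seeding inside the
deficit inverts the picture.  Recomputing a whole map takes well under a
second, which is what makes cursor-driven exploration possible.
"""

import time

import numpy as np

from tspmap import PhantomSpec, generate_phantom, make_brain_mask, seed_similarity_map

series, gt = generate_phantom(PhantomSpec(rng_seed=42))
mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
healthy = mask.mask & ~gt.lesion_mask

healthy_seed = tuple(np.argwhere(healthy)[healthy.sum() // 2])
lesion_seed = tuple(np.argwhere(gt.lesion_mask & mask.mask)[50])

t0 = time.perf_counter()
map_h = seed_similarity_map(series, mask, healthy_seed)
dt = time.perf_counter() - t0
print(f"whole-map recompute: {dt * 1000:.0f} ms for {mask.n_voxels} voxels")

map_l = seed_similarity_map(series, mask, lesion_seed)
for label, smap in (("healthy seed", map_h), ("lesion seed ", map_l)):
    mh = np.nanmean(smap.values[healthy])
    ml = np.nanmean(smap.values[gt.lesion_mask & smap.defined])
    print(f"{label}: mean R healthy = {mh:+.3f}, mean R lesion = {ml:+.3f}")
print("with a healthy seed the deficit stands out as low R; "
      "seeding inside the deficit inverts the contrast")
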