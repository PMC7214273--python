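"""Test whether a chromatin loop gains contact intensity between conditions.

Two UMI-4C contact profiles (0 h and 168 h) around the same bait are
distance-filtered to the assay's reliable 0.5 kb - 1 Mb band, depth-
normalized, summarized in a multi-scale domainogram, and the planted loop
fragment is tested with a 2x2 chi-square of UMI counts inside vs outside
the window.
"""

import numpy as np

from meth3dlink import SimConfig, generate_dataset
from meth3dlink.umi4c_lite import (
    contact_test, distance_filter, domainogram, fragment_index,
    per_fragment_z, smooth_profile,
)

ds = generate_dataset(SimConfig(seed=1))
t0 = distance_filter(ds.contact_t0)
t168 = distance_filter(ds.contact_t168)
print(f"{len(t0.fragments)} fragments within 0.5 kb - 1 Mb of the bait "
      f"({t0.total_umis} and {t168.total_umis} UMIs at 0 h / 168 h)")

gene, frag, boosted = ds.truth.loop_target
iv = ds.contact_t0.fragments[frag][0]
i = fragment_index(t0, iv.chrom, iv.start + 1)

dg = domainogram(t0, t168, scales=(1, 3, 5))
print(f"domainogram: {dg.values.shape[0]} scales x {dg.values.shape[1]} fragments; "
      f"scale-1 differential contact at the planted fragment = {dg.values[0, i]:+.4f}")

z = per_fragment_z(t0, t168)
print(f"strongest differential fragment by z score: index {int(np.argmax(np.abs(z)))} "
      f"(planted loop index {i})")

res = contact_test(t0, t168, (i, i))
table = res.table
print(f"2x2 UMI table [in, out]: 0 h {list(table[0])}, 168 h {list(table[1])}")
print(f"chi2 = {res.chi2:.1f}, adjusted p = {res.p_adjusted:.3g} -> the loop toward "
      f"{gene}'s promoter gains contacts upon transdifferentiation")
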