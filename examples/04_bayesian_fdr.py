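"""Bayesian FDR thresholding of a PIP map.

The rule declares the largest top set of voxels whose mean posterior
non-inclusion probability (1 - PIP) stays below delta; phi is the
realized PIP threshold and xi the number of surviving voxels.
"""

import numpy as np

import voxelbma as vb
from voxelbma.fdr import realized_bayes_fdr

# the four-voxel worked example: running means of (1 - PIP) are
# 0.01, 0.015, 0.027, 0.12 -> the third voxel is the last one under 0.1
res = vb.bfdr_threshold(np.array([0.99, 0.98, 0.95, 0.60]), delta=0.10)
print(f"worked example: phi = {res.phi}, xi = {res.xi}, "
      f"realized FDR = {realized_bayes_fdr(res):.4f}")

# a larger map: 180 nulls with modest PIPs, 20 signals near 1
rng = np.random.default_rng(8)
pips = np.concatenate([rng.uniform(0, 0.6, 180), rng.uniform(0.97, 1.0, 20)])
res = vb.bfdr_threshold(pips, delta=0.10)
print(f"mixed map: phi = {res.phi:.3f}, xi = {res.xi} "
      f"(the ~20 high-PIP voxels, realized FDR {realized_bayes_fdr(res):.3f} <= 0.10)")

# raising delta can only grow the declared set
for delta in (0.05, 0.10, 0.20):
    print(f"  delta={delta:.2f} -> xi={vb.bfdr_threshold(pips, delta).xi}")
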