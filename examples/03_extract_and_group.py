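"""Break a curve into fragments and reassemble it by good continuation.

Demonstrates the localization half of the pipeline in isolation: a smooth
300-px curve is cut into pieces with 8-20 px gaps, and perceptual grouping
(PCA endpoint models -> gated cubic bending-energy cost -> Hungarian
matching -> mutual validation -> merge) recovers a single ordered curve.
"""

import numpy as np

from wiretrace import GroupingParams, SceneConfig, generate_curve, group
from wiretrace.grouping import build_cost_matrix, endpoint_models

rng = np.random.default_rng(3)
curve = generate_curve(SceneConfig(height=384, width=384), rng)
print(f"original curve: {len(curve)} px")

# cut into 4 pieces with gaps
bounds = np.linspace(0, len(curve), 5).astype(int)
pieces = [curve[a : b - 15] for a, b in zip(bounds[:-1], bounds[1:])]
print(f"fragments: {[len(p) for p in pieces]}")

params = GroupingParams()  # nit=3, npts=10, dmax=40, rho=0.7, tau=10
M = build_cost_matrix(endpoint_models(pieces, params.npts), params)
feasible = np.argwhere(M < params.sentinel)
costs = sorted({float(v) for v in np.round(M[M < params.sentinel], 4)})
print(f"endpoint pairs passing the gates: {len(feasible) // 2} (costs {costs})")

merged = group(pieces, params)
print(f"after grouping: {len(merged)} curve(s) of {[len(c) for c in merged]} px")
# The merged curve keeps only original fragment points (gap pixels are not
# invented); rasterization can optionally bridge the seams for evaluation.
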