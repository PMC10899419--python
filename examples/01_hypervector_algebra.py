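"""Hypervector algebra: near-orthogonality, binding, bundling.

Random high-dimensional vectors are nearly orthogonal, binding (element-wise
product) associates symbols while preserving similarity, and bundling
(element-wise sum) memorizes its constituents instead of averaging them away.
"""

import numpy as np

from spikehd import HDConfig, bind, bundle, cosine_similarity, make_bipolar_hv

cfg = HDConfig(D=10_000, seed=1)
a = make_bipolar_hv(cfg, "a")
b = make_bipolar_hv(cfg, "b")
c = make_bipolar_hv(cfg, "c")

print(f"cos(a, b) for independent random HVs: {cosine_similarity(a, b):+.4f}")
print(f"cos(a (x) b, a) — binding hides both operands: {cosine_similarity(bind(a, b), a):+.4f}")
print(f"cos(a (x) c, b (x) c) == cos(a, b) exactly: "
      f"{cosine_similarity(bind(a, c), bind(b, c)) == cosine_similarity(a, b)}")

k = 5
members = [make_bipolar_hv(cfg, f"m{i}") for i in range(k)]
total = members[0]
for m in members[1:]:
    total = bundle(total, m)
sims = [cosine_similarity(total, m) for m in members]
print(f"bundle of {k} HVs: cos with each constituent ~= 1/sqrt({k}) = {1/np.sqrt(k):.3f}; "
      f"measured {np.mean(sims):.3f}")
probe = make_bipolar_hv(cfg, "fresh")
print(f"cos with a fresh random probe (not a constituent): {cosine_similarity(total, probe):+.4f}")
# A similarity query against the bundle therefore reveals membership: the
# constituents score ~0.45, the outsider ~0.
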