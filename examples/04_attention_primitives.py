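"""The attention primitives in isolation: criss-cross attention, per-set
gates, and PCAT.

Demonstrates the two structural guarantees the tagger relies on: at height 1
the criss-cross neighbourhood is the whole sequence (dense attention), and a
zero value projection makes the block an exact identity.
"""

import numpy as np

from kiwiner.autograd import Tensor
from kiwiner.neural import (
    AttSoftParams,
    CCNetParams,
    PcatParams,
    attsoft_weights,
    criss_cross_attention,
    pcat_forward,
)

rng = np.random.default_rng(0)

# dense-attention degeneracy at H=1
params = CCNetParams(8, rng=rng)
m = rng.normal(size=(8, 6, 1))  # 8 channels, width 6, height 1
out = criss_cross_attention(Tensor(m), params)
print(f"criss-cross output shape: {out.shape} (equals input)")

params.wv.data[:] = 0.0
identity = criss_cross_attention(Tensor(m), params)
print(f"zero value projection -> max |out - in| = {np.abs(identity.data - m).max():.1e}")

# per-set gates: four pooled set vectors -> four weights in (0, 1)
gate_params = AttSoftParams(8, rng=rng)
v_sets = rng.normal(size=(8, 4, 1))
a = attsoft_weights(Tensor(v_sets), gate_params)
print(f"set gates (B, M, E, S): {np.round(a.data, 3)}  all in (0, 1)")

# PCAT preserves the sequence shape for any width
pcat = PcatParams(8, rng=rng)
for width in (1, 5, 23):
    y = pcat_forward(Tensor(rng.normal(size=(8, width))), pcat)
    assert y.shape == (8, width)
print("PCAT preserves [channels, width] for widths 1, 5, 23")
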