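"""Apply GEFA to a random feature map and inspect its gate.

Shows the plug-in contract: shape preservation, a gate strictly inside
(0, 1), and the residual identity y = x + A * U.
"""

import numpy as np

from gefay.attention import GEFA, AttentionSpec, eca_kernel_size
from gefay.autograd import Tensor

rng = np.random.default_rng(0)
c, h, w = 64, 20, 20
x = rng.normal(0, 1, (1, c, h, w)).astype(np.float32)

spec = AttentionSpec("gefa")  # calibrated defaults: G=8, k=1, w=13/8, p=5
mod = GEFA(c, spec, rng=rng)
y = mod(Tensor(x))

print(f"input {x.shape} -> output {y.shape}")
print(f"adaptive 1-D kernel k(C={c}) = {eca_kernel_size(c)}")
print(f"learned weights: {mod.num_parameters()}")
update = y.data - x
print(f"residual update magnitude: mean |y - x| = {np.abs(update).mean():.4f}")
for name, n in list(mod.weight_inventory().items()):
    print(f"  {name}: {n}")
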