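"""Reproduce the complexity table: parameters and GFLOPs per attention
variant at 640x640.

Builds the 20-class detector with each attention operator in the
AttentionC3 slots and prints the (variant, GFLOPS, params M) grid.  The
NONE row is the attention-free baseline; params never decrease when an
attention module is added.
"""

from gefay.attention import AttentionSpec
from gefay.model import ModelSpec
from gefay.profiler import table_report

base = ModelSpec(nc=20)
specs = [AttentionSpec("none"), AttentionSpec("se"), AttentionSpec("eca"),
         AttentionSpec("ca"), AttentionSpec("cbam"), AttentionSpec("mlca"),
         AttentionSpec("gefa")]
print(table_report(base, specs, input_size=640))
print()
print("Params column: millions of learned weights, truncated to 2 decimals.")
print("GFLOPS column: one 640x640 forward pass under the frozen convention.")
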