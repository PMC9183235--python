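"""Render a probabilistic rastergram of p(specific) time records.

Orders AOIs by decreasing time-to-first-binding and color-codes
p(specific), giving an at-a-glance view of binding activity across the
field of view.  Writes rastergram.png next to this script.
"""

from pathlib import Path

import numpy as np

from cosmospot import rastergram, sample_traces, simulate_kinetic_states

z = simulate_kinetic_states(0.01, 0.1, N=40, F=400, rng=7).astype(float)
# soften the record into probabilities, as an image fit would produce
p = np.clip(z + np.random.default_rng(0).normal(0, 0.06, z.shape), 0, 1)

fig, order = rastergram(p, frame_step=2)
out = Path(__file__).with_name("rastergram.png")
fig.savefig(out, dpi=150)
print(f"wrote {out}")
print(f"first AOI plotted (latest binder arrival): {order[0]}")
print(f"last AOI plotted (earliest binder arrival): {order[-1]}")
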