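"""Boost a run of modest per-site p-values by combining neighbors.

CpG methylation is locally correlated, so several adjacent sites with
moderate evidence are jointly more convincing than any one of them.
The weighted-Z (Stouffer-Liptak) combination makes that explicit while
correcting for the correlation between nearby tests.
"""

import numpy as np

from betameth.combine import adjust_all

rng = np.random.default_rng(0)

n = 5000
positions = np.cumsum(rng.integers(20, 120, size=n))
chroms = np.repeat("chr1", n)

p_raw = rng.uniform(size=n)
p_raw[2500:2510] = 0.04        # ten consecutive sites with weak evidence

p_combined = adjust_all(chroms, positions, p_raw,
                        window_bp=200, max_dist=200)

inside = slice(2501, 2509)      # interior of the run
print(f"raw p inside the run:       {p_raw[inside].mean():.4f}")
print(f"combined p inside the run:  {p_combined[inside].mean():.2e}")
print(f"median combined p elsewhere: {np.median(np.delete(p_combined, range(2500, 2510))):.3f}")
print()
print("Sites inside the run drop below their raw 0.04 because the")
print("neighbors that share their window agree; background sites stay")
print("near uniform, so the combination adds power without")
print("manufacturing significance.")
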