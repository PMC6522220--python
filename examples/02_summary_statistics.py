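"""Compute the four spatial summary statistics S1-S4 on synthetic
tracking data and show how they separate clustered from uniform worms.

S1: pair correlation (neighbour excess vs uniform), S2: single-linkage
branch-length histogram, S3: positional standard deviation (mm),
S4: positional kurtosis (Gaussian = 3, uniform ~ 1.8).
"""
import numpy as np

from wormswarm import generate_fixtures, summarize_dataset

for kind in ("uniform", "clustered"):
    ds = generate_fixtures(kind, seed=4)
    s = summarize_dataset(ds)
    peak_bin = np.nanargmax(s.s1)
    print(f"{kind:9s}  S1 peak {np.nanmax(s.s1):6.1f} at "
          f"r = {s.s1_edges[peak_bin]:.1f}-{s.s1_edges[peak_bin + 1]:.1f} mm, "
          f"S3 = {s.s3:.2f} mm, S4 = {s.s4:.2f}")

print("\nClustered positions show a large S1 short-range peak, a smaller")
print("spread S3 and a heavier-tailed S4 than the uniform control.")
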