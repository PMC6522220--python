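"""Detect reversal events in a scripted track and estimate density-binned
reversal rates from synthetic worm-frames with a known rate law.

Reversals are positive-to-negative sign changes of the signed speed (the
dot product of the pharynx skeleton vector with the velocity sets the
sign), kept when the backward path is >= 50 µm.
"""
import numpy as np

from wormswarm import detect_reversals, generate_fixtures, signed_speed
from wormswarm.tracks import reversal_rate_by_density

ds = generate_fixtures("scripted_reversal",
                       {"lengths_um": [100.0, 60.0, 55.0, 40.0]}, seed=0)
fps = ds.truth["frame_rate"]
speed = signed_speed(ds.centroids[:, 0], ds.truth["skeleton_vec"], fps)
events = detect_reversals(speed, ds.centroids[:, 0], fps)
print(f"scripted excursions 100/60/55/40 µm -> {len(events)} detected "
      "(40 µm is below the 50 µm minimum)")

# density-binned rate estimation on synthetic Poisson reversals, r = c*rho
rng = np.random.default_rng(0)
c, dt = 0.05, 0.1
rho = rng.uniform(0.5, 6.0, size=50_000)
event_idx = np.where(rng.uniform(size=rho.size) < 1 - np.exp(-c * rho * dt))[0]
bins = np.arange(0, 7, 1.0)
rates, _, boot_std = reversal_rate_by_density(
    rho, np.ones_like(rho, dtype=bool), event_idx, dt, bins, rng=1)
for lo, hi, r, s in zip(bins[:-1], bins[1:], rates, boot_std):
    print(f"  rho {lo:.0f}-{hi:.0f} /mm^2: rate {r:.3f} +- {s:.3f} /s "
          f"(truth {c * (lo + hi) / 2:.3f})")
print("\nEstimated rates rise linearly with density, matching r = 0.05*rho.")
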