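"""Align five replicate profiles on the fitted reference peak and average them.

Each replicate embryo's reference peak lands at a different position (3 px
placement jitter); after Gaussian-peak fitting and centering, the mean ± s.e.m.
curve has its reference maximum at 0.
"""

import numpy as np

import hcrprof as hp

stacks, truth = hp.generate_scene(hp.stage13_scene(seed=0))
profiles = [
    hp.normalize_profile(hp.extract_profile(hp.max_project(s), line))
    for s, line in zip(stacks, truth.lines)
]

aligned = hp.align_profiles(profiles, reference_channel="pax3")
print("per-image fitted centers:",
      {k: round(f.center, 2) for k, f in aligned.fits.items()})
print("applied shifts:", aligned.shifts)

avg = hp.average_profiles(aligned)
peak = avg.grid[np.argmax(avg.channel_mean("pax3"))]
print(f"common grid: [{avg.grid.min()}, {avg.grid.max()}] px, n = {avg.n}")
print(f"reference mean peak at {peak} px (0 = perfectly centred)")
print(f"median s.e.m. of klf17: {np.median(avg.channel_sem('klf17')):.4f}")
# The fitted centers track each replicate's jitter; the shifts cancel it, so
# the averaged reference peak sits at (or within 1 px of) position 0.
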