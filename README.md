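# hcrprof

Quantitative line-profile analysis of multiplexed fluorescence (HCR) images
of embryonic gene-expression domains.

Developmental biologists often need to say, quantitatively, how two gene
expression domains are arranged relative to each other — does a query gene's
domain cover a reference stripe, or has it resolved into bands that flank it?
`hcrprof` implements the standard measurement chain for answering this from
two-channel confocal images of banded (stripe-shaped) domains along an
embryo's medial–lateral axis:

1. **Projection** — per-channel maximum intensity projection over z.
2. **Line profiles** — bilinear sampling of every channel at unit steps along
   a user-defined medial→lateral segment (optional perpendicular averaging).
3. **Normalization** — per channel, per profile: `(I − min)/(max − min)`,
   so every channel spans [0, 1].
4. **Peak-centred alignment** — the reference channel of each image is fitted
   with a Gaussian peak `b + A·exp(−(x−c)²/2σ²)`; all of that image's
   profiles are shifted so the fitted peak sits at position 0; replicate
   grids are intersected ("common x-values") and trimmed.
5. **Averaging** — per channel and position, mean and s.e.m. (`sd/√n`) over
   replicates: the familiar mean-curve-with-shading plot.
6. **Domain metrics** — the reference domain is its FWHM interval around 0;
   the overlap coefficient is the fraction of baseline-subtracted query
   signal mass inside that interval; a categorical call
   (`overlapping` / `partial` / `flanking`) makes the geometry explicit.

Because microscopy data of this kind are rarely shareable, the package ships
a seeded synthetic-scene generator with analytic ground truth (mixtures of
Gaussian bands plus noise and replicate jitter), including presets for the
two canonical geometries: an early-neurula-like scene where the query channel
broadly overlaps the reference stripe, and a late-neurula-like scene where
the query has split into two bands flanking it.

Supporting statistics round out a typical study: phenotype-scoring
percentages with Wilson intervals, ΔΔCt qPCR fold changes
(`fold = 2^(−ΔΔCt)`, normalized to a reference gene such as ODC), and
fold-change tests (Welch's unpaired two-tailed *t*).

## Worked example

```python
import numpy as np
import hcrprof as hp

stacks, truth = hp.generate_scene(hp.stage13_scene(seed=0))
profiles = [
    hp.normalize_profile(hp.extract_profile(hp.max_project(s), line))
    for s, line in zip(stacks, truth.lines)
]
aligned = hp.align_profiles(profiles, reference_channel="pax3")
avg = hp.average_profiles(aligned)
rel = hp.classify_relation(avg, "pax3", "klf17")
print(avg.grid[np.argmax(avg.channel_mean("pax3"))], rel.call,
      round(rel.overlap_coefficient, 3))
```

prints

```
-1 overlapping 0.666
```

— after alignment the reference mean peak sits within 1 px of 0, and 66.6%
of the query channel's signal mass lies inside the reference FWHM, so the
two domains are called overlapping.  Running the same chain on the
`stage17` preset (reference `snai2`) prints `flanking` with an overlap
coefficient of 0.008: the query's two bands sit at −30 and +32 px, outside
the reference FWHM of [−9.5, 9.8] px.  The `examples/` directory has one
short script per capability; each prints the numbers it computes and what
they mean.

A thin CLI mirrors the stages for shell use:

```bash
hcrprof simulate --config scene.json --outdir imgs
hcrprof profile  --images imgs --lines imgs/lines.csv --out profiles.csv
hcrprof align    --profiles profiles.csv --reference pax3 --out avg.csv
hcrprof metrics  --avg avg.csv --reference pax3 --query klf17
hcrprof run      --config pipeline.json     # end to end, with a manifest
hcrprof score / ddct / foldtest             # the statistics commands
```

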