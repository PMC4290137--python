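# vesselseg

Localized hybrid level-set segmentation of 3D vessel images.

Extracting vasculature from MRA/CTA volumes is hard because vessel intensity
is *inhomogeneous*: contrast falls from the bright trunk toward thin distal
branches, so any single global intensity threshold either loses the thin
branches or floods the background. `vesselseg` implements a hybrid active
contour whose region force is driven by **automatically computed, spatially
varying lower-bound thresholds**

    μ(u) = k · (K_σ ∗ I)(u),        k ∈ [0.5, 1]

(the k-scaled Gaussian local mean of the image), combined with the geodesic
active contour edge term. The evolving surface is the zero set of a level-set
field φ, updated per iteration as

    φ′ = φ + Δt·α·δ_ε(φ)(I − μ)                        (region)
    φ  = φ′ + Δt·β·δ_ε(φ′)·div(g(|∇I|) ∇φ′)           (edge),

with exact signed-distance reinitialization before each half-step,
`g(h) = 1/(1 + c h²)`, and the arctan-regularized Heaviside/Dirac pair.
Setting a constant `global_mu` runs the *original* hybrid model through the
same code path, so the two can be compared on bit-identical inputs. The
package also ships a branching-vessel phantom generator with exact ground
truth (intensity-inhomogeneous branches, calibrated Gaussian noise), Dice /
segmentation-error validation, volume I/O (NIfTI, NRRD, single-series DICOM
directories), MIP rendering, and a CLI.

Intended users: image-analysis researchers who need a reproducible
region+edge level-set baseline for tubular structures, and anyone comparing
local-threshold against global-threshold active contours.

## Worked example

```python
from vesselseg import (BallSeed, HybridLevelSet, PhantomSpec,
                       add_gaussian_noise, generate_phantom)

spec = PhantomSpec.default((64, 48, 64), rng_seed=0)   # branching-tube phantom
truth = generate_phantom(spec)                         # clean volume + ground truth

trunk = spec.centerline_tree[0]
i = len(trunk.points) // 5                             # a ball seed inside the trunk
seed = BallSeed(tuple(trunk.points[i]), max(float(trunk.radii[i]) - 1.0, 1.5))

res = HybridLevelSet(truth.volume, [seed]).fit()
print(res.summary())
print("Dice vs ground truth:", round(res.dice(truth.mask), 4))
```

prints

```
Hybrid level-set segmentation results
==========================================
Model:                localized_hybrid
Volume shape:         64x48x64
Iterations:           46 (converged=True)
Interior voxels:      3653
dt / alpha / beta:    4.0 / 0.01 / 0.5
sigma / eps / k / c:  3.0 / 1.0 / 0.9 / 400.0

Dice vs ground truth: 0.898
```

The run converges in 46 iterations; Dice 0.898 against the exact tube mask
means the surface sits within a fraction of a voxel of the true boundary
everywhere, including the branch dimmed to 45 % intensity (a global
threshold at half the peak covers only ~26 % of that branch). The boundary
sits marginally outside the nominal tube surface because the local mean —
hence μ — dips below the boundary isovalue around thin tubes; see
`docs/methods.md`. On the same phantom corrupted with variance-0.001
Gaussian noise the model reaches Dice 0.904.

The baseline comparison, from the shell:

```bash
vesselseg benchmark --shape 64 48 64 \
    --variances 0.001 --variances 0.005 --variances 0.01 --variances 0.015 \
    -o bench_out
```

writes a CSV / text table of Dice and SE per (model, variance), MIP
snapshots, and a reproducibility manifest. `vesselseg phantom`,
`vesselseg segment` and `vesselseg metrics` generate phantoms, segment
arbitrary NIfTI/NRRD/DICOM volumes from seed balls or seed masks, and score
mask pairs.

## Layout

- `src/vesselseg/numerics.py` — Heaviside/Dirac, edge indicator, threshold
  map, SDF reinitialization, edge-weighted divergence
- `src/vesselseg/model.py` — configuration, seeding, evolution loop,
  `HybridLevelSet` / `SegmentationResult`
- `src/vesselseg/phantom.py` — branching-tube phantom with ground truth
- `src/vesselseg/metrics.py` — Dice/SE, components, benchmark runner
- `src/vesselseg/io.py` — NIfTI/NRRD/DICOM volumes, masks, MIPs
- `src/vesselseg/cli.py` — `vesselseg` command group
- `docs/methods.md` — model, parameters, numerical choices, limitations
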