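# Methods

## Model

`vesselseg` segments bright tubular structures (vessels in MRA/CTA) with a
hybrid level-set active contour. The surface is the zero set of a scalar
field φ over the voxel grid (φ > 0 inside), evolved to minimize an energy
with two parts:

- a **region term**, weight α, that pushes the surface outward wherever the
  image intensity I exceeds a *lower-bound threshold* for vessel tissue, and
  inward where it falls below it;
- a **geodesic edge term**, weight β, the classic edge-weighted curvature
  flow `div(g(|∇I|) ∇φ)` with `g(h) = 1/(1 + c h²)`, which regularizes the
  surface where the image is flat and switches itself off (g → 0) at strong
  gradients so that real boundaries are not smoothed away.

The package's contribution-bearing piece is the **localized threshold map**

    μ(u) = k · (K_σ ∗ I)(u),

the Gaussian-weighted local mean of the image scaled by an adjustment
coefficient k ∈ [0.5, 1]. A single preset global threshold μ (the *original*
hybrid model, available here as the same code path with a constant threshold
map) cannot be right simultaneously for a bright vessel trunk and its dim
distal branches; the local mean adapts, and k < 1 biases the threshold low
enough that the contour does not stall inside a vessel before reaching its
boundary. Setting `global_mu` in the configuration reproduces the original
model exactly — the comparison between the two isolates precisely the effect
of localization.

Each iteration performs, with time step Δt (forward Euler):

1. reinitialize φ to a signed distance function (SDF);
2. obtain μ(u) (precomputed once — it depends only on I, σ, k);
3. region force δ_ε(φ)·(I − μ);
4. φ′ = φ + Δt·α·δ_ε(φ)·(I − μ);
5. reinitialize φ′ to an SDF;
6. φ ← φ′ + Δt·β·δ_ε(φ′)·div(g ∇φ′).

δ_ε and H_ε are the arctan-regularized Dirac/Heaviside pair,
H_ε(s) = ½(1 + (2/π)·arctan(s/ε)), δ_ε(s) = (ε/π)/(ε² + s²), which restrict
updates to a band of width ~ε around the surface. Step 6 evaluates δ_ε and
∇φ on the freshly reinitialized field from step 5 (that reinitialization
exists to precondition the curvature step); `stale_curvature_field=True`
switches to the stale pre-region-update field for A/B comparison — in our
experiments the difference is marginal.

## Parameters

| name | default | units | role |
|---|---|---|---|
| `dt` | 4.0 | iterations⁻¹ | explicit time step |
| `alpha` | 0.01 | – | region-force weight |
| `beta` | 0.5 | – | edge-force weight |
| `sigma` | 3.0 | voxels | Gaussian scale of the local threshold map |
| `eps` | 1.0 | voxels | Dirac/Heaviside band width |
| `k` | 0.9 | – | threshold adjustment coefficient (warned outside [0.5, 1]) |
| `c` | 400 | – | edge-indicator scope on the [0,1]-rescaled image |
| `sigma_edge` | 1.0 | voxels | gradient pre-smoothing for the edge map |
| `max_iters` / `tol_voxels` | 500 / 0 | – | stop after 3 consecutive iterations changing ≤ `tol_voxels` mask voxels |

The first six defaults are the reference parameter set used unchanged for
every experiment in this package. `c` has no reference value; we define it
on the intensity-normalized image so it is modality-independent, and choose
c = 400, i.e. g = ½ at a gradient of 5 % of the dynamic range per voxel.
This is a considered choice: with c of order 1 on normalized data, g ≥ 0.94
everywhere, so the edge term degenerates into an *unweighted* mean-curvature
flow — it then pinches off thin branches (a tube tip of radius ρ shrinks at
rate ∝ 2/ρ, which outruns the region force's discrete capture rate) while
never performing its edge-stopping duty. With c = 400, flat and noise-scale
gradients keep g ≈ 1 (regularization on) and boundary-scale gradients drive
g ≈ 0 (curvature gated off at edges), which is the behavior the edge
indicator is defined to produce.

## Numerical choices

- **Reinitialization** is the exact signed Euclidean distance transform of
  the binarized field {φ ≥ 0} (scipy EDT), not iterative PDE sweeping:
  deterministic, unconditionally stable, idempotent, and the zero level set
  never moves more than one voxel. Magnitudes carry a −½ voxel offset so the
  implied interface sits between the inside and outside voxel layers;
  thresholding at φ ≥ 0 recovers the binarization exactly.
- **Capture margin.** Because reinitialization clamps a voxel's headroom to
  ±½ voxel, a voxel adjacent to the surface flips inside only when
  Δt·α·δ_ε(½)·(I − μ) > ½, i.e. I − μ ≳ 49 gray at the defaults. Region
  forces below that margin cannot advance the front (and conversely a
  captured voxel is only released below −49). This discrete hysteresis makes
  the front *tighter* than the continuous flow, whose equilibrium is I = μ.
- **Gradients** are central differences with one-sided stencils at the faces
  (`numpy.gradient`), in voxel units; anisotropic spacing is metadata only
  and never enters the PDE.
- **Gaussian filtering** uses reflective boundaries so thresholds are not
  artificially darkened at the volume faces.
- The stability log line: with the defaults, Δt·β·max(δ_ε) = 0.64 exceeds
  the linear heat-equation bound 1/6; the per-iteration exact
  reinitialization bounds the scheme in practice, and a warning is logged
  once per process.
- Degenerate cases: an all-positive or all-negative φ raises a
  degenerate-interface error carrying the iteration index; non-finite values
  raise a numerical-failure error. Two empty masks make Dice undefined and
  raise rather than return a value.

## Synthetic phantom

The generator emulates an angiographic validation volume with known ground
truth: a branching tube tree on a 100×70×106 grid (any shape ≥ 24×24×32
works; the scaled benchmarks below use 64×48×64), peak intensity 500 inside
the tubes, a linear ramp of half-width w = 1 voxel through 250 exactly at
the tube surface, background 0. The default tree is a curved trunk of radius
4 voxels with two generations of daughters leaving at ≈40°, caliber dropping
by a factor 0.75 across each bifurcation down to 1.5-voxel terminal tips
(within-branch taper is mild — real vessels lose caliber mainly at
branch points). One first-generation branch and its child are dimmed to 0.45
of full intensity to simulate intensity inhomogeneity: in a maximum
intensity projection the dim branch looks disconnected, while the geometric
ground truth (all voxels within the local tube radius of the centerline
tree) is unchanged. Zero-mean Gaussian noise is defined on the [0,1]
intensity scale (divide by the 500 peak), added i.i.d., clipped to [0, 1.2]
— the ceiling above 1 keeps the in-vessel noise distribution from being
half-truncated — and mapped back.

What the phantom does **not** emulate: MR bias fields, Rician noise
statistics, partial-volume point-spread (the w = 1 ramp is a coarse stand-in),
vessel curvature continuity at junctions, or background tissue texture.
Passing these benchmarks therefore shows that the implementation realizes
the model's comparative behavior (localization beats a global threshold
under inhomogeneity and noise), not that it reaches any particular accuracy
on clinical data.

## Benchmarks and problem sizes

The validation protocol fixes one phantom, corrupts it at variances
{0.001, 0.005, 0.01, 0.015}, and runs both models from the same trunk seed
on bit-identical inputs (the noise field is one standard-normal draw scaled
by √variance — common random numbers — so the variance trend is a paired
comparison). Quality is the Dice coefficient Dice = 2|A∩B|/(|A|+|B|)
reported as segmentation error SE = (1 − Dice)·100; fragmentation is counted
as 26-connected components of the mask restricted to the dilated ground
truth. Benchmarks run on a 64×48×64 grid with the same tree topology and
absolute tube calibers as the full-size default; at that size the full
two-model, four-variance suite completes in about a minute on one core.

Typical numbers (phantom seed 0/1): localized SE ≈ 9.8–11.9 % rising
monotonically with variance, original hybrid (global μ = 250) ≈ 13.1–15.0 %;
dimmed-branch coverage ≈ 93 % (localized) vs ≈ 26 % (original); both
restricted masks form a single connected component.

## Known limitations

- **Sub-voxel boundary dilation.** By construction the localized model
  annexes every boundary-halo voxel whose intensity clears μ plus the
  capture margin; on the analytic w = 1 ramp this is a 0.1–0.4 voxel outward
  bias (clean-phantom Dice ≈ 0.90 at the default tree's surface-to-volume
  ratio — SE ≈ 10 %, which is where a sub-voxel surface bias lands on
  tubes of 1.5–4 voxel radius). The bias shrinks as vessels get thicker or
  edges sharper.
- The region force cannot advance through gaps where the local mean exceeds
  the dim-branch interior (a short collar can be missed right at a
  bright-to-dim junction).
- Full-grid updates only (no narrow band); cost is linear in voxels per
  iteration, ~0.5 s/iteration on a 100×70×106 grid.
- No topology control, vesselness priors, or automatic seeding; seeds must
  lie strictly inside the target vessel.
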