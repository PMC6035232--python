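# Methods

## Model

Every length-normalised intensity profile `y_j` (a column of the N × M
matrix `Y`) is assumed to be a non-uniformly sampled observation of one
continuous population template `f(x, c)` on `[0, 1]`, distorted by an
unknown monotone warp `g_j`. The template is a finite sinc expansion,

    f(x) = Σ_{k=0}^{L−1} c_k sinc(x/Δ − k),  Δ = (L−1)⁻¹,

so `f(kΔ) = c_k` exactly. Estimation minimises

    E(X, c, Y) = E_Y(X, c, Y) + α cᵀψ_L c + β Tr[Xᵀψ_N X]

jointly over the coefficients `c` and the sample locations
`X = {x_ij} ⊂ [0, 1]`, alternating between the two blocks. `ψ` is the
first-difference quadratic penalty (`cᵀψc = Σ(c_k − c_{k−1})²`), whose null
space is the constants; the same operator applied down the location columns
is a tension term that stops warps from collapsing all samples onto one
point. The endpoints `x_{0,j} = 0`, `x_{N−1,j} = 1` are pinned and never
updated, which (with the tension term) makes the location problem well
posed.

Two data-fidelity models are available. Gaussian (AWGN):
`E_Y = Σ ω_{j} (f(x_ij) − y_ij)²`. Poisson — appropriate for photon-limited
fluorescence — uses the negative log-likelihood
`E_Y = Σ ω_j [f(x_ij) − y_ij log f(x_ij)]`, with `f` clipped below at
ε = 10⁻⁶ inside the logarithm, and enters the quadratic solver through the
local curvature weights `γ_ij = 1/(2 f(x_ij) + ε)`.

Internuclear (IN) templates carry a mirror-symmetry constraint
`c = P c̃` (the interface between cells A and B is the same seen from
either side); radial (RD) templates do not. For a mirror-symmetric `c` the
full penalty satisfies `cᵀψ_L c = 2 c̃ᵀψ_{L/2} c̃`, so the folded normal
equations use `2α ψ_{L/2}` — this makes the folded solve the exact energy
minimiser, at the cost of reading `α` as defined on the full-length
coefficient vector.

### Outlier rejection

A profile whose squared distance to the current template,
`d_j = ‖f(x_j) − y_j‖²`, exceeds

    τ = med(d) + outlier_factor · (1.4826·MAD(d) + med(d))

has its indicators set to zero and is excluded from the template fit; its
locations keep being updated by the data force, so it is re-admitted
automatically if `d_j` later falls below τ. Flooring the spread estimate by
the median makes the rule scale-free: after convergence the well-aligned
bulk concentrates near the noise floor, where the MAD alone degenerates and
would flag ordinary biological heterogeneity; genuine garbage sits orders of
magnitude above the median and is caught at any reasonable factor. On
heterogeneous image stacks (beams grazing triple points or the frame
border) the rule intentionally rejects a substantial minority of columns —
those are profiles the single-template model cannot explain. Whenever the
indicator vector changes, the coefficients are re-fitted before the
location step, so a rejected column (including the all-ones first pass)
never leaks into the template that drives the warps.

### Optimisation and numerical safeguards

* **Coefficient step** — exact solve of the regularised weighted normal
  equations (IRLS-style under the Poisson model, with weights frozen at the
  previous template).
* **Location step** — the fixed-point form
  `x_j ← (1/3)(Ω x_j − z_j/β)`, `z_ij = γ_ij (f − y) ḟ`, where Ω is the
  tridiagonal neighbour-sum operator with doubled boundary entries. Three
  safeguards wrap it: (i) a trust region capping each entry's displacement
  at one grid spacing 1/(N−1), because γ diverges where `f` approaches
  zero; (ii) a per-column backtracking line search that halves the step
  fraction until the column's (data + tension) energy does not increase —
  the location problem is column-separable given `c`, and per-column
  damping stops one pathological profile from throttling everyone else's
  step size; (iii) re-pinning of the endpoints followed by projection onto
  the monotone cone (running maximum, clipped to [0, 1]) after every step,
  since the raw update does not preserve the monotonicity the warp model
  requires. The line-search merit weights **all** columns so that rejected
  profiles remain free to realign; the reported energy trace uses the
  ω-weighted objective and is non-increasing except at iterations where the
  outlier set changes (re-admission legitimately re-adds data terms).
* **Stopping** — relative change of the all-columns merit below `tol`, or
  `max_iter` sweeps.
* **Compensated map** — each column's pairs `(x*_ij, y_ij)` are resampled
  onto the uniform grid by monotone piecewise-linear interpolation, which
  cannot overshoot and tolerates the ties the projection can create.

### Defaults

| parameter | default | meaning / rationale |
|---|---|---|
| N | 101 | samples per normalised profile; midpoint is index 50, so interface readouts land on a round position |
| n | 10 | lines per IN beam |
| m | 36 | rays per RD fan (10° steps) |
| L | 20 | sinc basis size; Δ ≈ 0.053 resolves interface ridges a few samples wide without chasing noise |
| α | 0.3 | template smoothness; chosen by the variance-reduction / template-recovery property tests — 1.0 over-smooths narrow peaks enough to lose to the naive column mean, 0.1 lets single-column perturbations move the template |
| β | 10 | location tension; with the trust region the solver is insensitive to β over ~2 orders of magnitude |
| outlier_factor | 3 | multiplier in τ above |
| ε | 1e-6 | Poisson guard constant |
| max_iter, tol | 200, 1e-6 | alternation budget and relative-energy stopping tolerance |

## Synthetic data

The image generator (`synthgen`) emulates a confluent epithelial-like
monolayer: nucleus centroids on a jittered grid (so populations are
irregular but non-overlapping), cell territories formed by the Voronoi
partition of the centroids clipped to per-cell random ellipses (leftover
pixels reassigned to the nearest covering cell so the frame is tiled without
gaps — confluence is required for internuclear beams to cross only true
cell–cell interfaces), and three marker prototypes: a Gaussian ridge along
the region boundary (membrane), a field rising toward but dipping at the
boundary (cytoplasm), and a perinuclear annulus over a near-dark cytosol
(organelle). Intensities live on an 8-bit-like [0, 255] "a.u." scale;
optional per-channel Poisson shot noise makes the channels resemble
photon-limited micrographs. Everything is reproducible from a single seed.

`warped_profile_stack` generates the 1-D benchmark condition used by the
compensation tests: 30 columns `y_j = f(g_j(x))` for a Gaussian-bump
template (peak 100 a.u., width 0.12) under random monotone cubic Bézier
warps blended 60/40 with the identity (typical mid-profile displacement
~0.09 — the scale of cell-size variability the method is meant to absorb),
plus Poisson noise.

What the generator does **not** emulate: point-spread-function blur,
uneven illumination and background gradients, touching/overlapping nuclei,
3-D sectioning effects, photobleaching, or multi-clone mixtures. Passing
tests therefore demonstrate the correctness of the geometry, the estimator
and its robustness properties under the stated noise model — not
segmentation robustness on difficult real micrographs, where the
minimum-area filter and the centroid-override input are expected to carry
more weight.

## Design choices where the design was open

* The four beam anchors are read as the two perpendicular-diameter ends of
  each nucleus, with line i running from a point swept across nucleus A's
  diameter to the matching point on B's — the only reading consistent with
  quasi-parallel-to-the-axis beams, per-line lengths equal to the centroid
  distance, and an interface peak at the profile midpoint.
* Triangle pruning uses the largest internal angle and the longest edge as
  the two outlier statistics, computed per image, in a single pass
  (statistics are not re-estimated after removals, which could cascade).
* Profiles are floored at zero when packed into `Y`: intensities are
  physically non-negative and bi-cubic resampling ringing would otherwise
  break the Poisson likelihood.
* Ray–spline intersection uses a dense (1024-point) polyline and exact
  ray–segment intersection with a smallest-radius tie-break.
* Border cells (fewer than 3 network neighbours, or a centroid outside its
  neighbour spline) are excluded from RD analysis rather than extrapolated.
* Peak positions resolve ties to the smallest index (logged).

## Known limitations

* The alternation converges to a local optimum; profiles warped far beyond
  the template's overlap can stall as permanent outliers. The defaults
  handle mid-profile displacements up to roughly ±0.15.
* The Poisson energy uses a quadratic surrogate for the coefficient step;
  its trace can in principle wiggle within an iteration even though the
  location step is line-searched (not observed in the test conditions).
* Segmentation is a plain Otsu + connected components; touching nuclei are
  not split (no watershed), matching the scope of the pipeline it
  implements — a centroid-override JSON input stands in for manual fixes.
* `Tr[Xᵀψ_N X]` couples only within columns; the method does not exploit
  spatial adjacency between neighbouring beams.
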