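# profilecomp

Quantitative mapping of fluorescence markers in cell populations whose cells
differ in size and shape. Immunofluorescence images of real cultures are
morphologically heterogeneous: the same marker (a membrane adhesion protein,
a cytoskeletal component, an organelle dye) sits at a different pixel
distance from every nucleus, so naively averaging intensity profiles across
cells smears the signal beyond interpretation. `profilecomp` removes that
geometric variability by *elastic geometric compensation*: it treats every
extracted 1-D profile as a warped observation of one latent population
profile, estimates the warp of each profile together with the latent
template, and reports compensated maps, mean ± SD curves and virtual-cell
reconstructions.

The package is aimed at bioimage analysts who want per-compartment intensity
profiles (cell–cell interface vs. intracellular distribution) rather than
whole-cell integrated intensities.

## Method

**Profile extraction.** Nuclei are segmented (Otsu threshold,
Moore-neighbour boundary tracing with Jacob's stopping criterion) and their
centroids triangulated with a Delaunay tessellation; highly obtuse triangles
(largest angle > μ + 3σ, or longest edge > μ + 5σ, per image) are pruned.
Surviving edges define neighbouring cell pairs and neighbourhoods:

* **IN (internuclear) profiles** — for each pair, n = 10 quasi-parallel lines
  flank the axis joining the two nucleus centroids, each running from one
  nucleus's perpendicular diameter to the other's and sampled (bi-cubically,
  sub-pixel) at one point per pixel of centroid distance. They capture the
  shared cell–cell interface.
* **RD (radial) profiles** — m = 36 equi-angular rays from each centroid out
  to a closed periodic spline through the neighbouring centroids. They
  capture the intracellular distribution of a single cell.

All profiles are length-normalised to N = 101 samples (midpoint index 50)
and packed as the columns of a matrix `Y`.

**Geometric compensation.** Each column `y_j` is modelled as a distorted
sampling of an ideal profile

    f(x) = Σ_k c_k sinc(x/Δ − k),   Δ = 1/(L−1),   x ∈ [0, 1],

through an unknown monotone warp. The coefficients `c` and the per-profile
sample locations `X = {x_ij}` are found by alternating minimisation of

    E(X, c, Y) = E_Y(X, c, Y) + α cᵀψ_L c + β Tr[Xᵀψ_N X]

with `E_Y` a Poisson (or Gaussian) data-fidelity term, ψ first-difference
smoothness/tension penalties, and per-profile binary outlier indicators ω_j
that exclude profiles far from the current template (they keep being warped
and can re-enter later). The coefficient step is an exact regularised
weighted least-squares solve; the location step is a safeguarded fixed-point
update with endpoints pinned at 0/1 and a monotonicity projection. IN
templates are mirror-symmetric by construction (`c = P c̃`), since the
interface looks identical from either cell.

## Worked example

```python
import numpy as np
import profilecomp as pc

cfg = pc.PopulationConfig(n_cells=30, marker_mode="membrane", seed=1)
sample = pc.generate_population(cfg)                       # 512x512, Poisson noise
records = pc.segment_nuclei(pc.preprocess(sample.nuclei_channel))
network = pc.build_network(np.array([r.centroid for r in records]), records)
beams = pc.extract_in_profiles(sample.marker_channel, network, n_lines=10)
matrix = pc.assemble_matrix(beams, 101)
state, ideal = pc.compensate(matrix)                       # Poisson model, symmetric
comp = pc.compensated_map(state, matrix)
summary = pc.summarize(comp, state.omega)
```

which prints, via the obvious `print` statements:

```
nuclei detected      : 30
network edges        : 81
IN profiles extracted: 810
outlier profiles     : 220
iterations           : 18
raw peak             : position 50, 152.0 a.u.
compensated peak     : position 50, 196.4 a.u.
mean row SD raw      : 21.9 a.u.
mean row SD comp.    : 14.4 a.u.
```

The membrane marker was rendered at 200 a.u.: averaging the raw profiles
smears the interface ring down to 152 a.u., while the compensated mean
recovers a sharp peak of 196 a.u. exactly at internuclear position 50 — the
shared plasma membrane — with a 34 % smaller mean row SD. Rejected columns
are profiles the template cannot explain (beams grazing triple points or the
image border); they are flagged, not discarded, in the compensated map.

The same workflow is available from the shell:

```bash
profilecomp simulate --out sim/ --seed 1
profilecomp run --nuclei sim/nuclei.tif --marker sim/marker.tif --out report/
```

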