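# Methods

This note documents the models and procedures implemented in `cellseg`,
the parameters that matter, the design decisions that were genuinely open,
and what the synthetic phantom suite does and does not establish.

## Imaging model

In negative phase contrast, a transparent object of thickness *h* and
refractive index *n₂* in a medium of index *n₁* imposes a phase shift
Δφ = 2π(n₂ − n₁)h/λ, and for small Δφ the recorded intensity is
I = |exp(jπ/2) + jΔφ|² ≈ 1 + 2Δφ — linear in the phase shift, hence in the
object's thickness. An adherent cell, thickest over its nucleus and
thinning toward its margin, therefore images as a bright convex hill with a
single apex above the nucleus. Two consequences drive the whole design:

* the *gradient* of intensity points up toward the apex everywhere over the
  cell, so a curve pushed down-slope from inside will come to rest at the
  cell's edge, where the hill meets the flat background;
* the *number of intensity peaks* inside any connected bright region equals
  the number of cells in it, once peaks from bright organelles are removed.

## Boundary detection: contour expansion

A closed parametric curve **v**(s) minimizes
E = ∮ (½α|**v**_s|² + ½β|**v**_ss|² + E_ext) ds with E_ext ∝ I, i.e. the
curve prefers to be short, smooth, and to lie on dark pixels. Stationarity
gives α**v**_ss − β**v**_ssss − ∇E_ext = 0.

**Discretization.** Vertices are kept at uniform ~2 px arc-length spacing
(resampled every iteration; this prevents vertex bunching and makes the
difference stencils uniform). The internal terms assemble into the periodic
pentadiagonal matrix −αD₂ + βD₄; the semi-implicit step with viscosity γ
solves (γI − αD₂ + βD₄)·v⁺ = γ·v + F(v) per coordinate. The matrix is
circulant (each row sums to γ) and positive definite for all α, β ≥ 0,
γ > 0, so the step is unconditionally stable in the internal terms; it is
solved by FFT. The explicit image force is F = −κ∇I, bilinearly sampled at
the vertices: down-slope, hence outward on a bright cell. Vertices are
clamped to the frame; border-touching cells are segmented but flagged.

**Termination.** The monitored metric is the mean image intensity sampled
along the curve. While the curve descends the cell's hill the metric falls
steadily; on the boundary it flattens. Iteration stops once the per-step
change stays below `eps_converge` for `patience` consecutive steps, or at
`max_iter` (flagged). The mean gradient magnitude along the curve is
recorded in the trace alongside the metric.

**Parameters** (all exposed on `SnakeParams` and the CLI):

| name | default | units / meaning |
|---|---|---|
| α (`alpha`) | 0.01 | tension gain; with β, sets how much the curve resists stretching |
| β (`beta`) | 0.01 | rigidity gain; both at 0.01 let the curve reach the boundary while staying smooth |
| γ (`gamma`) | 1.0 | viscosity (inverse time step) of the semi-implicit scheme |
| κ (`kappa`) | 6.0 | image force weight on −∇I |
| `eps_converge` | 0.002 | termination band, normalized intensity units |
| `patience` | 10 | consecutive in-band steps required to stop |
| `max_iter` | 500 | iteration cap |
| `resample_spacing_px` | 2.0 | target vertex spacing |

κ deserves a comment: the termination rule and the force weight are
coupled. The metric drops per step by roughly (κ/γ)·|∇I|² near the rim, so
if κ is too small the 0.002 band swallows the drop while the curve is still
mid-rim and the expansion stops early. κ = 6 keeps the metric moving for
rim gradients down to ~0.02 intensity/px, which covers the flattest cells
the generator produces; it is deliberately not larger, since the explicit
force step κ·|∇I| must stay well under a pixel per iteration. No balloon
or pressure force is used — the intensity gradient alone drives expansion,
so the equilibrium is purely image-determined.

**Degenerate inputs.** A contour that collapses below 8 vertices or ~4 px²
raises a degenerate-contour error naming the cell. Zero gradient and zero
gains leave the contour exactly fixed. Self-intersections occasionally
produced by the discrete update are repaired by taking the largest simple
piece of the polygon (logged); the public area routine instead *rejects*
self-intersecting input, and auto-reorients clockwise input to CCW.

## Thresholding and masks

The threshold comes from the smoothed image: image mean + offset,
Otsu + offset (256-bin between-class-variance criterion), or an absolute
value; offsets quoted on the 8-bit scale are divided by 255. Foreground is
strictly `I > t`. Components are 8-connected; holes are filled (the snake
needs one outer boundary per mask); components under `min_area_px` (default
50 px ≈ 22 µm²) are dropped as debris. Labels are ordered by descending
area with row-major tie-breaks, so the whole pipeline is deterministic.
Thresholding, peak detection and the snake's gradient field all use the
*same* smoothed image, which keeps masks and peaks mutually consistent.
Frames whose intensity spread is below `min_contrast` (default 0.02) are
declared blank — mean- and Otsu-style thresholds are meaningless at the
noise floor, where they would otherwise mark half the pixels.

## Clump splitting

Peaks are 8-connected regional maxima of the smoothed intensity restricted
to foreground; a plateau contributes one peak at its centroid; maxima below
the threshold are discarded. Peaks are ordered by the scan position of the
plateau, making all tie-breaks reproducible. A mask with one peak is one
cell; with k ≥ 2 peaks, each pixel goes to its Euclidean-nearest peak (ties
to the lowest peak index). If a sub-area ends up disconnected from its own
peak — possible in bent clumps — the connected part containing the peak is
kept and orphans are re-assigned by geodesic flooding inside the mask
(logged). Each sub-area boundary is then expanded independently; the
expansion corrects modest errors of the straight division because each
curve settles on the true intensity valley between cells. Overlaps between
expanded neighbours are resolved at rasterization by the nearest-peak rule
(ties to the lower cell id). A mask with *zero* peaks is kept as a single
cell and flagged.

The smoothing width σ (default 3 px) is the one parameter that must be
matched to the data: it has to exceed the organelle speckle scale (2–5 px)
without blurring away the intensity valley between touching cells (peaks
closer than ~2σ merge). The full-field benchmark runs at σ = 5 because its
scenes combine pronounced speckles with cells as flat as 2 µm; everyday
use of the default σ = 3 suits moderately speckled cells, and the
regional-maxima count is monotonically non-increasing in σ, so widening the
blur is always the safe direction for counting.

## Baselines

*Watershed*: Euclidean distance transform of the foreground, negated,
flooded from all its regional minima — deliberately without h-minima
suppression, because the point of the baseline is its failure mode: basin
count is driven by mask shape, so bumpy clump outlines fragment. An
optional `h_minima` depth exists but defaults off. *Region-based active
contour*: the two-phase piecewise-constant (morphological Chan–Vese)
formulation from scikit-image, brighter phase taken as foreground, with a
minimum phase-contrast guard for blank frames. Like plain thresholding it
is a global criterion and under-reaches the true boundary, which is what
the area comparison quantifies.

## Evaluation

Counting follows the over/under/false taxonomy: each prediction is
attributed to the truth object it overlaps most and vice versa; a truth
object claimed by m ≥ 2 predictions contributes m − 1 over-segmentation
events, a prediction claiming m ≥ 2 truth objects m − 1 under-segmentation
events; predictions overlapping no truth at all are false detections;
mutually-best pairs with IoU ≥ 0.5 are matches. The construction is
exactly self-dual: swapping the roles of the maps swaps the over- and
under-segmentation counts. The IoU floor applies only to match counting,
not to event counting, and is a disclosed surrogate for by-eye judgment.

## Synthetic scenes: what they emulate, and what they do not

Cells are elliptical domes realized through the optics model above.
The default body profile is parabolic, h = H(1 − ρ²) in normalized
elliptical radius ρ — a spread adherent cell whose periphery thins
gradually, so low thresholds genuinely under-segment the rim (the premise
of the contour-expansion comparison) while the rim still rises above the
noise floor, keeping the ground truth optically meaningful. A Gaussian
nucleus bump (+35% apex thickness over a ρ < 0.25 core) makes the apex a
single sharp peak above the nucleus. Spherical-cap, cosine-dome and
Gaussian-dome profiles are available for sensitivity work: the cap's steep
rim is fully captured by even low thresholds, and the cosine dome's
zero-slope rim is optically invisible — both useful as extreme cases, and
the reason neither is the default.

Scene ingredients and defaults: n₂ − n₁ = 0.03, λ = 0.55 µm, apex heights
2–6 µm, background level 0.15, intensity scale 0.165 (a 4 µm apex sits near
0.6), additive Gaussian noise σ = 0.01, organelle speckles (Gaussian bumps,
radius 2 px, ~0.12–0.18 amplitude, 3 per cell), and cell-free debris blobs.
Heights of touching cells combine by pointwise maximum — contacting, not
stacked — so apexes stay distinct, and the ground-truth label of an
overlapped pixel is the locally taller cell. Field scenes follow the
target imaging regime: 120–150 cells per 1344 × 1024 frame, 12–20%
coverage, ~15% of cells placed in contact, apex separation ≥ 16 px. All
randomness flows from one numpy PCG64 generator per scene seed;
regeneration is bit-identical.

Not emulated: diffraction halos and shade-off artifacts of real phase
optics, uneven illumination, intensity reversal of very tall (mitotic)
cells in *positive* phase contrast, cell-to-cell texture, motion blur.
Passing the phantom suite therefore shows the algorithmic claims —
expansion to an energy equilibrium, peak-count cell detection, the
watershed failure mode, the error taxonomy — under the stated optics
model; it does not certify performance on any particular microscope's
images, where σ, offsets and `min_area_px` need per-dataset choices.

## Benchmark studies and problem sizes

The studies in `cellseg.benchmarks` (run by the test suite and
`scripts/acceptance.py`) use: a 96 × 96 radial phantom for the
snake-behavior studies (energy-oracle agreement on a 10–35 px radius grid
at 0.25 px step; convergence-rule behavior; gain ordering; seeding-
threshold robustness); 100 speckled single-cell scenes; 102 clump scenes
cycling k ∈ {2, 3, 4}; 100 irregular 4-cell clumps for the watershed
comparison; one 50-cell isolated field for the per-method area comparison;
and 20 full 1344 × 1024 fields (~2,700 cells pooled) for the error-rate
benchmark. On one CPU the whole suite takes a few minutes.

One nuance made explicit: the energy-oracle study runs the snake at
α = β = 0.1 with a 10⁻⁴ termination band, because it checks the
*stationarity condition* of the discretized Euler–Lagrange equation, and
the production 0.002/10 rule intentionally cuts the final slow crawl along
near-flat tails (that rule's behavior is a separate study). The oracle
evaluates the discrete energy on the same fixed vertex grid the snake ended
with; letting the vertex count vary with the candidate radius would add a
vertex-count penalty that is not part of the curve's equilibrium.

## Known limitations

* Sharp protrusions (filopodia, tails) are rounded off by the internal
  energy — inherent to small but nonzero α, β.
* Cells whose apexes sit closer than ~2σ merge into one detected peak
  (under-segmentation); elongated cells with two comparable intensity
  lobes can split (over-segmentation).
* The nearest-peak division line is straight; expansion corrects it only
  within the reach of the intensity valley between cells.
* Debris of cell-like size and brightness is detected as a cell by design;
  only the minimum-area filter guards against small debris.
* The termination rule measures image values, not geometry; on extremely
  low-contrast cells (rim gradient ≲ 0.01 intensity/px at κ = 6) it can
  still stop short of the boundary.
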