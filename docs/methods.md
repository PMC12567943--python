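# Methods

`wiretrace` recovers ordered curves describing thin wire-like structures
from noisy grayscale images. This note records the models, the parameter
choices, the numerical conventions, and what the synthetic experiments do
and do not demonstrate.

## Coarse-to-fine segmentation

**Model.** An encoder maps the image to a stride-`z` feature grid
(`z = 16`); a 1×1 head `w0` (C→1) classifies each z×z patch (coarse logits
`s0`), a 1×1 head `w1` (C→z²) emits per-patch pixel logits that are tiled
row-major into the full-resolution map `s`. The output keeps `s` only where
the coarse cell is positive. The assumption behind the design: for objects
occupying ~0.3% of pixels, patch-level classification generalizes from far
less data than dense prediction, so the coarse branch both speeds up and
regularizes the fine one. There is no decoder and there are no skip
connections; everything downstream of the encoder is linear per cell.

**Built-in encoder.** The reference backbone for this architecture at full
scale is a large pretrained CNN; here the built-in encoder is a desk-scale
hybrid sized for CPU training (~1.4M parameters):

- a learned two-layer ReLU MLP over the (3z)² = 48×48 intensity window
  centered on each cell (reflect padding, per-image standardization),
  512 hidden units → 256 context channels;
- two fixed per-cell channels of the cell's own 16×16 patch: Gaussian
  smoothed intensity (σ = 1) and a difference-of-Gaussians map
  (σ = 3 minus σ = 1, gain 4), 2·z² = 512 channels.

The learned part answers "is there a wire in this neighborhood and roughly
where"; the fixed channels hand the fine head pixel-accurate local-contrast
evidence, which keeps the predicted band free of speckle holes — without
them the skeleton of the predicted band shatters into dozens of tiny chains.
Any object with the `(z, C, forward)` contract can replace this encoder;
the architecture itself only requires the stride and channel count.

**Losses.** Coarse part: soft Dice (sigmoid sharpness `alpha = 50`, ε = 1e-6
on the denominator for empty-foreground batches) + class-balanced BCE
(mean over positives + mean over negatives; an empty class contributes 0).
Fine part: same Dice + BCE, or the Lorenz loss `log(1 + relu(1 ∓ s)²)`,
a margin loss that saturates on large errors and so tolerates annotation
noise on 1-px targets. The fine part — both terms — is evaluated only
inside the upscaled coarse-positive region `M(y0)`: restricting it is what
the masking consistency of the architecture implies, and it raises the
foreground fraction from ~0.3% of the image to a few percent of the scored
pixels. The printed soft-Dice expression is the coefficient (maximal when
correct); the implemented loss is one minus it so that minimization is
correct.

**Training.** SGD with momentum 0.9, weight decay 3e-5, batch 8, 20 epochs,
learning rate decaying linearly from 0.03 to 0; augmentation: horizontal
and vertical flips, rotations up to 15°, translations up to 4 px. The rate
was selected from a coarse sweep at mid scale: 0.01 under-trains this MLP
within 20 epochs, 0.1 diverges, and 0.05 is unstable for some
initializations; 0.03 converges reliably across seeds. Binarization of the
fine logits is at 0 (probability 0.5). Gradients are hand-derived per loss
and verified against finite differences in the test suite.

## Curve extraction

The mask is thinned (scikit-image `thin`; `skeletonize` and `medial_axis`
are options) and curves are extracted from the 8-neighbor graph of the
skeleton as maximal chains through degree-2 nodes: seed at a degree-2
pixel, grow both ways while the frontier has degree 2 and an unvisited
neighbor, emit, remove the chain's pixels, repeat. Conventions fixed here
(the procedure itself leaves them open): row-major scan order for seeds and
neighbor tie-breaks; degrees are recomputed on the updated graph after each
removal, so a junction pixel is claimed by the first chain to reach it; a
frontier whose neighbors are all already in the chain (a closed loop) ends
the growth. Isolated pixels and 2-pixel components have no degree-2 seed
and are never extracted. Coordinates are 0-based (row, col).

## Perceptual grouping

Endpoint models: PCA over the first/last `npts = 10` points of each curve
(all points if shorter); direction = first principal axis, flipped to point
outward (toward the terminal point); a window of identical points has no
direction and is excluded via the sentinel. Endpoints are indexed 2i
(start) / 2i+1 (end), 0-based.

Continuation cost between endpoints i, j: with `l = ‖vj − vi‖`,
`ux = (vj − vi)/l`, `uy = rot90(ux) = (−ux_y, ux_x)`, the gates require
`1 ≤ l ≤ dmax`, `di·ux > ρ`, `dj·ux < −ρ` (ρ = 0.7 ≈ cos 45°); failing
pairs, the diagonal, and same-curve pairs get the sentinel cost 1e5
(same-curve masking prevents self-loops, which the merge step cannot
represent). Slopes `s1 = di·uy`, `s2 = −dj·uy` parameterize the cubic
`f(x) = ax + bx² + cx³` with the closed form
`(a, b, c) = (s1, −(2s1+s2)/l, (s1+s2)/l²)` (unique solution of the four
interpolation constraints), and the cost is the exact bending-energy
integral `4b²l + 12bcl² + 12c²l³`. The slopes are used as printed rather
than divided by the x-components; the gates keep those components above ρ,
so the small-slope approximation is controlled. The cost is symmetric.

Alternative measure: Bhattacharyya distance between PPCA endpoint Gaussians
`Σi = λi di diᵀ + σ²I₂` (first singular value λi, isotropic noise
`σ² = 10`), with the same gates applied.

Matching: `scipy.optimize.linear_sum_assignment` minimizes
`Σ M[i, σi]`; matches with cost > τ are voided; only mutual pairs
(`σ(σ(i)) = i`) survive, yielding an involutive partial matching. Merging
walks from each free endpoint, appending a curve forward when entered at
its start and reversed when entered at its end. Mutual validation does not
preclude closed rings of ≥ 2 curves; a ring's costliest link is broken with
a warning. The loop (models → costs → assignment → validation → merge) runs
`nit = 3` times, recomputing endpoint models on merged curves, and stops
early when an iteration merges nothing. Merged curves keep only original
points; straight-segment bridging of the merge seams is an option of the
rasterizer (off by default), since bridging changes recall only marginally
and invents pixels that were never observed.

Defaults: `nit = 3, npts = 10, dmax = 40 px, ρ = 0.7, τ = 10, lmin = 0,
sentinel = 1e5` — the reference setting of the method, which its ablations
show to be flat over wide ranges. `τ` must stay below the sentinel.

## Evaluation measures

Exact-overlap Dice/IOU collapse on 1-px structures (a global 1-px shift
scores 0), so the primary measures are distance-tolerant: precision = % of
predicted pixels with a true pixel within `tol` (default 3 px, Euclidean,
exact distance transform), recall symmetric, F1 harmonic. AHD = mean of the
two directed average nearest-neighbor distances; undefined (and skipped,
with a count) when either mask is empty. Localization scoring thins the
ground-truth mask first (idempotent on 1-px annotations) and rasterizes the
predicted curves; `avg_curves` counts predicted curves per image. Both-empty
masks score Dice = IOU = 1 (nothing to find, nothing found — logged
convention). Metrics are computed per image and then averaged across a test
set.

## Synthetic scenes

The generator emulates the statistics the pipeline targets rather than the
physics of X-ray formation: smooth random curves (cubic splines through
4–8 jittered control points, rasterized to 8-connected chains, ≥ 100 px,
direction change ≤ 45° per 10-px window — the regime the grouping gates
assume), dilated to 1–5 px width, darkened by `contrast` on a low-frequency
background around mid-gray, i.i.d. Gaussian noise, Poisson-placed invisible
gap segments (non-overlapping, so gaps never chain), optional blob clutter.
Defaults: 512×512, one curve of width 3, contrast 0.3, noise σ 0.08, one
expected 5–20 px gap per curve — foreground a few tenths of a percent,
mirroring the clinical class imbalance. Identical seeds give bit-identical
scenes.

What passing on these scenes shows: the architecture trains end-to-end, the
gating/extraction/grouping mathematics is correct, and the pipeline
direction (grouping reduces fragment counts toward the true curve count)
holds. What it does not show: performance on clinical fluoroscopy, whose
backgrounds contain anatomy and other instruments, whose noise is not
Gaussian or stationary, and whose wires vary in contrast along their
length.

## Scaled-down experiments

The reference experiment (tests and `scripts/acceptance.py`) trains the
built-in encoder on 200 synthetic 256×256 scenes for 20 epochs and
evaluates 50 held-out scenes — sizes chosen so the whole run fits in a few
CPU-minutes. Localization there applies cleanup with `lmin = 40 px` (the
cleanup length used in the method's own ablations): the desk-scale
segmentation leaves a few 3–6 px junction stubs that a full-scale backbone
would not produce, and cleanup is the pipeline stage designed to remove
them. Typical results: segmentation F1(3px) ≈ 98, localization F1(3px) ≈
97, curves per image ≈ 2.7 (raw extraction) → 1.3 (grouping) → 1.0
(cleanup) against a ground truth of 1.0.

## Known limitations

- The numpy trainer is single-process and CPU-bound; it is sized for the
  synthetic regime, not for clinical-resolution datasets.
- The hybrid encoder's fixed channels assume dark-on-light wires at widths
  of a few pixels; other polarities/scales need the gains and sigmas
  adjusted.
- Grouping considers endpoint pairs only; it cannot split a chain that
  thinning routed through the wrong branch of a junction.
- Curves crossing each other produce junctions whose ownership is
  scan-order dependent (deterministic, but one of several valid readings).
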