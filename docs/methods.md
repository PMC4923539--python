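# Methods

## The comparison the package implements

Two finite-element models of the same implanted bone segment are built on a
common voxel lattice and solved under one load case. The *refined* model
resolves the trabecular microstructure of the cancellous interior; the
*simplified* model replaces that interior with a homogeneous cancellous
block, the standard practice when only conventional-CT-resolution imaging
(≈0.2–0.25 mm voxels, too coarse to resolve trabeculae) is available. The
quantity of interest is the distribution of stress and strain over the
implant-bone interface, summarized per model and compared as percent
changes. Because both models derive from one ground truth on one lattice,
differences are attributable to the treatment of microstructure, not to
registration error or element size. (A `solve_on_cbct_lattice` flag instead
solves the simplified model on the coarse lattice, reproducing the
confound a literal micro-CT-vs-CBCT comparison carries.)

## Synthetic specimens

Real scans of implanted bone are animal- and scanner-specific and not
distributable, so the pipeline's inputs are synthesized by a first-class,
tested generator.

**Geometry.** A rectangular bone segment with a cortical shell of uniform
thickness on all faces and a trabecular interior. The trabecular phase is a
thresholded, anisotropically smoothed Gaussian random field: white noise is
smoothed with per-axis σ = (correlation length)/(2·voxel) × anisotropy, and
the threshold is the quantile realizing the target BV/TV. After
connectivity cleanup (trabecular islands not 6-connected to the shell are
relabeled marrow) the threshold is re-adjusted by feedback until realized
BV/TV is within ±0.01 of target. This stochastic model reproduces the
rod-like-struts-with-rounded-voids morphology of mandibular cancellous bone
at controllable BV/TV and feature size; it does not reproduce plate-like
trabeculae, cortical porosity, or the load-adapted (remodeled) architecture
around a healed implant.

**Implants.** Threaded cylinders (defaults Ø4.1 mm × 8 mm, the regular-neck
dimensions of the implants the study design targets), voxelized by
center-inclusion. The thread is modeled as rectangular annular rings (pitch
0.8 mm, depth 0.3 mm, ring width = half pitch) rather than a helix: rings
are voxel-friendly and preserve the mechanical role of threads (local
interdigitation); helical lead angle effects are ignored. Implant voxels
overwrite any tissue label (the surgical osteotomy).

**Default lattice.** 0.25 mm voxels over a 14 × 6 × 10 mm segment
(56 × 24 × 40), cortical thickness 0.75 mm, BV/TV 0.30, correlation length
0.75 mm, mild vertical anisotropy (1, 1, 1.5), two implants 4 mm apart
edge-to-edge with tops flush with the superior face. The domain is sized by
the geometry it must contain — two Ø4.1 mm implants, their separation and a
lateral bone margin — and the lattice pitch is chosen so that a full paired
comparison (two ~150 k-DOF solves) completes in about half a minute,
letting the multi-seed comparisons run as ordinary tests. BV/TV 0.30 and
strut spacing ~0.75 mm are plausible mandibular values; no measured
morphometry for this anatomy was available to calibrate against, and the
generator exposes all of these as parameters. Metadata carries physical
spacing, so literal 18 µm lattices are a config choice for users with
patience.

**Scanner emulation.** Per-label base intensities (background 20, bone 100,
implant 230, arbitrary units, chosen so the three classes are separable by
discriminant thresholding in the noiseless limit) → multiplicative metal
artifact → Gaussian blur → additive Gaussian noise → (CBCT only)
block-averaging to the output pitch. The metal artifact multiplies bone
intensity by (1 − a·w(x)) where w is, for each implant pair, a radial
Gaussian in the transverse plane equal to 1 on the pair midline (σ = half
the center distance), constant over the implants' shared axial span with a
1 mm cosine rolloff below — emulating the inter-implant shading that
defeats global thresholding on metal-bearing scans. Defaults: micro-CT-like
image blur σ 0.1 mm, noise SD 8, artifact amplitude 0.5; CBCT-like image
0.5 mm voxels, blur σ 0.3 mm, noise SD 4, artifact 0.2. Block averaging
requires an integer spacing ratio (non-integer ratios are rejected rather
than interpolated) so that mean intensity is conserved exactly. No
beam-hardening physics or reconstruction artifacts beyond this shading
model are simulated.

## Segmentation

Two-stage discriminant (Otsu) thresholding assigns implant / bone /
background. Otsu's threshold is computed exhaustively over histogram levels
(exact integer levels when the data are integer with a modest range; 256
uniform bins otherwise), ties breaking toward the lower threshold. With
three classes expected, the first split separates the implant and a second
split separates bone from background on the sub-threshold residue; if the
residue splits less effectively (between-class variance fraction η) than
the upper class, the bright side carries the second split instead. When the
class count is unknown, `n_classes="auto"` accepts a third class only if
some second-stage η ≥ 0.8 — above the ~0.64–0.75 range that unimodal noise
produces — a heuristic adequate for clean images; the pipeline passes
`n_classes=3` because an implant is always in its field of view.

Graph-cut refinement solves the seeded binary labeling exactly: unaries are
negative log likelihoods from add-one-smoothed seed-intensity histograms
(64 bins), pairwise weights λ·exp(−(ΔI)²/2σ²) with λ = 2 and σ = 10
intensity units on the 6-neighborhood, seeds as infinite-cost hard
constraints, implant voxels held fixed. Defaults were calibrated once on a
held-out specimen seed; λ in [1, 4] and σ in [8, 15] perform equivalently.
The min-cut is computed with SciPy's integer max-flow; float capacities are
quantized at up to 2⁻²⁰ resolution (the scale is reduced automatically on
large volumes so the flow value stays within 32-bit range), making the
result optimal up to a quantization error bounded by (#energy terms)·2⁻²⁰ —
the enumeration tests use a 1e-4 tolerance accordingly. The interactive
seeding such tools assume is replaced by a reproducible protocol: seed
files (`i j k label` lines) or a helper that samples seeds from the ground
truth, which is how the tests emulate a user marking artifact-darkened
bone.

The pipeline segments the **raw** micro-CT-like image: at a 0.25 mm lattice
trabecular struts are 1–3 voxels wide and a median prefilter erases them
(measurably worse Dice), while the graph cut's pairwise term already
absorbs the noise. The denoising operations (median, Gaussian; reflective
borders) remain available for workflows at finer lattices. Component
cleanup removes bone components smaller than `min_voxels` (default 8) or
anchored to neither a domain face nor the implant, and implant debris
below the same size.

Cortical vs trabecular bone is *not* distinguished from intensity — the
refined model assigns both the same material anyway; the cortical label
exists only in ground truth and the homogenized model.

## Finite elements

One 8-node hexahedral element per foreground voxel, corner nodes
deduplicated exactly on the shared lattice; VTK hexahedron ordering with
positive Jacobians. Because every element is the same cube, one 24×24
stiffness template per distinct material (2×2×2 Gauss quadrature, isotropic
Hooke tensor) serves the whole mesh. The bonded interface is node sharing —
100% osseointegration, no contact or friction.

Boundary conditions: all nodes on the two faces normal to the specimen's
long (mesiodistal) axis are fixed in all directions; each implant's
most-superior exposed face nodes carry the axial load, split equally within
an implant. The default gives each implant the full 50 N
(`load_per_implant=False` divides it instead); no abutment or crown is
modeled.

Constrained DOFs are eliminated by reduction (not penalties), keeping the
reduced matrix well-conditioned and reactions exactly recoverable as
K u − f. The SPD system is solved by Jacobi-preconditioned CG to relative
residual 1e-8 (default; results move by <0.1% tightening to 1e-10), with a
dense direct path retained for oracle comparisons. Meshes are pre-checked
for connected components containing no constrained node (reported as a
rigid-mode error naming an offending node). Units are mm / N / MPa.

## Post-processing conventions

Strain is evaluated at each element centroid from trilinear shape-function
gradients; stress follows per-element Hooke's law. "Equivalent stress" is
von Mises √(3/2 s:s); "equivalent strain" the deviatoric analogue
√(2/3 e:e) — a total-strain convention would rescale but not reorder
comparisons at fixed ν. Tensile and compressive measures are the first and
(sign-flipped) third principal values clamped at zero, so all six measures
are non-negative, matching how such results are reported. Interface
statistics are taken over bone elements sharing a face with an implant
element — element-wise at centroids, never nodally averaged, so the census
is unambiguous — and implant elements are excluded.

## Reproducibility

All randomness flows from explicit seeds; the pipeline derives stage seeds
from one master seed by fixed offsets (stage seed = 10·master + offset) and
records SHA-256 digests of every intermediate array in a run manifest.
Identical configs reproduce byte-identical summaries and digests.

## Problem sizes used by the test suite and acceptance script

Five paired comparisons on the default 56×24×40 specimen (~40 k elements,
~150 k DOF each branch, ~1100/650 CG iterations), one solid-limit pair and
two determinism runs on a 16×12×20 single-implant specimen, mechanics
verification on ≤100-node meshes, 50 Otsu-oracle images at 10³ voxels, and
100 graph-cut enumeration instances with ≤16 free voxels.

## Known limitations

Linear elasticity only (no damage, plasticity or remodeling); isotropic
tissue properties; idealized ring threads and perfect osseointegration;
the stochastic trabecular model is stationary (no peri-implant
densification); the scanner model omits beam hardening and reconstruction
artifacts; percent changes depend on the chosen BV/TV, materials and
lattice, so only their directions and orders of magnitude — not specific
values — generalize.
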