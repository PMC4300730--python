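# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `jforce`, in the order the pipeline runs them.

## Units and conventions

Lengths in µm, tractions/stresses in Pa (= pN/µm²), forces in pN,
energies in aJ (= pN·µm), 2-D plate stress in pN/µm. With these units
the Boussinesq surface displacement of a point force,
u = F(1+ν)/(πEr), carries no conversion constants. Images use 0-based
pixel indices, origin top-left, x = column, y = row; physical
coordinates are pixel index × `pixel_size` (default 0.16 µm/px).
Every interface polyline is stored with the convention that `cell_a`
lies on the left of the traversal direction, which makes the
label-to-cell mapping recoverable from the interface file alone.

## Substrate model and traction reconstruction

The gel is an isotropic, linear elastic, infinite half-space
(E ≈ 8–35 kPa, ν = 0.5). The forward map from traction to surface
displacement is a convolution with the Boussinesq tensor

    G_ij(r) = (1+ν)/(πE r³) [ (1−ν) r² δ_ij + ν r_i r_j ].

**Discrete forward operator.** Each kernel entry is the *exact* integral
of G over one square grid cell, evaluated from the closed-form
antiderivatives ∫∫x²/r³ = y·ln(x+r), ∫∫y²/r³ = x·ln(y+r),
∫∫xy/r³ = −r at the four cell corners. This renders the singular
self-cell (a convergent improper integral) and the strongly curved
near-field cells without quadrature error; the convolution is evaluated
by FFT on a grid zero-padded ×2 per axis to suppress wrap-around of the
long-ranged kernel. An independent Gauss–Legendre quadrature of G
verifies the kernel in the test suite.

**Bead tracking.** Beads are detected as intensity maxima in the
unstrained reference frame. A square template (default 21 px ≈ 3.4 µm,
within the conventional 15–25 px range) is matched within ±16 px by
maximizing the normalized cross-correlation; matches whose primary peak
is less than `significance_ratio` (default 1.5) times the secondary peak
(outside a 4-px exclusion zone) are rejected as insignificant matches;
the particular ratio test is this package's choice of rejection rule.
Sub-pixel refinement maximizes the correlation of the
template against the cubic-interpolated deformed window (Nelder–Mead,
0.02 px tolerance); unlike 3-point vertex fits this is unbiased by
neighbouring beads and returns exactly zero displacement on identical
images (measured accuracy ≈ 0.01 px on rendered spot images).

**FTTC.** Scattered displacements are linearly interpolated onto a
square grid (nearest-neighbour extrapolation at the margins) and
inverted per Fourier mode with zero-order Tikhonov regularization,
T̂ = (Ĝₙᴴ Ĝₙ + λ²I)⁻¹ Ĝₙᴴ û / s_max, where Ĝₙ = Ĝ/s_max is the
analytic Fourier Boussinesq tensor normalized by its largest singular
value s_max = 2(1+ν)/(E k_min). This makes λ² a dimensionless
regularization strength comparable across grids and substrates;
`lambda2_from_legacy` maps values quoted for the raw (Pa, µm) operator —
historically 5×10⁻⁸ to 10⁻⁶ — to this scale (λ²_norm = λ²_raw/s_max²,
of order 10⁻³ for typical geometries). The k = 0 mode is zeroed (no net
force). Round-trip accuracy on band-limited fields supported in the
central half of the grid is ~0.5% relative L2; the residual error is
dominated by zero-padding truncation of the long-ranged displacement,
which is why round-trip checks exclude the outer quarter margin.

## Segmentation

The tight cluster mask comes from the junction-marker channel: Gaussian
smoothing (σ = 5 px), histogram threshold at the first minimum after the
lowest-intensity maximum (256 bins over the observed range, 3-bin moving
average before extremum detection — raw float histograms are too spiky),
largest connected component, morphological closing with a 3-px disk.
Holes larger than the closing scale remain open. The mask is dilated by
a disk (15–45 px; default 30 px) to capture tractions falling outside
the marker-based segmentation. Interfaces are inputs (hand-drawn in the
original workflow, generator-provided here); they are rasterized as cuts
— prolonged ~20 px past their endpoints so a mask that bulges past the
drawn interface is still separated — and 4-connected components become
cell footprints. Interface length is the chord sum over every 10th
pixel, skipping chords whose endpoints fall into segmentation holes.

## Force balancing on the cluster graph

f_res,i = −∫_Ωi T dA is computed as a masked grid sum. An edge is
resolvable iff it is a bridge of the junction graph; the junction force
is the symmetrized mean of the two group sums. Every edge stores the
force exerted by `cell_a` on `cell_b`; all reports derive from that one
orientation, and antisymmetry holds exactly by construction. The sign
convention follows the two-cell definition (f_i,j = f_res,i); the
symmetrized-mean identity is applied in that convention.

## Thin-plate FEM

The cluster cortex (≈1 µm thick, ≈20 µm lateral — effectively 2-D) is a
linear elastic plate loaded by the sign-inverted tractions:

    ∂σ_ik/∂x_k − T_i + κu_i = 0 in Ω (dilated mask),  σ_ik n_k = 0 on ∂Ω.

*Constitutive law.* Plane stress, σ = E(x)/(1+ν)(ε + ν/(1−ν)·tr ε·I),
with ν = 0.5 (incompressible cortex). A plane-strain-like form with a
1/(1−2ν) trace term is singular at ν = 0.5; plane stress is finite
there, standard in monolayer stress microscopy, and preserves the key
property that E cancels between loading and stress recovery: junction
forces change by < 10⁻¹⁰ relative under a 1000× change of E₀.

*Modulus field.* E = E₀ inside the tight mask, decaying as
E₀·e^(−d/λ) outside with λ = 1.6 µm, penalizing tractions by their
distance from the detected cluster edge.

*Stabilization.* κ/E₀ = 10⁻⁷ (with a 1 µm reference length) removes the
rigid-body null space so the system stays solvable when measured
tractions do not balance exactly. Because κ scales with E₀ the solution
is exactly E₀-invariant, and halving κ changes junction forces by
< 0.1% on well-balanced fields.

*Discretization.* The boundary polygon is traced from every 10th
boundary pixel; interior nodes come from a staggered (near-equilateral)
lattice at the target edge length (default 1.5 µm), boundary nodes from
arc-length resampling; Delaunay triangulation restricted to the polygon
plus a few Laplacian smoothing rounds gives minimum angles ≳ 25°.
Linear (P1) triangles; the load vector uses edge-midpoint quadrature
(markedly more accurate than nodal lumping near the cuts); element
stresses are area-averaged to nodes. Two recovery details matter for
force accuracy and are this package's own choices:

- **Boundary projection.** The weak form imposes σ·n = 0 only weakly;
  raw recovered stress leaks ~10% of a transmitted force through the
  free rim. Nodal stress at boundary nodes is therefore projected onto
  the tangential space (a free surface carries only tangential stress).
- **Separating cuts.** A junction force must integrate σ·n over a cut
  spanning the *whole* plate, including the dilated band beyond the
  drawn interface. The cut is the equidistance contour between the two
  cell groups' footprints (from distance transforms), which coincides
  with the interface inside the cluster and continues through the
  middle of the band — also in pinched geometries where a straight
  extension of the interface would slice into a third cell's territory.
  Sub-junctional *profiles* still sample the drawn interface at every
  10th pixel with normals from ±5 px central differences, oriented
  toward cell *n*; forces integrate by the trapezoidal rule and are
  additive over sub-junctional stretches.

Mesh convergence: one further uniform refinement changes junction
forces by < 2%.

## Strain energy

U_j = ½∫_Ωj T·u_j dA with u_j the forward Boussinesq map of the
traction *restricted to Ω_j*. Using the full measured displacement
would be wrong because elastic deformations are long-ranged — the
displacement under one cell contains contributions from its neighbours.
U_j ≥ 0 always (the kernel is positive semi-definite) and scales as
1/E. The implementation reuses the forward-model kernel; the test
oracle integrates G independently by Gauss–Legendre quadrature.

## Tracking and time-series analytics

Cells link frame-to-frame by a globally optimal nearest-centre
assignment with a 20 µm gate; after a division the closest daughter
continues the track and the other starts a new one. Interfaces link by
the optimal assignment over cost = proximal endpoint distance + second
endpoint distance + centre-of-mass distance ("all possible pairings" is
read as global optimality, not greedy matching). For correlation
analyses all series are bin-averaged to a 240 s frame interval and
normalized to unit variance per component. The scalar vector
correlation is the mean of the two diagonal componentwise correlations,
c(dt) = ½[corr(f1x(t+dt), f2x(t)) + corr(f1y(t+dt), f2y(t))]; positive
dt pairs f1's later samples with f2's earlier ones, so a series that
*trails* another minimizes c at negative dt. Off-diagonal components
average to zero for isotropic statistics and are available for that
check. Transmission analysis reports, per junction i of a middle cell
m, c(f_i,m, Σ_{j≠i} f_j,m) and c(f_i,m, f_res,m): a passive force
transducer gives (−1, 0), an anchored cell (0, −1).

## Stress–intensity coupling analytics

Marker images are smoothed with a plain average filter of circular
support (radius 10 px, 317 pixels) and read at every 10th interface
pixel, pairing each stress sample with an intensity sample. Pearson
correlation is computed on stress magnitudes, either per interface per
frame or pooled. The coupling length scale subdivides each junction
into segments of length Δl (junctions shorter than Δl are skipped; the
remainder fragment is complemented with neighbouring points to span
exactly Δl), permutes intensities within each segment (one seeded RNG
governs all shuffles), and reports the smallest Δl at which the median
randomized correlation falls below half the median correct one.
The intensity autocorrelation length is where the median per-junction
arc-length autocorrelation first drops below 0.5 (linear interpolation
between sample lags). Short junctions bias this estimator low — with a
~40 µm junction and a 10 µm correlation length the per-junction mean
subtraction removes a large part of the low-frequency variance — so the
recovery benchmark evaluates it on long (320 µm) arcs of the same
intensity model, where the bias is negligible.

## Synthetic scenes

The generator defines the study conditions for every benchmark:

- **Geometry.** Perturbed-seed Voronoi partition of a smooth blob
  (union of per-seed disks, holes filled, lightly smoothed), polygons
  resampled at 1-px arc steps, shared interfaces identical from both
  sides. Cells are ~18 µm across (`cell_radius` 9 µm). Topology is
  enforced on the realized adjacency (trees exactly match a drawn
  random tree with degree ≤ 3; loops must contain a cycle), and
  non-adjacent cells must keep a 12 µm clearance so the dilated masks
  of unconnected cells never merge — mask bridging would create load
  paths that the graph truth does not have. Layouts are re-jittered
  until all conditions hold; everything is deterministic in the seed.
- **Traction.** Inward-pointing Gaussian patches (σ = 1.5 µm) anchored
  4 µm inside the cluster-exterior boundary every ~3 µm, amplitudes
  ~600 Pa ± 30%, smoothly windowed to vanish ~3 µm outside the cluster.
  In the default *emergent* mode each cell's amplitudes are smoothly
  polarized (a cos-modulation around the cell) so it develops a natural
  net imbalance; the global field is then projected to exactly zero net
  force and torque with distance-tapered correction fields that vanish
  at footprint boundaries (the field stays smooth across interfaces),
  and the true residuals are *measured* from the final field. Junction
  forces of tree clusters follow exactly as partition sums of those
  residuals; typical magnitudes are 25–100 nN, matching experimental
  scales. A prescribed-residual mode pins per-cell integrals to given
  values via a minimal-change amplitude adjustment; it is kept for the
  API but concentrates traction near junction ends when the prescribed
  values are unnatural for the patch layout, which real reconstructed
  fields do not show.
- **Bead images.** A seeded uniform point process (0.4 beads/µm²),
  Gaussian spots (σ = 0.3 µm), deformed frame shifts each bead by the
  bilinearly interpolated forward-model displacement; optional per-bead
  positional noise.
- **Marker images.** Background 100, cluster plateau 500, interfaces
  drawn as Gaussian-profile lines whose centreline brightness follows
  the ground-truth profile intensity.
- **Sub-junctional truth.** Stress magnitude along a junction is its
  mean transmitted stress |f|/L modulated ±50% by smooth arc noise with
  the configured correlation length; intensity = 600 + coupling·stress
  + correlated noise. `intensity_corr_length` is defined as the arc lag
  at which the autocorrelation drops to 0.5 (Gaussian kernel of
  σ = ℓ/(2√ln2)).

What the scenes do *not* emulate: image noise of real microscopy,
focal-plane drift, bead polydispersity, out-of-plane (z) tractions,
finite gel thickness, nuclei, photobleaching, or 3-D cell shape. The
benchmarks therefore measure method error under ideal imaging, not
biological variability; the noise benchmark perturbs the traction field
directly (10% multiplicative) to compare how the two force methods
degrade together.

## Benchmark sizes

The validation runs use 20 tree scenes (3–6 cells) for cross-method
consistency, 10 scenes for the noisy comparison, 10 full image-pipeline
scenes, 24 pair scenes plus 10 long arcs for the coupling analytics,
and 100 random tractions for the energy checks — sizes at which the
medians are stable across seeds while the whole suite completes in a
few minutes on one core.

## Known limitations

- P1 stress recovery limits per-junction FEM accuracy to ~1% of the
  gross transmitted stress; junctions carrying little net force show
  larger *relative* errors.
- The balance method integrates over footprints at image resolution;
  with FTTC-reconstructed tractions its error (~25–40% per junction,
  from traction smearing across footprint boundaries) exceeds the
  FEM's (~10%), which integrates through cuts and is insensitive to
  in-group smearing.
- Loop-topology junction forces from pairwise cuts satisfy per-cell
  balance but have no independent experimental cross-check, as the
  static indeterminacy argument implies.
- The histogram threshold assumes a clearly bimodal marker intensity;
  low-contrast images fall back to an Otsu split with a warning.
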