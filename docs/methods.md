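# Methods

## The sheaf construction

A protein is reduced to its C-alpha point cloud (one point per residue).
For a focal atom *A* and a radius *r*, the neighborhood is every C-alpha
within *r* Å of *A* (the neighborhood cutoff equals the filtration
radius; nothing else in the pipeline introduces a second length scale).
The alpha complex on the neighborhood keeps the simplices of its Delaunay
triangulation whose smallest empty circumscribing sphere has squared
radius at most *r*²; that squared radius is the simplex's filtration
value, and the threshold is boundary-inclusive. Simplices are truncated
at dimension 2: L₀ needs edges, L₁ needs triangles, and no feature uses
anything higher.

The sheaf assigns the stalk ℝ to every simplex. Vertex labels are
*q* = 0 for the focal atom and 1 for the others; restriction maps are
*q<sub>j</sub>*/*r<sub>ij</sub>* (vertex into edge) and
*q<sub>k</sub>*/(*r<sub>ik</sub>r<sub>jk</sub>*) (edge into triangle).
Zero labels are permitted even though the general theory asks for
nowhere-zero labels — every formula stays well-defined, and the zero
focal label is precisely what localizes the spectrum. With all labels 1,
L₀ degenerates to the graph Laplacian weighted by 1/*r<sub>ij</sub>*²
(the combinatorial Laplacian when all edges have unit length), which is
the main structural cross-check in the test suite.

Orientation is the global ascending-index convention with incidence sign
(−1)^position; spectra are orientation-invariant, and d₁d₀ = 0 holds by
the sheaf axioms (asserted numerically at 1e−10).

## The persistent pair operator

For nested complexes *X* ⊆ *Y* over the same labeled cloud the package
provides the persistent sheaf Laplacian on degree-*q* cochains of *X*:

Δ<sub>q</sub><sup>X,Y</sup> = D̃D̃ᵀ + d<sub>q−1</sub><sup>X</sup>(d<sub>q−1</sub><sup>X</sup>)ᵀ,

where D̃ is the adjoint coboundary (d<sub>q</sub><sup>Y</sup>)ᵀ of the
larger complex restricted to the degree-(q+1) cochains whose adjoint
image is supported on simplices of *X* (that image then automatically
lies in C<sup>q</sup>(X), because a face of an X-simplex is an
X-simplex). The construction was chosen, among the variants the
literature leaves open, to satisfy the kernel contract: the kernel
dimension equals the rank of the restriction-induced map
H<sup>q</sup>(Y) → H<sup>q</sup>(X) on sheaf cohomology, verified in the
test suite against an explicit cochain-level linear-algebra oracle on
random nested complexes. At *X* = *Y* the operator *is* the sheaf
Laplacian (same code path), which is the only case the feature pipeline
uses.

## Numerical conventions

- **Zero eigenvalue threshold**: λ counts as zero iff
  λ < 1e−8 · max(1, λ<sub>max</sub>). The relative form guards against
  Å-scale conditioning; an absolute override is available in
  `summarize`.
- **Eigensolvers**: dense symmetric (`eigvalsh`) throughout. Per-residue
  matrices have at most a few hundred rows; no sparse path is warranted.
- **Degenerate geometry**: exactly collinear/coplanar/cospherical inputs
  that Qhull rejects receive a deterministic jitter of 1e−6 Å seeded from
  the coordinates themselves, so reruns are bit-identical. One- and
  two-point clouds and single triangles are handled in closed form.
- **Alpha values**: a simplex's value is its squared circumradius if its
  smallest circumsphere is empty (Gabriel), else the minimum over its
  Delaunay cofaces; a final monotonization pass enforces
  face ≤ coface. An independent brute-force oracle enumerates empty
  circumscribing spheres directly (circumspheres of the simplex augmented
  by up to 4 − |simplex| points are the only possible constrained
  minima) and must agree to 1e−9 Å² on clouds of up to 10 points.
- **Boundary inclusion**: threshold alpha ≤ r² + 1e−9·max(1, r²), so a
  simplex entering exactly at r² is kept.

## Feature set

Per residue: 15 PSL spectral values (5 per radius: zero count, max, min,
mean, median-or-std of the nonzero eigenvalues); packing densities —
heavy-atom neighbor counts of the focal C-alpha in the shells d < 3 Å,
3 ≤ d < 5 Å, 5 ≤ d, each divided by the protein's total heavy-atom count
(the focal atom itself is not counted as its own neighbor); a 21-way
residue one-hot (20 standard amino acids + X for anything else); a 7-way
secondary-structure one-hot over the STRIDE classes {H, G, I, E, B, T, C}
plus φ, ψ and solvent-accessible area (the 360.0 terminus sentinel is
replaced by 0); occupancy; and the global R-value, resolution and
heavy-atom count. The secondary-structure block is 10 numeric columns;
the class set is configuration, not hard-coded, since conventions for
counting "secondary features" vary. Missing R-value/resolution stay
missing (never zero) and are imputed with the training-split mean inside
each validation split, never from test rows.

Structure input: first coordinate MODEL only; alternate locations
resolved to the highest-occupancy conformer (ties to the smallest
alt-loc id); HETATM records and hydrogens excluded; residues without a
C-alpha skipped. STRIDE is treated purely as an input format — the
program is never invoked — and a structure whose STRIDE records do not
cover every C-alpha is flagged, mirroring standard benchmark curation.

## Predictors

- **Per-protein fit**: ordinary least squares of experimental B on the 15
  features + intercept, per protein; the reported set-level number is the
  unweighted mean of per-protein Pearson correlations on the fitted
  values (the in-sample convention of the flexibility literature).
  Proteins with fewer than 17 residues fall back to a 1e−8 ridge.
- **GNM baseline**: Kirchhoff matrix with −1 contacts at 7 Å, profile =
  diagonal of the Moore–Penrose pseudoinverse (zero modes dropped at the
  spectral tolerance), calibrated to B with least-squares slope +
  intercept — the weakest calibration that defines an RMSE; the
  correlation is calibration-invariant.
- **Blind prediction**: scikit-learn gradient boosting
  (n_estimators 1000, max_depth 7, min_samples_split 5, subsample 0.8,
  learning_rate 0.002) and random forest (n_estimators 1000, max_depth 8,
  min_samples_split 4, max_features "sqrt", min_samples_leaf 1) defaults,
  user-overridable. Leave-one-protein-out and protein-level k-fold score
  each test protein separately, then average over proteins and over
  seeds; atom-level k-fold scores each fold's pooled predictions (the
  pooled-over-everything correlation is reported alongside). The
  exclusion list of 18 PDB identifiers used to curate the 346-protein
  blind benchmark ships as package data.

## The synthetic generator

The generator emulates what the pipeline assumes about real data:
C-alpha traces at ~3.8 Å spacing (ideal alpha-helix with 1.5 Å rise,
2.3 Å radius, 100°/residue; a self-avoiding random-walk coil with 3 Å
minimum separation; a gently curved chain that is never exactly
degenerate), a heavy-atom environment of 4 atoms per residue at bonded
distances, per-residue B-factors **exactly linear** in the 15 L₀ PSL
features plus Gaussian noise, and STRIDE-like records aligned 1:1 with
the chain. Everything is deterministic per seed.

Because the targets are generated from the package's own feature map,
recovery tests are sharp — at zero noise the per-protein fit must return
PCC = 1 to 1e−9 — but a high PSL-vs-GNM margin on such data is partly
circular. A GNM-profile-based target generator is therefore included and
the acceptance script reports the comparison both ways. What passing
synthetic tests do *not* show: performance on real crystallographic
noise, side-chain packing, multi-chain contacts, or B-factor
heterogeneity across crystal forms; those require real structures via
`scripts/reproduce_benchmark.py`.

For the blind-prediction studies the generator adds per-protein
coefficient jitter and intercept shifts plus per-protein metadata
(R-value, resolution, size). This creates the within-protein target
structure that real proteins have, and reproduces the known leakage
ordering: atom-level cross-validation, whose test rows share proteins
with training rows, scores far above protein-level cross-validation on
identical data. The gap is a property of the protocols, not of any model.

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data: 8–10 proteins of 25–40 residues for the regression and
cross-validation studies, 100-seed families of ≤10-point clouds for the
geometric/spectral property checks, and scaled-down ensembles
(60–150 trees, depth 3–4, learning rate 0.1–0.15) for the
cross-validation studies. These sizes were chosen so that every estimate
is well-resolved while a full run stays within a few CPU-minutes; the
full published hyperparameters remain the defaults of `ModelConfig` and
are exercised by `scripts/reproduce_benchmark.py` on real data.

## Known limitations

- mmCIF input, biological-assembly expansion and hydrogen handling are
  out of scope; PDB-format files only.
- Sheaf Laplacians above degree 1 (tetrahedra and beyond) are not built.
- The pair operator beyond *X* = *Y* is exercised by tests, not by the
  feature pipeline; alternative conventions for it differ only there.
- The per-protein regression is in-sample by design (a literature
  convention); blind generalization is measured by the cross-validated
  predictors, whose protein-level numbers are the honest ones.
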