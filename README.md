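# pslflex

Protein flexibility analysis with **persistent sheaf Laplacians (PSL)**:
per-residue spectral features on alpha-complex filtrations of C-alpha point
clouds, per-protein B-factor regression, a Gaussian network model (GNM)
baseline, and blind machine-learning B-factor prediction.

## Who this is for

Structural bioinformaticians and method developers who want a localized,
multiscale topological descriptor of protein structure. The prediction
target is the crystallographic B-factor (Debye–Waller factor, Å²), which
quantifies the mean-square thermal displacement of each atom and is the
standard proxy for per-residue flexibility. Only C-alpha atoms carry the
topology; heavy atoms contribute packing densities; STRIDE output files
(read, never invoked) contribute secondary-structure features.

## The model

For a focal C-alpha atom *A*, collect the C-alpha atoms within a cutoff,
build the **alpha complex** at a filtration radius *r* (a simplex enters
at the squared radius of its smallest empty circumscribing sphere), and
put a **cellular sheaf** on it: every simplex carries a one-dimensional
stalk, each vertex *v<sub>i</sub>* a label *q<sub>i</sub>* (0 for the focal
atom, 1 for its neighbors), and the restriction maps are the scalars

- *F*<sub>v<sub>i</sub> ≤ v<sub>i</sub>v<sub>j</sub></sub> = *q<sub>j</sub>* / *r<sub>ij</sub>*,
- *F*<sub>v<sub>i</sub>v<sub>j</sub> ≤ v<sub>i</sub>v<sub>j</sub>v<sub>k</sub></sub> = *q<sub>k</sub>* / (*r<sub>ik</sub>* · *r<sub>jk</sub>*),

with *r<sub>ij</sub>* the Euclidean edge length. The coboundary matrices
d₀, d₁ give the sheaf Laplacians **L₀ = d₀ᵀd₀** and
**L₁ = d₁ᵀd₁ + d₀d₀ᵀ**. Because the focal label is 0, the spectrum is
localized at *A*: harmonic (zero) eigenvalues count topology, nonzero
eigenvalues carry local geometry. For each radius the features are the
zero-eigenvalue count plus the maximum, minimum, mean, and a fourth
statistic (median or standard deviation) of the nonzero spectrum — five
numbers per radius, fifteen per residue over three radii.

Two presets mirror the two prediction pipelines:

| preset | Laplacian | radii (Å) | 5th statistic | used by |
|---|---|---|---|---|
| `PslConfig.regression()` | L₀ | 6, 9, 12 | median | per-protein OLS fit |
| `PslConfig.blind()` | L₁ | 7, 10, 13 | std | blind GBDT/RF prediction |

The pair operator for nested complexes *X* ⊆ *Y* (the persistent sheaf
Laplacian) is also provided; its kernel dimension equals the rank of the
restriction map on sheaf cohomology H<sup>q</sup>(Y) → H<sup>q</sup>(X),
and it reduces exactly to the sheaf Laplacian at *X* = *Y*.

Baselines and predictors: per-protein ordinary least squares of the
experimental B-factors on the 15 PSL features (reported as the Pearson
correlation, averaged over proteins); the classical GNM at a 7 Å cutoff
(flexibility profile = diagonal of the pseudoinverse of the contact
Kirchhoff matrix); and blind gradient-boosted / random-forest regression
over PSL + packing + sequence + secondary-structure + global features with
leave-one-protein-out, protein-level 10-fold, and C-alpha-level 10-fold
validation.

## Worked example

```python
import pslflex as pf

# a 40-residue synthetic coil whose B-factors are exactly linear in the
# L0 PSL features (the generator's ground truth), no noise
protein = pf.synth_structure(
    pf.SyntheticSpec(n_residues=40, geometry="coil", noise_sigma=0.0, seed=11)
)
print(protein.features[0][:5])          # first residue, radius-6 block
fit = pf.fit_protein(protein.features, protein.structure.b_factors)
print(f"PSL per-protein PCC: {fit.pcc:.4f}   RMSE: {fit.rmse:.4f}")
gnm = pf.gnm_bfactors(protein.structure, cutoff=7.0)
print(f"GNM PCC: {gnm.pcc:.4f}   RMSE: {gnm.rmse:.4f}")
```

prints

```
[1.     0.0693 0.0693 0.0693 0.0693]
PSL per-protein PCC: 1.0000   RMSE: 0.0000
GNM PCC: 0.0956   RMSE: 2.8010
```

The radius-6 block reads: one connected component (one zero eigenvalue of
L₀) and a single nonzero eigenvalue 0.0693, so max = min = mean = median.
The linear fit recovers the generative model exactly (PCC 1, RMSE 0),
while the GNM — blind to the generative feature map — correlates weakly
on this target.

The same pipeline runs from the shell:

```sh
pslflex synth --n-residues 40 --geometry coil --seed 11 -o out/
pslflex featurize --pdb out/synthetic.pdb --stride out/synthetic.stride \
    --order 0 --radii 6,9,12 --stat median -o out/features.csv
pslflex fit --features out/features.csv
pslflex gnm --pdb out/synthetic.pdb --cutoff 7
```

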