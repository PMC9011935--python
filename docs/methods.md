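# Methods

This note documents the models, the numerical conventions, and the design
choices made where more than one defensible option existed. It describes
what the code computes; every empirical statement here is one the test
suite or `scripts/acceptance.py` computes itself.

## Featurization

A molecule is treated as a graph of heavy atoms; hydrogens remain implicit
and enter only through the per-atom "number of bonded hydrogens" attribute
(explicit H atoms in input SMILES are folded into those counts during
parsing). Each atom contributes a 145-wide row of blocks, in fixed order:
atom type (one-hot over atomic number, 118), degree (6), formal charge (5),
chirality (4), hydrogen count (5), hybridization (5), aromaticity (1), and
atomic mass divided by 100 (1). Each bond contributes a 12-wide row: bond
type (4: single/double/triple/aromatic), conjugation (1), ring membership
(1), stereochemistry (6). Dividing the mass by 100 puts the only
non-categorical atomic entry on the same order of magnitude as the one-hot
bits, so the local block needs no further normalization.

Conventions that the encoding fixes (the block contents alone do not
determine an order, and real libraries contain out-of-range values):

* formal-charge bins are (−2, −1, 0, +1, +2); chirality order is
  (unspecified, tetrahedral CW, tetrahedral CCW, other);
* out-of-range categories — degree > 5, exotic charges, unusual
  hybridizations, exotic bond orders — clamp to the last slot of their
  block, keeping the widths fixed without an extra "other" column;
* dummy atoms (atomic number 0) clamp into the first atom-type slot.

Global descriptors are the full RDKit collection (210 in the pinned RDKit;
the exact count is toolkit-version dependent and is recorded in the run
metadata). A descriptor returning NaN/Inf for a molecule is logged and
imputed to 0 before z-scoring; silent propagation of non-finite values
would poison the dataset-level PCA.

## Local-feature aggregation

Atom and bond matrices vary in size across molecules, so they are reduced
to a fixed-length vector by per-molecule PCA: the matrix is transposed
(rows = the fixed 145- or 12-long feature axis, columns = atoms or bonds),
each column is centered, and the rows are projected onto the first
principal component of the column covariance. This is the only orientation
that yields a length-145/12 output regardless of the molecule's size.
Numerical conventions:

* **Sign.** A principal component's sign is arbitrary; we flip it so the
  loading with the largest absolute value is positive, making vectors
  comparable across runs.
* **Centering only.** Variables are centered but not scaled — the features
  are already one-hot or mass/100.
* **Degenerate cases.** One column (a 1-atom or 1-bond molecule) reduces to
  centering; a matrix with zero total variance yields the zero vector; a
  molecule without bonds contributes a zero bond part. The fixture
  generator always includes a 1-atom, a 2-atom/1-bond and a 3-atom/2-bond
  molecule so these paths stay exercised.

The per-molecule vectors (157 = 145 + 12 long) are stacked and compressed
by a dataset-level PCA to 50 scores (centered, not scaled; explained
variance ratios are stored in the run metadata). Descriptors are z-scored
per column using the population SD (divide by n); constant columns become
all-zero and are flagged. The two blocks are concatenated — columns named
"PCA 1..50" then the descriptor names — and columns whose SD falls below
1e-12 are removed (the tolerance guards float noise around an exact
zero-variance rule). The number of surviving columns depends on the
library; small fixture libraries drop more constant descriptors than a
large diverse one would.

## Autoencoder and variational autoencoder

Both coders share one architecture: six blocks of (affine map → batch
normalization → ReLU) followed by an affine head. The encoder head emits
`d` values (AE code) or `2d` values interpreted as the posterior mean
E(Z) and **log**-variance — parameterizing log V(Z) keeps the variance
strictly positive by construction. The decoder mirrors the encoder back to
the input width. Default widths taper 128 → 96 → 64 → 48 → 32 → 24 and are
configurable.

The loss is the mean over the batch of the per-row squared error summed
over features; the VAE adds `(β/2) Σ_i (V − log V − 1 + E²)_i` per sample
(β default 1.0). Each KL summand is non-negative for V > 0 and vanishes
exactly at E = 0, V = 1, which the training loop asserts on every batch.
Optimization is Adam at learning rate 1e-3 (defaults: 100 epochs, batch
256, early stop when the epoch loss improves by less than 1e-5 for 10
consecutive epochs; a batch size above m/2 is reduced with a warning). A
single integer seed drives initialization, shuffling, and reparameterization
sampling, so a fit is exactly reproducible.

The networks are implemented directly on numpy arrays with explicit
forward and backward passes (He initialization, standard batch-norm
backward, Adam with bias correction). The backward pass is verified against
central-difference gradients in development; at the table sizes this
package targets (10²–10⁵ rows, ~250 columns) the loop is comfortably
CPU-bound-friendly. Embeddings are always extracted in inference mode:
batch normalization uses running statistics and the VAE contributes its
posterior mean, never a sample, so encoding is deterministic and
row-aligned.

## Clustering and the choice of k

K-means (k-means++ seeding, best of 10 restarts, tol 1e-4, max 300
iterations) and BIRCH (CF-tree threshold 0.5, branching factor 50, global
clustering of leaf entries) are delegated to scikit-learn; both use
Euclidean distance. When an over-large threshold collapses the CF-tree to
fewer leaves than the requested k, the global step is refined by clustering
the raw points so the requested k is honoured.

The cluster count is scanned over a grid (default 5–200 step 5). For each
k the mean Silhouette score is computed on a seeded subsample (default
10,000 points) because the exact O(m²) computation across a 40-point grid
is impractical for large libraries; final reported indices are always
exact. Scores are cached to CSV so interrupted scans resume. The selected
k is the smallest grid point whose next `window` (default 2) scores stay
within ε (default 0.01) of its own — the plateau onset — falling back to
the argmax when no plateau exists; the rule applied is logged.

## Internal validation indices

Silhouette, Calinski–Harabasz and Davies–Bouldin are implemented in-package
from their definitions (vectorized with a full pairwise-distance matrix)
and are checked in the test suite against brute-force double/triple-loop
oracles and against scikit-learn's implementations. Conventions: points in
singleton clusters contribute s = 0 to the Silhouette mean; the
Davies–Bouldin cluster "diameter" is the mean point-to-centroid distance;
the Calinski–Harabasz reference center is the global centroid over all
points; zero within-cluster dispersion yields +inf with a warning, and
coincident centroids are an error naming the clusters. All three indices
are invariant to label permutation and rigid translation.

## Similarity machinery

Fingerprints are folded Morgan/ECFP (defaults: count-based, radius 2, 2048
bits for similarity maps; binary, radius 1, 2048 bits for similarity
matrices, both configurable). Tanimoto similarity is |A∩B|/|A∪B| for bit
sets and Σ min / Σ max for count vectors (the count generalization is the
standard one); two empty fingerprints compare as 0 with a warning.

A similarity map weights each atom of a test molecule by the drop in
Tanimoto similarity to a reference when the atom's bits are removed. "An
atom's bits" are all bits with at least one circular environment containing
the atom (as center or member), and removal deletes the bit from the count
vector entirely. Weights are normalized by the maximum absolute weight
before rendering. Fingerprints are version-sensitive across RDKit releases,
so rendered images and specific similarity values are qualitative outputs,
not test surfaces. t-SNE for embedding scatters comes from scikit-learn
(seeded, PCA initialization).

## Synthetic data

The SMILES generator assembles molecules from a curated fragment grammar
(benzene/biphenyl/cyclohexane/piperidine scaffolds crossed with alkyl,
carboxylate, ester, amide, sulfonamide, halide, nitrile, nitro and ether
substituents, plus stand-alone heterocycles), guaranteeing validity without
rejection sampling, and always prepends the degenerate trio (1-atom,
2-atom/1-bond, 3-atom/2-bond). It emulates the motif variety of a drug-like
screening library, not the size or chemical distribution of any real
collection — passing tests demonstrate the pipeline's contracts, not
clustering quality on real libraries.

The Gaussian-mixture generator plants k isotropic unit-SD clusters.
`separation` is measured in units of the within-cluster **radial** SD (the
RMS point-to-centroid distance, √dim for unit per-coordinate SD): centroid
spacing is `separation · √dim`. Measuring spacing against the cluster
radius keeps the contrast of a given separation the same at every
dimensionality, so recovery results do not silently degrade as dim grows.
For k ≤ dim the centroids form a regular simplex (all pairwise spacings
equal, making the planted k unambiguous); for larger k, sampled directions
are rescaled so the minimum pairwise spacing equals the target. Cluster
sizes are balanced to within one point, and every generator is a pure
function of its seed.

## Pipeline and problem sizes

The pipeline stages (featurize → engineer → embed → scan → cluster →
evaluate → visualize) each write their artifact and skip when it already
exists, so runs resume; every artifact directory records the configuration
hash, and re-running a different configuration into the same directory is
refused. Tests and the acceptance script run the pipeline at fixture scale
— 200 generated molecules, a 16-d VAE for 20 epochs, k scanned over 2–10 —
which exercises every stage end-to-end in well under a minute; the same
code paths scale to full libraries by changing the configuration only.

## Known limitations

* Only the first principal component summarizes each molecule's local
  matrices; higher components are discarded by design.
* The latent representation carries no 3-D/conformer information and no
  graph-topological message passing; local structure enters only through
  the PCA-aggregated one-hot blocks.
* Representation learning and clustering are two separate stages; the
  embedding is not trained with a clustering objective.
* Internal indices compare clusterings of the *same* representation
  faithfully, but comparisons across representations (raw table vs.
  different latent spaces) inherit the usual caveat that the space itself
  changes the index scale.
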