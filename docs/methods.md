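# Methods

## Representation

A molecule is its heavy atoms only: atomic numbers from a configured element
set (default {C, N, O}) and Cartesian coordinates in angstrom. Hydrogens are
implicit throughout — their Coulomb-matrix terms are small, so reconstruction
errors would distort them disproportionately; adding and relaxing hydrogens
is delegated to external tools through the XYZ export hooks.

The Coulomb matrix uses `0.5 Z^2.4` diagonals and `Z_i Z_j / d_ij`
off-diagonals with distances in angstrom. No distance unit is canonical for
this descriptor; angstrom matches the coordinate and maximum-distance units
used everywhere else in the package, and any consistent choice only rescales
the off-diagonal block.

Padding and canonical order. Matrices are embedded in fixed species blocks
(slot counts = per-species maxima over the dataset, blocks ascending in Z).
Within a block, atoms are sorted by descending CM row norm — the standard
sorted-Coulomb-matrix convention — which makes the representation invariant
to the input atom order. Ties in the row norm are broken by input order;
exact ties require geometrically identical environments and do not occur for
generic geometries. Network I/O is the flattened upper triangle (length
L(L+1)/2); decoded vectors are mirrored into a symmetric matrix by
construction rather than symmetrized by averaging.

Inversion. Composition: each diagonal d maps to `(2d)^(1/2.4)` and is
assigned the nearest value in {0} ∪ allowed elements, with 0 meaning an empty
slot — a total function with no tunable threshold, robust to decoder noise of
a few units because neighbouring elements are ~8 diagonal units apart.
Distances: `d_ij = Z_i Z_j / M_ij` over occupied slots; a nonpositive
occupied off-diagonal is unphysical and raises an error (downstream pipelines
catch it and count the sample as a failed reconstruction). Coordinates:
classical multidimensional scaling — double-center `B = -J D^2 J / 2`,
eigendecompose, keep the three largest eigenvalues clamped at zero so noisy,
non-embeddable distance matrices still produce 3D coordinates. The output is
defined up to rotation, translation and reflection; the representation cannot
distinguish enantiomers, so RMSDs are reported with the reflection branch
allowed unless stated otherwise (Kabsch superposition, atoms matched by
canonical slot order, both handedness branches evaluated explicitly).

## Joint model

Structure encoder and decoder are mirrored tanh MLPs (default 512-256 hidden,
latent 32); the property encoder is a 128-128 MLP. The encoder outputs a
diagonal Gaussian (mu, sigma) with sigma = exp(logvar/2), logvar clipped to
±15. The decoder and the property encoder parameterize unit-variance
Gaussians, so both negative log likelihoods reduce to 0.5·squared error plus
a constant, and the property encoder's reported sigma is identically one.
The training loss per sample is

    beta * KL(q_phi(z|x) || N(0, I))
    + 0.5 ||x - x_hat(z)||^2 + const
    + tau * (0.5 ||z - mu_psi(y)||^2 + const),

with z drawn by the reparameterization trick. Inputs are standardized with
statistics from the training split only: property columns are z-scored, CM
vectors are divided by their global maximum.

Defaults: beta = 4e-3, tau = 0.1, Adam with learning rate 3e-3, batch 128,
800 epochs. tau deserves comment: the property term pulls the latent toward
what the properties can predict, and with tau ~ 1 this collapses the latent
before the autoencoder has learned a rich code — reconstruction stalls and
composition recovery fails. tau = 0.1 keeps the property alignment (the
property encoder's own regression is unaffected by the weight) while letting
the reconstruction term shape the code. All arithmetic is float64 NumPy with
hand-derived gradients (verified against finite differences in the test
suite); training is bit-reproducible for a fixed seed.

Masking mode (off by default): per sample, a Bernoulli(0.5) vector b of
length L forms the rank-one mask `2 b b^T`; entries where the target CM is
zero get the leaky value 0.1. The mask's upper triangle weights the
per-element reconstruction NLL. Note the factor 2 restores the expected
weight on the diagonal (E[2b^2] = 1) but not off the diagonal
(E[2 b_i b_j] = 0.5); the rule is implemented literally as stated for the
method, and the all-ones mask reproduces the unmasked loss exactly.

Inference. The latent for a property vector is the *mean* of p_psi(z|y) —
the maximum-likelihood estimator — never a sample. The self-consistency
metric re-encodes the decoded CM with the structure encoder:
`||dz|| = ||mu_psi(y) - mu_phi(decode(mu_psi(y)))||`. It requires no ground
truth and correlates positively with the reconstruction RMSD, which is what
makes it usable as a generation filter.

## Attribution

Jacobians d(CM vector)/d(property) are exact forward-mode derivatives through
the property-encoder mean and decoder, taken with respect to standardized
properties so the columns are comparable across units (the raw-unit choice
would bury small-magnitude properties). The attribution score of property j
averages the Jacobian column norm over a subset of well-reconstructed
molecules (default: up to 150 with RMSD <= 0.2 A, ascending RMSD, ties broken
by identifier); the decoded upper triangle is used directly so off-diagonal
entries are not double counted. Scores are optionally normalized by the
maximum. The latent PCA projection uses a deterministic sign convention
(largest-magnitude loading positive) so repeated runs agree.

## Property-space mixture and targeted generation

The 17-property joint distribution is modeled by a full-covariance Gaussian
mixture fitted by EM on z-scored properties (k-means++ initialization, fixed
number of restarts, seeded); K is selected by BIC over a configurable grid
(default 1-10 at desk scale — the appropriate grid grows with dataset size).
Fitted weights/means/covariances are reported in raw property units.
Singular covariances are regularized by 1e-6 on the diagonal with a warning.

Generation conditions the maximum-marginal-likelihood component on the
targeted values via the closed-form conditional mean and covariance (the
conditional covariance is independent of the targeted values), samples the
free properties, maps every assembled vector through the model, and keeps
samples whose ||dz|| lies in the acceptance interval, ranked ascending. The
default interval [0, 0.4] is a per-target configuration field: the useful
range depends on the model and target, and an over-stringent interval simply
yields an empty (warned) result. The quantum-chemistry screening of generated
structures used in full-scale studies is out of scope; in its place a
geometric sanity screen rejects clear overlaps (< 0.5 A) and broken contact
graphs (nearest heavy-atom neighbour beyond 2.5 A) — deliberately permissive
because decoded geometries are not re-optimized — and every structure can be
exported as XYZ for external refinement. Target quality is quantified by
epsilon = |y_calc - y_target| / range(y) * 100.

## Geodesic interpolation

A path between two molecules lives in property space: points y_0..y_N with
endpoints fixed, latent image z_i = mu_psi(y_i). Starting from the linear
interpolation, interior points minimize

    L = sum ||z_{i+1} - z_i||^2 + eps_reg * sum ||y_{i+1} - y_i||^2

with eps_reg = 1e-2 (<< 1; just enough to keep the path continuous in
property space, measured in standardized units). The optimizer is first-order
descent with Barzilai-Borwein step selection and backtracking, so accepted
losses are monotone non-increasing; it stops when the gradient norm drops
below 1e-4 (configurable) or at the iteration cap. For a linear encoder the
unique optimum is the straight line, which the optimizer recovers to 1e-6 —
the closed-form limit used as a correctness check. Candidate endpoint pairs
should pass the mirror-image check (reflection-allowed RMSD small, forbidden
RMSD large): enantiomer pairs look identical to the representation and make
the interpolation degenerate. Energy profiles along the path require an
external engine; the module exports the decoded structures as XYZ initial
guesses instead.

## Synthetic chemical space

The generator produces the study conditions for all desk-scale experiments:
compositions uniform over the multisets of 1-7 atoms from {C, N, O};
geometries grown by sequential attachment at uniform bond lengths in
[1.2, 1.7] A with a hard floor of 0.8× the minimum bond length, giving
connected contact graphs; splits 70/5/25 train/validation/test.

The 17 properties mimic the *roles* of a typical QM property table, not its
physics: six extensive energy-like sums over per-element constants and
pairwise `Z_i Z_j / d_ij` combinations (so same-composition molecules form
tight clusters in, e.g., the pseudo-kinetic/pseudo-exchange plane); an
extensive pseudo-polarizability (per-element terms plus capped
nearest-neighbour distances, additive over far-apart fragments); bounded
intensive gap/orbital-like functions of the distance spectrum; a dipole-like
norm with fixed per-element charges; the exact maximum atom-atom distance;
and one property of pure noise — a designed negative control that attribution
must rank last. Gaussian noise with sigma = 0.2% of each property's nominal
scale is added to all: the emulated tables are computed quantities, so their
noise is numerical rather than experimental, and markedly larger noise would
wash out near-degenerate composition differences (2N vs C+O in the
pseudo-kinetic sum) that real property sets do resolve.

What passing the synthetic benchmark shows: that the whole pipeline —
representation, joint training, inversion, attribution, conditioning,
filtering, interpolation — is internally consistent and recovers structure
from properties when the properties carry the information. What it does not
show: performance on real QM data, where property-structure relationships
are nonlinear in ways this generator does not emulate, and where the
headline accuracies require full-scale training on the real dataset (reader
provided, accession-gated).

## Problem sizes and numerical choices

The reference study trains on 1,400 molecules (of a 2,000-molecule space)
for 800 epochs — a few minutes on one CPU — reaching ~99% held-out
composition accuracy, mean relative CM error ~17%, and a significantly
positive Spearman correlation between ||dz|| and RMSD. The property-count
scan retrains with nested property subsets (2, 4, 8; composition anchors
first) at 400 epochs, where the median CM error decreases monotonically with
the property count. Numerical tie-breaks and degenerate-input behaviour:
logvar clipping at ±15; CMDS eigenvalue clamping at zero; empty-slot
assignment by nearest value rather than thresholds; covariance regularization
1e-6; PCA sign convention by largest loading; RMSD ties broken by identifier.

## Known limitations

* Decoded Coulomb matrices are occasionally uninvertible (nonpositive
  occupied off-diagonals); pipelines report such samples as failed
  reconstructions rather than repairing them.
* Geometry accuracy is information-limited: 17 scalar properties cannot pin
  down ~15 geometric degrees of freedom of a 7-atom molecule, so RMSDs are
  honest but wide; composition recovery is the sharp result.
* Chirality is invisible to the representation; everything is defined up to
  reflection.
* The generator's property map is linear-ish by design; conclusions about
  deep nonlinear property encoders require the real dataset.
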