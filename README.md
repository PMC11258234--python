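# molinverse

Inverse property-to-structure mapping for small organic molecules: given a
vector of global quantum-mechanical (QM) properties, reconstruct a plausible
heavy-atom 3D structure. The package is aimed at researchers exploring
property-driven navigation of chemical compound space — inverse QSPR,
explainability of property/structure relationships, multi-objective targeted
generation, and transition-path guessing — at desk scale, on synthetic data
by default and optionally on a real QM dataset.

## The model

Molecules (heavy atoms C/N/O, hydrogens implicit) are represented by the
Coulomb matrix

```
M_ii = 0.5 Z_i^2.4,     M_ij = Z_i Z_j / |r_i - r_j|,
```

padded into fixed per-species blocks, canonically ordered by descending row
norm, and flattened to the upper triangle. The representation is invariant to
rotation/translation and *invertible*: diagonals yield atomic numbers via
`(2d)^(1/2.4)`, off-diagonals yield distances, and classical multidimensional
scaling (CMDS) recovers coordinates up to a chirality transformation.

Three networks are trained jointly on pairs (x = CM vector, y = 17
properties):

* structure encoder `q_phi(z|x)` and decoder `p_theta(x|z)` — a VAE;
* a property encoder `p_psi(z|y)` sharing the same latent space.

The loss is `beta·D_KL[q_phi || N(0,I)] - E_q[log p_theta(x|z)]
- tau·E_q[log p_psi(z|y)]`; with `tau = 0, beta = 1` it is the standard ELBO.
At inference the latent for a property vector is the mean of `p_psi(z|y)`;
decoding and inverting the CM yields the molecule. On top of this mapping the
package provides:

* **attribution maps** `A_j = (1/N) sum_k ||d CM^k / d p_j||` ranking
  properties by their influence on the reconstruction;
* **targeted generation**: a BIC-selected Gaussian mixture over property
  space, closed-form conditioning on targeted values, sampling of the free
  properties, and filtering by the self-consistency metric `||dz||`
  (property-encoder latent vs. re-encoded decoded structure);
* **geodesic interpolation**: property-space paths whose latent image has
  minimal squared length, optimized with endpoints fixed — transition-path
  guesses between isomers, exported as XYZ sequences;
* a **synthetic data generator** emulating the statistical structure of a
  small-molecule QM dataset, and an HDF5 reader for the real thing
  (Zenodo accession 10.5281/zenodo.4288677).

## Worked example

```python
import numpy as np
from molinverse import (
    SyntheticDatasetSpec, make_dataset, PropertyStructureVAE,
    evaluate_reconstruction, PaddedCM,
)
from molinverse.coulomb import unflatten_upper

# a desk-scale chemical space: 2,000 molecules, <=7 heavy atoms from {C, N, O}
dataset = make_dataset(SyntheticDatasetSpec(n=2000, seed=42))
_, X_train, Y_train = dataset.subset("train")
_, X_test, Y_test = dataset.subset("test")

model = PropertyStructureVAE(random_state=0)
model.fit(X_train, Y_train)

# invert the property vector of a held-out molecule into a structure
idx_test, _, _ = dataset.subset("test")
i = idx_test[0]
padded, molecule = model.property_to_structure(Y_test[0], dataset.layout)
report = evaluate_reconstruction(
    dataset.molecules[i],
    PaddedCM(unflatten_upper(dataset.X[i]), dataset.layout),
    model.predict(Y_test[:1])[0],
)
print("true composition:", dataset.molecules[i].species)
print("reconstructed:  ", molecule.species)
print(f"relative CM error: {report.delta_percent:.1f}%")
print(f"heavy-atom RMSD:   {report.rmsd:.2f} A")
print(f"self-consistency ||dz||: {model.self_consistency_delta(Y_test[0]):.3f}")
```

Output (about three minutes on one CPU):

```
true composition: (8, 8, 8, 8, 7, 6)
reconstructed:   (6, 7, 8, 8, 8, 8)
relative CM error: 21.2%
heavy-atom RMSD:   1.20 A
self-consistency ||dz||: 0.453
```

The heavy-atom composition is recovered exactly (the reconstruction lists
atoms in canonical species order). The relative CM error Delta = |C~ - C|/|C|
x 100 summarizes representation fidelity; the RMSD of 1.2 A marks a mediocre
geometry, consistent with its `||dz||` of 0.45 — reconstructions with
`||dz||` below ~0.4 are typically the reliable ones, which is exactly how the
generation pipeline filters its samples.

## Command line

Every stage is also a subcommand of the `molinverse` executable, driven by a
YAML config and a seed, writing CSV/XYZ/JSON outputs plus a manifest:

```
molinverse simulate    --config config.yaml --seed 1 --out runs/sim
molinverse train       --dataset runs/sim/dataset.npz --seed 1 --out runs/model
molinverse evaluate    --dataset ... --model ... --out runs/eval
molinverse attribute   --dataset ... --model ... --out runs/attr
molinverse generate    --dataset ... --model ... --out runs/gen
molinverse interpolate --dataset ... --model ... --start 0 --end 1 --out runs/path
```

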