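"""Synthetic molecules and property vectors for desk-scale experiments.

The generator emulates the statistical structure of a quantum-chemistry
dataset of small organic molecules (up to seven heavy atoms from {C, N, O})
without running any electronic-structure code:

* compositions are drawn uniformly over the allowed element multisets;
* geometries are grown by sequential attachment at bond-like distances with a
  hard-sphere rejection floor, yielding connected contact graphs;
* 17 named properties mirror the roles of common QM observables — extensive
  entries are per-atom or per-pair sums (so molecules cluster by composition
  in, e.g., the pseudo-kinetic/pseudo-exchange plane), intensive entries are
  bounded functions of geometry, the maximum atom-atom distance is exact, and
  one property is pure noise, a designed negative control for attribution.

These are caricatures: real orbital energies, dispersion corrections, etc.
are not computed. An HDF5 reader for the real dataset (Zenodo accession
10.5281/zenodo.4288677) is provided for optional full-scale runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from . import coulomb
from .coulomb import CoulombLayout
from .molecule import DEFAULT_ELEMENTS, Molecule

#: canonical property ordering shared by all model components
PROPERTY_NAMES = (
    "e_at", "e_mbd", "e_xx", "e_nn", "e_ee", "e_kin",
    "e_gap", "e_homo_0", "e_lumo_0", "e_homo_1", "e_lumo_1",
    "e_homo_2", "e_lumo_2", "dipole", "polarizability", "d_max",
    "noise",
)

#: extensive properties scale with system size; the rest are intensive
EXTENSIVE = frozenset(
    {"e_at", "e_mbd", "e_xx", "e_nn", "e_ee", "e_kin", "polarizability"}
)

# fixed per-element coefficients (slightly incommensurate so that composition
# sums separate cleanly across multisets)
_KIN = {6: 1025.3, 7: 1483.1, 8: 2037.9}
_XX = {6: 290.7, 7: 395.2, 8: 514.6}
_AT = {6: 7.43, 7: 8.91, 8: 10.27}
_EE = {6: 610.4, 7: 871.6, 8: 1189.3}
_POL = {6: 11.7, 7: 7.2, 8: 5.1}
_CHARGE = {6: -0.10, 7: 0.35, 8: -0.45}

#: nominal magnitude of each property, used to scale the additive noise
PROPERTY_SCALES = {
    "e_at": 60.0, "e_mbd": 0.5, "e_xx": 2500.0, "e_nn": 400.0,
    "e_ee": 6000.0, "e_kin": 10000.0, "e_gap": 2.0, "e_homo_0": 2.0,
    "e_lumo_0": 2.0, "e_homo_1": 2.0, "e_lumo_1": 2.0, "e_homo_2": 2.0,
    "e_lumo_2": 2.0, "dipole": 1.0, "polarizability": 60.0, "d_max": 3.0,
    "noise": 1.0,
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Conditions under which the synthetic chemical space is generated."""

    n: int = 2000
    elements: tuple = DEFAULT_ELEMENTS
    max_atoms: int = 7
    bond_range: tuple = (1.2, 1.7)  # angstrom, typical heavy-atom bonds
    noise_sigma: float = 0.002  # fraction of each property's nominal scale
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(int(z) for z in self.elements))
        object.__setattr__(self, "bond_range", tuple(float(v) for v in self.bond_range))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.bond_range
        if not (0.8 < lo <= hi < 2.5):
            raise ValueError("bond range must lie within (0.8, 2.5) angstrom")


def enumerate_compositions(elements=DEFAULT_ELEMENTS, max_atoms=7):
    """All heavy-atom multisets with 1..max_atoms atoms, in a fixed order."""
    out = []
    for n in range(1, max_atoms + 1):
        out.extend(combinations_with_replacement(sorted(elements), n))
    return out


def sample_molecule(rng: np.random.Generator, spec: SyntheticDatasetSpec) -> Molecule:
    """Draw one molecule: uniform composition, sequential-attachment geometry.

    Each new atom is placed at a uniform distance in ``bond_range`` from a
    randomly chosen existing atom, in a uniformly random direction; placements
    with any pair closer than 0.8 * min bond length are rejected.
    """
    compositions = enumerate_compositions(spec.elements, spec.max_atoms)
    floor = 0.8 * spec.bond_range[0]
    while True:
        species = list(compositions[rng.integers(len(compositions))])
        rng.shuffle(species)
        coords = [np.zeros(3)]
        ok = True
        for _ in range(1, len(species)):
            for _attempt in range(200):
                anchor = coords[rng.integers(len(coords))]
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                r = rng.uniform(*spec.bond_range)
                candidate = anchor + r * direction
                if all(np.linalg.norm(candidate - c) >= floor for c in coords):
                    coords.append(candidate)
                    break
            else:
                ok = False
                break
        if ok:
            return Molecule(tuple(species), np.array(coords))


def synthetic_properties(
    mol: Molecule, spec: SyntheticDatasetSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """The 17 synthetic properties of a molecule, in canonical order.

    With ``rng=None`` (or noise_sigma=0) the values are noise-free except for
    the dedicated "noise" property, which requires an rng and is set to 0
    without one.
    """
    z = np.asarray(mol.species, dtype=float)
    n = mol.n_atoms
    d = mol.distance_matrix()
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    inv_d = 1.0 / pair_d if pair_d.size else np.array([])
    zz = (z[:, None] * z[None, :])[iu]

    d_mean = float(pair_d.mean()) if pair_d.size else 0.0
    d_min = float(pair_d.min()) if pair_d.size else 0.0
    d_std = float(pair_d.std()) if pair_d.size else 0.0
    d_max = float(pair_d.max()) if pair_d.size else 0.0

    # nearest-neighbour distances, capped: additive over far-apart fragments
    if n > 1:
        nn_dist = np.minimum((d + np.diag(np.full(n, np.inf))).min(axis=1), 3.0)
    else:
        nn_dist = np.zeros(1)

    e_nn = float((zz * inv_d).sum()) if pair_d.size else 0.0
    e_mbd = -0.02 * float((inv_d ** 3).sum()) if pair_d.size else 0.0
    e_kin = float(sum(_KIN[int(s)] for s in mol.species))
    e_xx = -float(sum(_XX[int(s)] for s in mol.species)) - 0.4 * e_nn
    e_at = -float(sum(_AT[int(s)] for s in mol.species)) - 0.05 * e_nn
    e_ee = float(sum(_EE[int(s)] for s in mol.species)) + 0.6 * e_nn
    polar = float(sum(_POL[int(s)] for s in mol.species)) + 0.5 * float(nn_dist.sum())

    e_gap = 4.0 / (1.0 + d_mean)
    e_homo_0 = -4.0 - 2.0 / (1.0 + d_mean)
    e_lumo_0 = e_homo_0 + e_gap
    e_homo_1 = e_homo_0 - 0.8 / (1.0 + d_min)
    e_lumo_1 = e_lumo_0 + 0.6 * d_std / (1.0 + d_mean)
    hetero_frac = float(np.mean(z != 6))
    e_homo_2 = e_homo_0 - 1.5 * hetero_frac
    e_lumo_2 = e_lumo_0 + 0.9 * hetero_frac

    centroid = mol.coords.mean(axis=0)
    charges = np.array([_CHARGE[int(s)] for s in mol.species])
    dipole = float(np.linalg.norm((charges[:, None] * (mol.coords - centroid)).sum(axis=0)))

    values = {
        "e_at": e_at, "e_mbd": e_mbd, "e_xx": e_xx, "e_nn": e_nn,
        "e_ee": e_ee, "e_kin": e_kin, "e_gap": e_gap,
        "e_homo_0": e_homo_0, "e_lumo_0": e_lumo_0,
        "e_homo_1": e_homo_1, "e_lumo_1": e_lumo_1,
        "e_homo_2": e_homo_2, "e_lumo_2": e_lumo_2,
        "dipole": dipole, "polarizability": polar, "d_max": d_max,
        "noise": 0.0,
    }
    out = np.array([values[name] for name in PROPERTY_NAMES])
    if rng is not None:
        scales = np.array([PROPERTY_SCALES[name] for name in PROPERTY_NAMES])
        out = out + spec.noise_sigma * scales * rng.standard_normal(len(out))
        out[PROPERTY_NAMES.index("noise")] = rng.standard_normal()
    return out


@dataclass
class SyntheticDataset:
    """Molecules, their padded CM vectors, properties, and split labels."""

    spec: SyntheticDatasetSpec
    molecules: list
    layout: CoulombLayout
    X: np.ndarray = field(repr=False)  # (n, D) CM vectors
    Y: pd.DataFrame = field(repr=False)  # (n, 17) properties
    split: np.ndarray = field(repr=False)  # 'train' / 'val' / 'test'

    def subset(self, name):
        idx = np.flatnonzero(self.split == name)
        return idx, self.X[idx], self.Y.values[idx]


def make_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate a full dataset, deterministic under the spec seed.

    The padding layout is computed from the dataset species maxima and splits
    follow the 70/5/25 train/validation/test protocol.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = [sample_molecule(rng, spec) for _ in range(spec.n)]
    layout = CoulombLayout.from_molecules(molecules, spec.elements)
    X = np.stack([coulomb.padded_cm(m, layout).vector for m in molecules])
    Y = pd.DataFrame(
        np.stack([synthetic_properties(m, spec, rng) for m in molecules]),
        columns=list(PROPERTY_NAMES),
    )
    n_train = int(round(0.70 * spec.n))
    n_val = int(round(0.05 * spec.n))
    split = np.array(
        ["train"] * n_train + ["val"] * n_val + ["test"] * (spec.n - n_train - n_val)
    )
    return SyntheticDataset(spec, molecules, layout, X, Y, split)


# ---------------------------------------------------------------------------
# real-dataset reader (optional, accession-gated)
# ---------------------------------------------------------------------------

#: default HDF5 key mapping; override via the ``property_keys`` argument
QM7X_DEFAULT_KEYS = {
    "coordinates": "atXYZ",
    "species": "atNUM",
}

QM7X_ACCESSION = "10.5281/zenodo.4288677"


def qm7x_load(
    path,
    elements=DEFAULT_ELEMENTS,
    max_heavy_atoms=7,
    property_keys=None,
    structure_keys=None,
):
    """Load equilibrium structures from a local QM7-X-schema HDF5 directory.

    Keeps conformations whose group name marks them as optimized ("opt"),
    whose heavy atoms are a subset of ``elements`` and number at most
    ``max_heavy_atoms``. Hydrogens are dropped (implicit). Returns
    (molecules, properties DataFrame).

    ``property_keys`` maps canonical property names to dataset keys; the
    identity of all 17 properties is configuration, not hard-coded.
    """
    import h5py

    structure_keys = {**QM7X_DEFAULT_KEYS, **(structure_keys or {})}
    property_keys = dict(property_keys or {})
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if f.endswith((".h5", ".hdf5"))
    ) if os.path.isdir(path) else []
    if not files:
        raise FileNotFoundError(
            f"no HDF5 files under {path!r}; download the dataset from Zenodo "
            f"accession {QM7X_ACCESSION} first"
        )
    molecules, rows = [], []
    allowed = set(int(z) for z in elements)
    for fname in files:
        with h5py.File(fname, "r") as fh:
            for mol_key in fh:
                group = fh[mol_key]
                for conf_key in group:
                    if "opt" not in conf_key:
                        continue  # equilibrium conformations only
                    conf = group[conf_key]
                    species = np.asarray(conf[structure_keys["species"]]).astype(int)
                    coords = np.asarray(conf[structure_keys["coordinates"]], dtype=float)
                    heavy = species != 1
                    heavy_z = species[heavy]
                    if len(heavy_z) == 0 or len(heavy_z) > max_heavy_atoms:
                        continue
                    if not set(heavy_z.tolist()) <= allowed:
                        continue
                    molecules.append(Molecule(tuple(heavy_z), coords[heavy]))
                    rows.append(
                        {name: float(np.asarray(conf[key]).ravel()[0])
                         for name, key in property_keys.items()}
                    )
    return molecules, pd.DataFrame(rows)
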