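"""Heavy-atom molecules.

Hydrogens are treated implicitly throughout: a molecule is a list of heavy-atom
atomic numbers plus Cartesian coordinates in angstrom. Adding and optimizing
hydrogens is left to external tools fed through the XYZ export hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: element symbol <-> atomic number, covering the organic subset this package targets
SYMBOL_TO_Z = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "Si": 14, "P": 15, "S": 16, "Cl": 17,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: default heavy-atom element set: carbon, nitrogen, oxygen
DEFAULT_ELEMENTS = (6, 7, 8)

#: hard floor below which two heavy atoms are considered coincident, in angstrom
DEFAULT_MIN_DISTANCE = 0.5


class GeometryError(ValueError):
    """Raised for degenerate or physically impossible geometries."""


@dataclass(frozen=True)
class Molecule:
    """A heavy-atom molecule: atomic numbers and 3D coordinates in angstrom."""

    species: tuple
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        species = tuple(int(z) for z in self.species)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(species) != len(coords):
            raise ValueError("species and coords length mismatch")
        if len(species) == 0:
            raise ValueError("molecule must contain at least one atom")
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def validate(self, min_distance: float = DEFAULT_MIN_DISTANCE) -> "Molecule":
        """Check the minimum pairwise distance; return self for chaining."""
        if min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.n_atoms > 1:
            d = self.distance_matrix()
            off = d[~np.eye(self.n_atoms, dtype=bool)]
            if off.min() < min_distance:
                raise GeometryError(
                    f"atoms closer than {min_distance} A (min pair {off.min():.4f} A)"
                )
        return self

    def composition(self) -> dict:
        """Heavy-atom composition as {atomic number: count}."""
        comp: dict = {}
        for z in self.species:
            comp[z] = comp.get(z, 0) + 1
        return comp

    def translated(self, shift) -> "Molecule":
        return Molecule(self.species, self.coords + np.asarray(shift, dtype=float))

    def rotated(self, rotation) -> "Molecule":
        rotation = np.asarray(rotation, dtype=float)
        return Molecule(self.species, self.coords @ rotation.T)

    def mirrored(self) -> "Molecule":
        coords = self.coords.copy()
        coords[:, 2] *= -1.0
        return Molecule(self.species, coords)
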