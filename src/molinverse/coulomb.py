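"""Coulomb-matrix representation: construction, padding, and exact inversion.

The Coulomb matrix (CM) of a molecule with atomic numbers Z_i and positions r_i is

    M_ii = 0.5 * Z_i**2.4
    M_ij = Z_i * Z_j / |r_i - r_j|        (distances in angstrom)

It is invariant to rotation and translation and, crucially for inverse design,
invertible up to a chirality transformation: the diagonal yields the atomic
numbers through g(d) = (2 d)**(1/2.4), the off-diagonal entries yield pairwise
distances, and classical multidimensional scaling (CMDS) recovers Cartesian
coordinates from the distance matrix.

For network I/O, matrices are padded into fixed per-species blocks (slot counts
taken from the dataset maxima), atoms within a block are ordered by descending
CM row norm so the representation is permutation-stable, empty slots are zero,
and the symmetric matrix is exchanged as its flattened upper triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .molecule import DEFAULT_ELEMENTS, GeometryError, Molecule

CM_DIAGONAL_EXPONENT = 2.4


class CapacityError(ValueError):
    """Molecule does not fit into the padding layout."""


class InvalidMatrixError(ValueError):
    """A padded CM cannot be inverted (e.g. nonpositive occupied off-diagonal)."""


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoulombLayout:
    """Species-block padding layout: ordered (Z, slot count) pairs.

    Blocks are ordered by ascending atomic number; the matrix side L is the
    total slot count.
    """

    slots: tuple  # ((Z, count), ...) ascending in Z

    def __post_init__(self):
        slots = tuple((int(z), int(c)) for z, c in self.slots)
        if any(c < 0 for _, c in slots):
            raise ValueError("slot counts must be nonnegative")
        zs = [z for z, _ in slots]
        if zs != sorted(set(zs)):
            raise ValueError("species blocks must be unique and ascending in Z")
        object.__setattr__(self, "slots", slots)

    @property
    def size(self) -> int:
        return sum(c for _, c in self.slots)

    @property
    def elements(self) -> tuple:
        return tuple(z for z, _ in self.slots)

    @property
    def vector_length(self) -> int:
        L = self.size
        return L * (L + 1) // 2

    def block_range(self, z: int) -> range:
        start = 0
        for bz, c in self.slots:
            if bz == z:
                return range(start, start + c)
            start += c
        raise KeyError(f"element Z={z} not in layout")

    def slot_species(self) -> np.ndarray:
        """Atomic number assigned to each slot (length L)."""
        out = []
        for z, c in self.slots:
            out.extend([z] * c)
        return np.array(out, dtype=int)

    @classmethod
    def from_counts(cls, counts: dict) -> "CoulombLayout":
        return cls(tuple(sorted(counts.items())))

    @classmethod
    def from_molecules(cls, molecules, elements=DEFAULT_ELEMENTS) -> "CoulombLayout":
        """Per-species slot counts = maxima over the dataset."""
        counts = {int(z): 0 for z in elements}
        for mol in molecules:
            comp = mol.composition()
            for z, c in comp.items():
                if z not in counts:
                    raise ValueError(f"element Z={z} outside the configured set")
                counts[z] = max(counts[z], c)
        return cls.from_counts(counts)


@dataclass(frozen=True)
class PaddedCM:
    """Species-block-padded, canonically ordered symmetric Coulomb matrix."""

    matrix: np.ndarray = field(repr=False)
    layout: CoulombLayout

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        L = self.layout.size
        if m.shape != (L, L):
            raise ValueError(f"matrix shape {m.shape} != layout size {L}")
        object.__setattr__(self, "matrix", m)

    @property
    def vector(self) -> np.ndarray:
        """Flattened upper triangle (including diagonal), the network I/O form."""
        return flatten_upper(self.matrix)


def flatten_upper(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(matrix.shape[0])
    return matrix[iu]


def unflatten_upper(vector: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix by mirroring the upper triangle."""
    vector = np.asarray(vector, dtype=float)
    n = int(round((np.sqrt(8 * vector.size + 1) - 1) / 2))
    if n * (n + 1) // 2 != vector.size:
        raise ValueError(f"vector length {vector.size} is not triangular")
    out = np.zeros((n, n))
    iu = np.triu_indices(n)
    out[iu] = vector
    out.T[iu] = vector
    return out


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def diagonal_entry(z) -> np.ndarray:
    """CM diagonal 0.5 * Z**2.4."""
    return 0.5 * np.asarray(z, dtype=float) ** CM_DIAGONAL_EXPONENT


def build_coulomb_matrix(mol: Molecule, min_distance: float = 1e-6) -> np.ndarray:
    """Unpadded Coulomb matrix of a molecule (distances in angstrom)."""
    n = mol.n_atoms
    z = np.asarray(mol.species, dtype=float)
    d = mol.distance_matrix()
    off = d[~np.eye(n, dtype=bool)]
    if n > 1 and off.min() < min_distance:
        raise GeometryError("coincident atoms: zero interatomic distance in CM")
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.outer(z, z) / d
    np.fill_diagonal(m, diagonal_entry(z))
    return m


def canonicalize_and_pad(cm: np.ndarray, species, layout: CoulombLayout) -> PaddedCM:
    """Place atoms into species blocks, canonically ordered, zero-padded.

    Within a block atoms are sorted by descending CM row norm (the standard
    sorted-Coulomb-matrix convention), which makes the result invariant to the
    input atom order.
    """
    cm = np.asarray(cm, dtype=float)
    species = np.asarray(species, dtype=int)
    n = len(species)
    if cm.shape != (n, n):
        raise ValueError("cm shape does not match species length")
    L = layout.size
    row_norms = np.linalg.norm(cm, axis=1)

    order = []  # original atom index for each occupied slot, in slot order
    for z, cap in layout.slots:
        members = np.flatnonzero(species == z)
        if len(members) > cap:
            raise CapacityError(
                f"{len(members)} atoms of Z={z} exceed layout capacity {cap}"
            )
        members = members[np.argsort(-row_norms[members], kind="stable")]
        order.append(members)

    placed = np.concatenate(order) if order else np.array([], dtype=int)
    if len(placed) != n:
        extra = set(species) - set(layout.elements)
        raise CapacityError(f"species {sorted(extra)} not present in layout")

    slot_of = []  # slot index for each entry of `placed`
    pos = 0
    for (z, cap), members in zip(layout.slots, order):
        slot_of.extend(range(pos, pos + len(members)))
        pos += cap

    out = np.zeros((L, L))
    slot_idx = np.array(slot_of, dtype=int)
    out[np.ix_(slot_idx, slot_idx)] = cm[np.ix_(placed, placed)]
    return PaddedCM(out, layout)


def padded_cm(mol: Molecule, layout: CoulombLayout) -> PaddedCM:
    """Convenience: build + canonicalize + pad."""
    return canonicalize_and_pad(build_coulomb_matrix(mol), mol.species, layout)


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def infer_composition(padded: PaddedCM) -> np.ndarray:
    """Atomic number per occupied slot, in slot order.

    Each diagonal entry d maps to Z~ = (2 d)**(1/2.4) and is assigned the
    nearest value in {0} U allowed-elements (0 = empty slot). Total on any
    input, including noisy decoder output.
    """
    diag = np.clip(np.diag(padded.matrix), 0.0, None)
    z_tilde = (2.0 * diag) ** (1.0 / CM_DIAGONAL_EXPONENT)
    candidates = np.array([0, *padded.layout.elements], dtype=float)
    nearest = candidates[np.argmin(np.abs(z_tilde[:, None] - candidates[None, :]), axis=1)]
    return nearest.astype(int)


def cm_to_distances(padded: PaddedCM, slot_species: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of the occupied slots, d_ij = Z_i Z_j / M_ij."""
    occupied = np.flatnonzero(slot_species)
    z = slot_species[occupied].astype(float)
    sub = padded.matrix[np.ix_(occupied, occupied)]
    n = len(occupied)
    if n == 0:
        raise InvalidMatrixError("all-zero matrix: no occupied slots")
    off_mask = ~np.eye(n, dtype=bool)
    if n > 1 and np.any(sub[off_mask] <= 0):
        raise InvalidMatrixError("nonpositive off-diagonal entry for an occupied pair")
    d = np.zeros((n, n))
    zz = np.outer(z, z)
    d[off_mask] = zz[off_mask] / sub[off_mask]
    return d


def cmds_embed(edm: np.ndarray) -> np.ndarray:
    """Classical multidimensional scaling to 3D coordinates.

    Double-center B = -1/2 J D^2 J, eigendecompose, keep the three largest
    eigenvalues clamped at zero. Output is defined up to rotation, translation
    and reflection; negative eigenvalues (non-embeddable, noisy input) are
    clamped so 3D coordinates are always produced.
    """
    d = np.asarray(edm, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("EDM must be square")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("EDM entries must be finite and nonnegative")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("EDM must be symmetric with zero diagonal")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:3]
    w3 = np.clip(w[idx], 0.0, None)
    coords = np.zeros((n, 3))
    coords[:, : len(idx)] = v[:, idx] * np.sqrt(w3)
    return coords


def reconstruct_molecule(padded: PaddedCM) -> Molecule:
    """Invert a padded CM: composition -> distances -> CMDS coordinates.

    The geometry is recovered up to a chirality (mirror) transformation.
    """
    slot_species = np.zeros(padded.layout.size, dtype=int)
    comp = infer_composition(padded)
    slot_species[: len(comp)] = comp
    occupied = np.flatnonzero(slot_species)
    if len(occupied) == 0:
        raise InvalidMatrixError("empty molecule: no occupied slots inferred")
    edm = cm_to_distances(padded, slot_species)
    coords = cmds_embed(edm)
    return Molecule(tuple(slot_species[occupied]), coords)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

class CompositionMismatchError(ValueError):
    """RMSD requested for molecules with different compositions."""


def _kabsch(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal proper rotation + translation of q onto p."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = qc.T @ pc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, sign])
    rot = vt.T @ np.diag(diag) @ u.T
    return float(np.sqrt(np.mean(np.sum((qc @ rot.T - pc) ** 2, axis=1))))


def heavy_atom_rmsd(a: Molecule, b: Molecule, allow_reflection: bool = True) -> float:
    """Minimal RMSD over rigid superpositions, atoms matched by slot order.

    With ``allow_reflection`` the minimum over both handedness choices is
    returned (the CM representation cannot distinguish enantiomers).
    """
    if a.species != b.species:
        raise CompositionMismatchError(
            f"composition mismatch: {a.species} vs {b.species}"
        )
    rmsd = _kabsch(a.coords, b.coords)
    if allow_reflection:
        rmsd = min(rmsd, _kabsch(a.coords, b.mirrored().coords))
    return rmsd


def relative_cm_error(c: np.ndarray, c_tilde: np.ndarray) -> float:
    """Relative CM reconstruction error Delta = |c~ - c| / |c| * 100 (percent)."""
    c = np.asarray(c, dtype=float).ravel()
    c_tilde = np.asarray(c_tilde, dtype=float).ravel()
    if c.shape != c_tilde.shape:
        raise ValueError("vectors must have equal length")
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("reference CM has zero norm; Delta undefined")
    return float(np.linalg.norm(c_tilde - c) / norm * 100.0)


@dataclass(frozen=True)
class ReconstructionReport:
    """Outcome of comparing a decoded CM against the original molecule."""

    composition_correct: bool
    delta_percent: float
    rmsd: float | None = None  # angstrom; present only when composition is correct
    reconstructed: Molecule | None = None

    def __post_init__(self):
        if self.delta_percent < 0:
            raise ValueError("delta_percent must be nonnegative")
        if self.rmsd is not None and self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")


def evaluate_reconstruction(
    original: Molecule,
    original_padded: PaddedCM,
    decoded_vector: np.ndarray,
    allow_reflection: bool = True,
) -> ReconstructionReport:
    """Score a decoded CM vector: Delta always; RMSD when composition matches.

    Callers branch on composition first; RMSD is undefined across compositions.
    A decoded matrix whose occupied off-diagonals are nonpositive cannot be
    inverted and is reported as an incorrect reconstruction.
    """
    decoded = PaddedCM(unflatten_upper(decoded_vector), original_padded.layout)
    delta = relative_cm_error(original_padded.vector, decoded.vector)
    try:
        rec = reconstruct_molecule(decoded)
    except InvalidMatrixError:
        return ReconstructionReport(False, delta)
    if sorted(rec.species) != sorted(original.species):
        return ReconstructionReport(False, delta, reconstructed=rec)
    # both molecules are in canonical slot order, so correspondence is by index
    canonical = reconstruct_molecule(original_padded)
    rmsd = heavy_atom_rmsd(canonical, rec, allow_reflection=allow_reflection)
    return ReconstructionReport(True, delta, rmsd, rec)
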