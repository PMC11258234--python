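"""Geodesic interpolation of transition geometries between isomers.

A path between two molecules is represented by property-space points
{y_0, ..., y_N} whose latent images z_i = mu_psi(y_i) are obtained through
the property encoder. Starting from the linear interpolation in property
space, the interior points are optimized by gradient descent (with
backtracking) on

    L = sum_i || z_{i+1} - z_i ||^2  +  eps_reg * sum_i || y_{i+1} - y_i ||^2

so the path becomes a geodesic of the metric induced by the latent encoding;
the small eps_reg term keeps the path continuous in property space. Endpoints
stay fixed, and optimization stops once the gradient norm drops below the
tolerance (default 1e-4). Decoded structures along the path serve as initial
guesses for external transition-path refinement, exported as an XYZ sequence.

Because the Coulomb-matrix representation cannot distinguish enantiomers,
endpoint pairs should first pass ``mirror_image_check``: a pair that is
identical up to reflection only would be seen as the same molecule.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .coulomb import heavy_atom_rmsd
from .io import write_xyz
from .molecule import Molecule


def mirror_image_check(a: Molecule, b: Molecule, tol: float = 1e-2) -> bool:
    """True iff a and b form an enantiomeric (mirror-image) pair.

    That is: reflection-allowed RMSD < tol but reflection-forbidden RMSD >= tol.
    Achiral pairs and identical molecules return False. Raises on composition
    mismatch.
    """
    with_reflection = heavy_atom_rmsd(a, b, allow_reflection=True)
    without = heavy_atom_rmsd(a, b, allow_reflection=False)
    return bool(with_reflection < tol <= without)


@dataclass
class GeodesicPath:
    """Property-space path with its latent image and decoded structures.

    ``Y`` holds raw-unit property points, rows 0 and N being the fixed
    endpoints. ``Z`` are the property-encoder means, ``structures`` the decoded
    molecules (None where decoding fails), ``loss_history`` the accepted-step
    losses (non-increasing), and ``converged`` whether the gradient-norm
    tolerance was met.
    """

    Y: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    structures: list = field(repr=False)
    loss_history: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_segments(self) -> int:
        return self.Y.shape[0] - 1


def _decode_structures(model, Y, layout):
    out = []
    for y in Y:
        try:
            _, mol = model.property_to_structure(y, layout)
        except Exception:
            mol = None
        out.append(mol)
    return out


def init_linear_path(model, y_start, y_end, n_segments=6, layout=None) -> GeodesicPath:
    """Linear interpolation y_i = y_start + (i/N)(y_end - y_start), i = 0..N."""
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    y_start = np.asarray(y_start, dtype=float)
    y_end = np.asarray(y_end, dtype=float)
    t = np.linspace(0.0, 1.0, n_segments + 1)[:, None]
    Y = (1.0 - t) * y_start + t * y_end
    Z, _ = model.encode_properties(Y)
    structures = _decode_structures(model, Y, layout) if layout is not None else []
    return GeodesicPath(Y, Z, structures)


def geodesic_loss(model, Y, eps_reg=1e-2):
    """Loss L and its gradient with respect to the path points.

    The latent term is differentiated through the property encoder by
    reverse-mode; endpoint gradients are zeroed (endpoints are fixed).
    Property distances enter in standardized units so eps_reg is
    scale-meaningful.
    """
    Y = np.asarray(Y, dtype=float)
    Ys = (Y - model.prop_mean_) / model.prop_scale_
    Z, cache = model.property_encoder_.forward(Ys, want_cache=True)
    dz = np.diff(Z, axis=0)
    dy = np.diff(Ys, axis=0)
    loss = float((dz ** 2).sum() + eps_reg * (dy ** 2).sum())
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite geodesic loss")

    # d loss / d z_i for the chain sum, then pull back through the encoder
    g_z = np.zeros_like(Z)
    g_z[:-1] -= 2.0 * dz
    g_z[1:] += 2.0 * dz
    g_ys, _ = model.property_encoder_.backward(cache, g_z)
    g_ys[:-1] -= 2.0 * eps_reg * dy
    g_ys[1:] += 2.0 * eps_reg * dy
    g_ys[0] = 0.0
    g_ys[-1] = 0.0
    # gradient is reported in standardized property units, matching the
    # coordinates in which the descent steps and the tolerance are measured
    return loss, g_ys


def optimize_path(model, path: GeodesicPath, eps_reg=1e-2, step=1e-2,
                  tol=1e-4, max_iter=5000, layout=None) -> GeodesicPath:
    """Gradient descent with backtracking on the interior points.

    Step lengths are chosen by the Barzilai-Borwein rule (falling back to
    ``step``), halved until the loss does not increase, so accepted losses are
    monotone. Steps are measured in standardized property units. Terminates when the
    gradient norm falls below ``tol`` (converged) or after ``max_iter``
    iterations (flagged unconverged); accepted-step losses are monotone
    non-increasing. Final structures are re-decoded when a layout is given.
    """
    Y = path.Y.copy()
    y0, yN = Y[0].copy(), Y[-1].copy()
    loss, grad = geodesic_loss(model, Y, eps_reg)
    history = [loss]
    converged = np.linalg.norm(grad) < tol
    it = 0
    prev_ys = prev_grad = None
    while not converged and it < max_iter:
        # Barzilai-Borwein step from the previous accepted move, falling back
        # to the base step; backtracking keeps accepted losses non-increasing
        trial_step = step
        ys = (Y - model.prop_mean_) / model.prop_scale_
        if prev_ys is not None:
            s = (ys - prev_ys).ravel()
            g_diff = (grad - prev_grad).ravel()
            denom = float(s @ g_diff)
            if denom > 0 and np.isfinite(denom):
                trial_step = float(s @ s) / denom
        for _ in range(60):
            candidate = Y - trial_step * grad * model.prop_scale_
            candidate[0], candidate[-1] = y0, yN
            new_loss, new_grad = geodesic_loss(model, candidate, eps_reg)
            if new_loss <= loss:
                break
            trial_step *= 0.5
        else:
            break  # no descent direction at machine precision
        prev_ys, prev_grad = ys, grad
        Y, loss, grad = candidate, new_loss, new_grad
        history.append(loss)
        converged = np.linalg.norm(grad) < tol
        it += 1

    Z, _ = model.encode_properties(Y)
    structures = _decode_structures(model, Y, layout) if layout is not None else path.structures
    return GeodesicPath(Y, Z, structures, history, bool(converged))


def export_path(path: GeodesicPath, directory, comment="geodesic step"):
    """One XYZ file per path step plus a JSON metadata record.

    Files are named step_000.xyz .. step_NNN.xyz, suitable as initial guesses
    for nudged-elastic-band refinement by external tools.
    """
    os.makedirs(directory, exist_ok=True)
    written = []
    for i, mol in enumerate(path.structures):
        if mol is None:
            continue
        fname = os.path.join(directory, f"step_{i:03d}.xyz")
        write_xyz(fname, mol, comment=f"{comment} {i}")
        written.append(fname)
    meta = {
        "n_segments": path.n_segments,
        "converged": path.converged,
        "loss_history": [float(v) for v in path.loss_history],
        "files": [os.path.basename(f) for f in written],
    }
    with open(os.path.join(directory, "path.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return written
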