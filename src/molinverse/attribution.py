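"""Gradient attribution maps and latent-space projections.

Which properties drive the reconstructed structure? For a molecule k the
Jacobian J^k = d CM^k / d p of the decoded CM vector with respect to the
(standardized) properties is computed by exact forward-mode differentiation
through the property-encoder mean and the decoder. Averaging the per-property
column norms over a subset B of well-reconstructed molecules gives the
attribution map

    A_j = (1/N) * sum_{k in B} || J^k_{., j} ||_2 ,

optionally normalized by its maximum. The companion PCA projection of the
latent space is used to inspect how the attribution hierarchy organizes the
learned representation and how structure- and property-encoder latents
overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


def property_jacobian(model, y) -> np.ndarray:
    """Jacobian (CM-vector dim x property dim) of decoder o property-encoder.

    ``y`` is one raw property vector; derivatives are taken with respect to
    *standardized* properties so columns are comparable across units.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("property_jacobian expects a single property vector")
    ys = (y - model.prop_mean_) / model.prop_scale_
    j_enc = model.property_encoder_.jacobian(ys)  # (latent, P)
    mu = model.property_encoder_.forward(ys)
    j_dec = model.decoder_.jacobian(mu)  # (D, latent), in scaled CM units
    return model.cm_scale_ * (j_dec @ j_enc)


def select_best_reconstructed(reports, rmsd_cutoff=0.2, count=150):
    """Identifiers of up to ``count`` best-reconstructed molecules.

    ``reports`` is a sequence of (identifier, ReconstructionReport). Only
    composition-correct entries with rmsd <= cutoff qualify; they are returned
    in ascending RMSD order, ties broken by identifier. Warns when fewer than
    ``count`` qualify.
    """
    qualifying = [
        (rep.rmsd, ident)
        for ident, rep in reports
        if rep.composition_correct and rep.rmsd is not None and rep.rmsd <= rmsd_cutoff
    ]
    qualifying.sort()
    if len(qualifying) < count:
        warnings.warn(
            f"only {len(qualifying)} molecules qualify (requested {count})",
            stacklevel=2,
        )
    return [ident for _, ident in qualifying[:count]]


def attribution_map(model, Y_subset, property_names=None, normalize=True) -> pd.DataFrame:
    """Attribution scores A_j averaged over the rows of ``Y_subset``.

    Returns a DataFrame with raw and (optionally) max-normalized scores,
    invariant to the ordering of the subset.
    """
    Y_subset = np.atleast_2d(np.asarray(Y_subset, dtype=float))
    if Y_subset.shape[0] == 0:
        raise ValueError("attribution subset must be nonempty")
    scores = np.zeros(Y_subset.shape[1])
    for y in Y_subset:
        jac = property_jacobian(model, y)
        scores += np.linalg.norm(jac, axis=0)
    scores /= Y_subset.shape[0]
    if property_names is None:
        property_names = [f"p{j}" for j in range(len(scores))]
    out = pd.DataFrame({"property": list(property_names), "attribution": scores})
    if normalize:
        out["attribution_normalized"] = scores / scores.max()
    return out


def latent_projection(latents, n_components=2):
    """Mean-centered PCA scores with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive. Returns (scores, explained_variance_ratio). Degenerate
    covariance reduces the number of components with a warning.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] < n_components:
        raise ValueError("need at least n_components samples")
    max_rank = min(latents.shape[0] - 1, latents.shape[1])
    k = min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(latents)
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    if rank < n_components:
        warnings.warn(
            f"degenerate covariance: only {rank} informative components",
            stacklevel=2,
        )
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1.0
            pca.components_[j] *= -1.0
    return scores, pca.explained_variance_ratio_
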