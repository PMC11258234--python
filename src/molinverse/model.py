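"""Joint VAE + property-encoder model for property-to-structure mapping.

Three networks are trained together on pairs (x, y) of flattened padded
Coulomb matrices x and property vectors y:

* a structure encoder q_phi(z|x), a diagonal Gaussian over the latent z;
* a decoder p_theta(x|z), a unit-variance Gaussian over CM vectors;
* a property encoder p_psi(z|y), a unit-variance Gaussian over latents.

The loss is the beta-weighted ELBO augmented with the property likelihood,

    loss = beta * D_KL[q_phi(z|x) || N(0, I)]
           - E_q[log p_theta(x|z)]
           - tau * E_q[log p_psi(z|y)],

with z drawn through the reparameterization trick. With tau = 0 and beta = 1
this is exactly the standard ELBO. At inference the latent for a property
vector y is the *mean* of p_psi(z|y) (the maximum-likelihood estimator, never
sampled); decoding it and inverting the Coulomb matrix yields the molecule.

An optional masking mode replaces the reconstruction term with a randomly
masked sum (Bernoulli(0.5) rank-one mask scaled by 2, leaky value 0.1 on
padding entries), which biases the model toward treating molecular fragments
independently.

The self-consistency metric ||dz|| = ||z - z~|| compares the property-encoder
latent z with the structure-encoder re-encoding z~ of the decoded CM; it is a
computable proxy for reconstruction quality used to filter generated
molecules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import coulomb
from .coulomb import CoulombLayout, PaddedCM
from .molecule import Molecule
from .nn import MLP, Adam

LOG_2PI = float(np.log(2.0 * np.pi))
_LOGVAR_CLIP = 15.0


def kl_divergence(mu, sigma) -> float:
    """Closed-form D_KL( N(mu, diag sigma^2) || N(0, I) ), summed over dims.

    For batched inputs the mean over the batch is returned.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    per = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - np.log(sigma ** 2))
    if per.ndim <= 1:
        return float(per.sum())
    return float(per.sum(axis=1).mean())


def make_mask(rng: np.random.Generator, target_matrix: np.ndarray) -> np.ndarray:
    """Random rank-one reconstruction mask for one padded CM.

    Draw b ~ Bernoulli(0.5)^L, set M = 2 * outer(b, b), then apply leaky
    masking of the padding: entries where the target CM is zero are set to 0.1.
    """
    target = np.asarray(target_matrix, dtype=float)
    L = target.shape[0]
    b = rng.integers(0, 2, size=L).astype(float)
    mask = 2.0 * np.outer(b, b)
    mask[target == 0] = 0.1
    return mask


def gaussian_nll(x, x_hat, weights=None) -> float:
    """Unit-variance Gaussian negative log likelihood, optionally masked.

    Per element: w * 0.5 * ((x - x_hat)^2 + log 2 pi); summed over elements,
    averaged over the batch. ``weights`` of ones reproduces the unmasked loss
    exactly.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise ValueError("shape mismatch between target and reconstruction")
    per = 0.5 * ((x - x_hat) ** 2 + LOG_2PI)
    if weights is not None:
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        if weights.shape != x.shape:
            raise ValueError("mask shape mismatch")
        per = weights * per
    return float(per.sum(axis=1).mean())


class PropertyStructureVAE(BaseEstimator):
    """Jointly trained VAE + property encoder (scikit-learn estimator).

    Parameters
    ----------
    latent_dim : size of the common latent space.
    encoder_hidden : hidden-layer sizes of the structure encoder; the decoder
        mirrors them in reverse.
    property_hidden : hidden-layer sizes of the property encoder.
    beta, tau : loss weights of the KL and property-likelihood terms.
    masking : enable the random fragment mask during training.
    n_epochs, batch_size, learning_rate : Adam training schedule.
    random_state : seed controlling initialization, shuffling, reparameterized
        sampling and masks; a fixed seed makes training bit-reproducible.

    Fitted attributes
    -----------------
    encoder_, decoder_, property_encoder_ : the trained networks.
    cm_scale_ : global max-abs scale of the training CM vectors.
    prop_mean_, prop_scale_ : per-property z-score statistics (train split only).
    history_ : per-epoch DataFrame of all loss components (train and, when
        validation data is supplied, validation).
    """

    def __init__(
        self,
        latent_dim=32,
        encoder_hidden=(512, 256),
        property_hidden=(128, 128),
        beta=4e-3,
        tau=0.1,
        masking=False,
        n_epochs=800,
        batch_size=128,
        learning_rate=3e-3,
        random_state=0,
    ):
        self.latent_dim = latent_dim
        self.encoder_hidden = encoder_hidden
        self.property_hidden = property_hidden
        self.beta = beta
        self.tau = tau
        self.masking = masking
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------
    # standardization
    # ------------------------------------------------------------------
    def _scale_x(self, X):
        return np.asarray(X, dtype=float) / self.cm_scale_

    def _unscale_x(self, Xs):
        return np.asarray(Xs, dtype=float) * self.cm_scale_

    def _scale_y(self, Y):
        return (np.asarray(Y, dtype=float) - self.prop_mean_) / self.prop_scale_

    # ------------------------------------------------------------------
    # network pieces
    # ------------------------------------------------------------------
    def _encode_scaled(self, Xs):
        out = self.encoder_.forward(Xs)
        k = self.latent_dim
        mu = out[..., :k]
        logvar = np.clip(out[..., k:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, np.exp(0.5 * logvar)

    def encode_structure(self, X):
        """Latent Gaussian (mu, sigma) of CM vectors in raw (unscaled) units."""
        X = np.asarray(X, dtype=float)
        if np.any(~np.isfinite(X)):
            raise ValueError("non-finite CM input")
        return self._encode_scaled(self._scale_x(X))

    def encode_properties(self, Y):
        """Latent Gaussian (mu, sigma) of raw property vectors; sigma == 1.

        The property-encoder likelihood is a unit-variance Gaussian, so the
        returned sigma is identically one.
        """
        Y = np.asarray(Y, dtype=float)
        if np.any(~np.isfinite(Y)):
            raise ValueError("non-finite property input")
        mu = self.property_encoder_.forward(self._scale_y(Y))
        return mu, np.ones_like(mu)

    def decode_latent(self, Z):
        """Decode latents to CM vectors in raw units."""
        return self._unscale_x(self.decoder_.forward(np.asarray(Z, dtype=float)))

    def predict(self, Y):
        """Property -> CM vector: decode the property-encoder mean (no sampling)."""
        mu, _ = self.encode_properties(Y)
        return self.decode_latent(mu)

    # ------------------------------------------------------------------
    # losses
    # ------------------------------------------------------------------
    def joint_loss(self, X, Y, rng=None, z=None, masks=None):
        """Evaluate the joint loss on a batch; returns the components.

        ``z`` overrides the reparameterized sample (for frozen-z checks);
        otherwise eps is drawn from ``rng``. ``masks`` is an optional
        (batch, D) array of per-element reconstruction weights (the upper
        triangle of Eq.-style mask matrices).
        """
        Xs = np.atleast_2d(self._scale_x(X))
        Ys = np.atleast_2d(self._scale_y(Y))
        if Xs.shape[0] != Ys.shape[0]:
            raise ValueError("batch size mismatch between X and Y")
        mu, sigma = self._encode_scaled(Xs)
        if z is None:
            if rng is None:
                rng = np.random.default_rng(0)
            z = mu + sigma * rng.standard_normal(mu.shape)
        else:
            z = np.atleast_2d(np.asarray(z, dtype=float))
        x_hat = self.decoder_.forward(z)
        mu_psi = self.property_encoder_.forward(Ys)
        kl = kl_divergence(mu, sigma)
        recon = gaussian_nll(Xs, x_hat, weights=masks)
        prop = gaussian_nll(z, mu_psi)
        total = self.beta * kl + recon + self.tau * prop
        return {"total": total, "kl": kl, "reconstruction": recon, "property": prop}

    def elbo_loss(self, X, Y=None, rng=None, z=None):
        """The plain ELBO: D_KL + reconstruction NLL (beta and tau ignored)."""
        saved_beta, saved_tau = self.beta, self.tau
        try:
            self.beta, self.tau = 1.0, 0.0
            parts = self.joint_loss(X, np.zeros((np.atleast_2d(X).shape[0],
                                                 self.prop_mean_.size)),
                                    rng=rng, z=z)
        finally:
            self.beta, self.tau = saved_beta, saved_tau
        return parts["kl"] + parts["reconstruction"]

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    def _loss_and_grads(self, Xs, Ys, eps, mask_vecs):
        """Loss components and parameter gradients for one scaled minibatch."""
        B = Xs.shape[0]
        k = self.latent_dim

        enc_out, enc_cache = self.encoder_.forward(Xs, want_cache=True)
        mu = enc_out[:, :k]
        logvar = np.clip(enc_out[:, k:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps

        x_hat, dec_cache = self.decoder_.forward(z, want_cache=True)
        mu_psi, prop_cache = self.property_encoder_.forward(Ys, want_cache=True)

        resid = x_hat - Xs
        w = mask_vecs if mask_vecs is not None else 1.0
        recon = float((0.5 * w * (resid ** 2 + LOG_2PI)).sum() / B)
        kl = float((0.5 * (mu ** 2 + sigma ** 2 - 1.0 - logvar)).sum() / B)
        dz_prop = z - mu_psi
        prop = float((0.5 * (dz_prop ** 2 + LOG_2PI)).sum() / B)
        total = self.beta * kl + recon + self.tau * prop

        # reconstruction -> decoder -> z
        g_xhat = (w * resid) / B
        g_z, dec_grads = self.decoder_.backward(dec_cache, g_xhat)
        # property term -> z and property encoder
        g_z = g_z + self.tau * dz_prop / B
        _, prop_grads = self.property_encoder_.backward(
            prop_cache, -self.tau * dz_prop / B
        )
        # z = mu + sigma*eps and the KL term -> encoder heads
        g_mu = g_z + self.beta * mu / B
        g_logvar = g_z * eps * 0.5 * sigma + self.beta * 0.5 * (sigma ** 2 - 1.0) / B
        _, enc_grads = self.encoder_.backward(
            enc_cache, np.concatenate([g_mu, g_logvar], axis=1)
        )
        grads = enc_grads + dec_grads + prop_grads
        parts = {"total": total, "kl": kl, "reconstruction": recon, "property": prop}
        return parts, grads

    def fit(self, X, Y, X_val=None, Y_val=None):
        """Train on CM vectors X (n, D) and property vectors Y (n, P).

        Standardization statistics are computed from (X, Y) only — pass the
        training split here and the validation split via X_val/Y_val.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2D with matching first dimension")
        rng = np.random.default_rng(self.random_state)

        self.cm_scale_ = float(np.abs(X).max()) or 1.0
        self.prop_mean_ = Y.mean(axis=0)
        self.prop_scale_ = np.maximum(Y.std(axis=0), 1e-8)
        self.n_features_in_ = X.shape[1]
        self.n_properties_in_ = Y.shape[1]

        D, P, k = X.shape[1], Y.shape[1], self.latent_dim
        self.encoder_ = MLP([D, *self.encoder_hidden, 2 * k], rng)
        self.decoder_ = MLP([k, *reversed(tuple(self.encoder_hidden)), D], rng)
        self.property_encoder_ = MLP([P, *self.property_hidden, k], rng)

        Xs, Ys = self._scale_x(X), self._scale_y(Y)
        pad_zero = X == 0  # leaky-mask positions, per sample
        opt = Adam(
            self.encoder_.params + self.decoder_.params + self.property_encoder_.params,
            lr=self.learning_rate,
        )

        iu = np.triu_indices(int(round((np.sqrt(8 * D + 1) - 1) / 2)))
        n = X.shape[0]
        history = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            sums = {"total": 0.0, "kl": 0.0, "reconstruction": 0.0, "property": 0.0}
            nb = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], Ys[idx]
                eps = rng.standard_normal((len(idx), k))
                mask_vecs = None
                if self.masking:
                    b = rng.integers(0, 2, size=(len(idx), iu[0].max() + 1)).astype(float)
                    mask_vecs = 2.0 * b[:, iu[0]] * b[:, iu[1]]
                    mask_vecs[pad_zero[idx]] = 0.1
                parts, grads = self._loss_and_grads(xb, yb, eps, mask_vecs)
                if not np.isfinite(parts["total"]):
                    raise RuntimeError(
                        f"divergent loss at epoch {epoch}: {parts}"
                    )
                opt.step(grads)
                for key in sums:
                    sums[key] += parts[key]
                nb += 1
            row = {"epoch": epoch}
            row.update({f"train_{key}": val / nb for key, val in sums.items()})
            if X_val is not None:
                val_parts = self.joint_loss(
                    X_val, Y_val, rng=np.random.default_rng(self.random_state + 1)
                )
                row.update({f"val_{key}": val for key, val in val_parts.items()})
            history.append(row)
        self.history_ = pd.DataFrame(history)
        return self

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------
    def property_to_structure(self, y, layout: CoulombLayout):
        """Map one property vector to a (PaddedCM, Molecule) pair.

        The latent is the property-encoder mean; the decoded upper triangle is
        mirrored into a symmetric padded CM and inverted through composition
        inference, distance recovery and CMDS.
        """
        vec = self.predict(np.atleast_2d(np.asarray(y, dtype=float)))[0]
        padded = PaddedCM(coulomb.unflatten_upper(vec), layout)
        return padded, coulomb.reconstruct_molecule(padded)

    def self_consistency_delta(self, Y):
        """||dz|| between property latents and re-encoded decoded structures.

        Vectorized over rows of Y; returns a 1D nonnegative array (or a scalar
        for a single vector).
        """
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 1
        mu_psi, _ = self.encode_properties(np.atleast_2d(Y))
        x_hat = self.decoder_.forward(mu_psi)  # scaled space
        mu_tilde, _ = self._encode_scaled(x_hat)
        dz = np.linalg.norm(mu_psi - mu_tilde, axis=1)
        return float(dz[0]) if single else dz
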