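"""Stacked Bayesian (variational) autoencoder for cell compression.

The filtered, scaled matrix is projected to a low-dimensional latent space
(m = 15 by default) by a small VAE trained in two stages with AdamW and SELU
activations:

* **warm-up** — reconstruction loss only, so the model learns a useful code
  before any distributional pressure is applied;
* **variational stage** — reconstruction plus the KL divergence of the
  per-cell posterior N(mu, sigma^2) from the standard-normal prior.

What makes the model "stacked": every forward pass draws several
realizations of the latent code, ``z_r = mu + sigma * eps_r`` with
``eps_r ~ N(0, I)``, and averages the reconstruction loss over them, which
regularises the code beyond a single-sample VAE.  The decoder is shared
across realizations.  At inference time the representation of a cell is the
posterior mean ``mu`` — no sampling — so downstream analyses are
deterministic given a trained model.

The reconstruction term is summed over genes per cell (the standard VAE
likelihood scale) and averaged over cells and realizations; the KL term is
summed over latent dimensions and averaged over cells, with weight 1.0 in
the variational stage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import AdamW, check_finite, lecun_normal, minibatches, selu, selu_grad
from .types import CompressedMatrix, InvalidInputError, ScaledMatrix

logger = logging.getLogger(__name__)

DEFAULT_LATENT_DIM = 15
DEFAULT_HIDDEN = 128
DEFAULT_N_REALIZATIONS = 5
DEFAULT_WARMUP_EPOCHS = 40
DEFAULT_EPOCHS = 200

_LOG_SIG_LO = float(np.log(1e-4))
_LOG_SIG_HI = float(np.log(10.0))


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Differentiable sampling: ``z = mu + sigma * eps`` elementwise.

    ``eps`` is a standard-normal draw of the same shape; gradients flow to
    both ``mu`` and ``sigma``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if mu.shape != sigma.shape or mu.shape != eps.shape:
        raise InvalidInputError(
            f"shape mismatch in reparameterize: mu {mu.shape}, sigma {sigma.shape}, eps {eps.shape}"
        )
    if np.any(sigma < 0):
        raise InvalidInputError("sigma must be nonnegative")
    return mu + sigma * eps


@dataclass
class StackedVAEModel:
    """Trained compression model; ``encode`` maps cells to their posterior means."""

    params: dict[str, np.ndarray]
    latent_dim: int
    n_realizations: int
    gene_ids: list[str] | None = None
    warmup_epochs: int = DEFAULT_WARMUP_EPOCHS
    epochs: int = DEFAULT_EPOCHS
    recon_history: list[float] = field(default_factory=list)
    kl_history: list[float] = field(default_factory=list)

    def _encode_values(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        h1 = selu(v @ p["W1"] + p["b1"])
        mu = h1 @ p["Wm"] + p["bm"]
        ls = np.clip(h1 @ p["Ws"] + p["bs"], _LOG_SIG_LO, _LOG_SIG_HI)
        return mu, np.exp(ls)


def _init_params(g: int, hidden: int, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "W1": lecun_normal(rng, g, hidden),
        "b1": np.zeros(hidden),
        "Wm": lecun_normal(rng, hidden, m),
        "bm": np.zeros(m),
        "Ws": lecun_normal(rng, hidden, m),
        # start sigma well below 1 so early reconstruction is not drowned in noise
        "bs": np.full(m, -2.0),
        "W2": lecun_normal(rng, m, hidden),
        "b2": np.zeros(hidden),
        "W3": lecun_normal(rng, hidden, g),
        "b3": np.zeros(g),
    }


def train_stacked_vae(
    x: ScaledMatrix,
    m: int = DEFAULT_LATENT_DIM,
    warmup_epochs: int = DEFAULT_WARMUP_EPOCHS,
    epochs: int = DEFAULT_EPOCHS,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    hidden: int = DEFAULT_HIDDEN,
    lr: float = 3e-3,
    weight_decay: float = 1e-2,
    batch_size: int | None = None,
    kl_weight: float = 1.0,
) -> StackedVAEModel:
    """Two-stage minibatch training of the stacked VAE.

    Epochs ``< warmup_epochs`` optimise reconstruction only; the remaining
    epochs add ``kl_weight`` times the KL penalty.  Per batch the
    reconstruction averages over ``n_realizations`` draws of ``z``.
    Deterministic given ``(x, seed)``.
    """
    v = x.values
    n, g = v.shape
    if n < 2:
        raise InvalidInputError("need at least 2 cells")
    if warmup_epochs > epochs:
        raise InvalidInputError("warmup_epochs cannot exceed total epochs")
    if batch_size is None:
        batch_size = min(n, 128)
    R = int(n_realizations)
    rng = np.random.default_rng(seed)
    # training runs in float32 for speed; the published representation
    # (posterior means from ``encode``) is cast back to float64
    v = v.astype(np.float32)
    params = _init_params(g, hidden, m, rng)
    params = {k: p.astype(np.float32) for k, p in params.items()}
    opt = AdamW(params, lr=lr, weight_decay=weight_decay,
                decay={"W1", "Wm", "Ws", "W2", "W3"})

    recon_hist: list[float] = []
    kl_hist: list[float] = []
    for epoch in range(epochs):
        beta = 0.0 if epoch < warmup_epochs else kl_weight
        ep_recon, ep_kl, ep_batches = 0.0, 0.0, 0
        for idx in minibatches(n, batch_size, rng):
            xb = v[idx]
            b = xb.shape[0]

            # ---- forward ----
            h1_pre = xb @ params["W1"] + params["b1"]
            h1 = selu(h1_pre)
            mu = h1 @ params["Wm"] + params["bm"]
            ls_raw = h1 @ params["Ws"] + params["bs"]
            ls = np.clip(ls_raw, _LOG_SIG_LO, _LOG_SIG_HI)
            sig = np.exp(ls)
            eps = rng.standard_normal((R, b, m)).astype(np.float32)
            z = (mu[None] + sig[None] * eps).reshape(R * b, m)
            h2_pre = z @ params["W2"] + params["b2"]
            h2 = selu(h2_pre)
            xh = h2 @ params["W3"] + params["b3"]
            x_rep = np.broadcast_to(xb, (R, b, g)).reshape(R * b, g)
            diff = xh - x_rep
            recon = float(np.sum(diff * diff) / (R * b))  # per-cell gene-summed MSE
            kl_terms = 0.5 * (mu * mu + sig * sig - 1.0 - 2.0 * ls)
            kl = float(np.sum(kl_terms) / b)
            check_finite(recon + kl, epoch=epoch, seed=seed, what="stacked VAE")

            # ---- backward ----
            dxh = 2.0 * diff / (R * b)
            dh2 = (dxh @ params["W3"].T) * selu_grad(h2_pre)
            dz = (dh2 @ params["W2"].T).reshape(R, b, m)
            dmu = dz.sum(axis=0)
            dsig = (dz * eps).sum(axis=0)
            if beta:
                dmu = dmu + beta * mu / b
                dls_kl = beta * (sig * sig - 1.0) / b
            else:
                dls_kl = 0.0
            dls = (dsig * sig + dls_kl) * ((ls_raw >= _LOG_SIG_LO) & (ls_raw <= _LOG_SIG_HI))
            dh1 = (dmu @ params["Wm"].T + dls @ params["Ws"].T) * selu_grad(h1_pre)
            grads = {
                "W3": h2.T @ dxh, "b3": dxh.sum(axis=0),
                "W2": z.T @ dh2, "b2": dh2.sum(axis=0),
                "Wm": h1.T @ dmu, "bm": dmu.sum(axis=0),
                "Ws": h1.T @ dls, "bs": dls.sum(axis=0),
                "W1": xb.T @ dh1, "b1": dh1.sum(axis=0),
            }
            opt.step(grads)
            ep_recon += recon
            ep_kl += kl
            ep_batches += 1
        recon_hist.append(ep_recon / ep_batches)
        kl_hist.append(ep_kl / ep_batches)
    logger.info(
        "stacked VAE: recon %.4f -> %.4f (warm-up ends %.4f), KL %.4f at end",
        recon_hist[0], recon_hist[-1],
        recon_hist[min(warmup_epochs, epochs) - 1] if warmup_epochs else recon_hist[0],
        kl_hist[-1],
    )
    return StackedVAEModel(
        params=params, latent_dim=m, n_realizations=R,
        gene_ids=list(x.gene_ids), warmup_epochs=warmup_epochs, epochs=epochs,
        recon_history=recon_hist, kl_history=kl_hist,
    )


def encode(model: StackedVAEModel, x: ScaledMatrix) -> CompressedMatrix:
    """Deterministic compression: posterior mean ``mu`` for every cell."""
    if model.gene_ids is not None and list(x.gene_ids) != list(model.gene_ids):
        missing = sorted(set(model.gene_ids) - set(x.gene_ids))
        raise InvalidInputError(
            f"gene set mismatch with trained model; missing {len(missing)} genes, "
            f"e.g. {missing[:5]}"
        )
    mu, _ = model._encode_values(x.values)
    return CompressedMatrix(mu, list(x.cell_ids))


def compress(
    x: ScaledMatrix,
    m: int = DEFAULT_LATENT_DIM,
    seed: int = 0,
    **train_kwargs,
) -> tuple[CompressedMatrix, StackedVAEModel]:
    """Train a stacked VAE on ``x`` and return the compressed matrix."""
    model = train_stacked_vae(x, m=m, seed=seed, **train_kwargs)
    return encode(model, x), model
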