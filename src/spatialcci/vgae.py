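"""Variational graph autoencoder for cell-cell interaction networks.

The model treats the CCI network as a link-prediction problem: cells (or
genes) are nodes, the observed interaction graph is the adjacency matrix A,
and the expression matrix X provides node features. A three-layer GCN
encoder maps (X, A-hat) to per-node Gaussian latents q(z|x) = N(mu, sigma^2),
a sample Z = mu + exp(log sigma) * eps is decoded by the inner-product
decoder A' = sigmoid(Z Z^T), and training minimizes

    L = L_recon + beta * L_KL  (+ adv_weight * L_gen)

where L_recon is (positively weighted) binary cross-entropy of A' against A,
L_KL is the Gaussian KL to the standard-normal prior, and the optional
adversarial term trains a small MLP discriminator to tell encoder latents
from prior draws, pushing the aggregate posterior toward N(0, I).

Everything is dense numpy with hand-derived gradients and a from-scratch
Adam optimizer: the graphs this package targets (hundreds to a few thousand
nodes) train full-batch in seconds on one CPU.

API shape follows the statsmodels convention: ``VGAE(X, adjacency)`` is the
model specification; ``fit()`` returns a :class:`VGAEResults` carrying the
trained parameters, latents, reconstruction and loss history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spatial_graph import Adjacency

_LOGSIG_CLIP = 10.0  # |log sigma| cap; gradient is masked where active


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


@dataclass
class EncoderParams:
    """GCN encoder weights: a shared ReLU trunk and linear mu / log-sigma heads.

    ``trunk[l]`` is W^(l) of the l-th propagation H^(l+1) = ReLU(A-hat H^(l) W^(l));
    ``w_mu`` and ``w_logsig`` are the final heads mu = A-hat H W_mu,
    log sigma = A-hat H W_logsig.
    """

    trunk: list[np.ndarray]
    w_mu: np.ndarray
    w_logsig: np.ndarray

    def __post_init__(self) -> None:
        dims = [w.shape for w in self.trunk] + [self.w_mu.shape, self.w_logsig.shape]
        for a, b in zip(dims[:-2], dims[1:-1]):
            if a[1] != b[0]:
                raise ValueError(f"incompatible layer dims {a} -> {b}")
        if self.w_mu.shape != self.w_logsig.shape:
            raise ValueError("mu and log-sigma heads must share shape")

    def flat(self) -> list[np.ndarray]:
        return [*self.trunk, self.w_mu, self.w_logsig]

    @classmethod
    def init(
        cls,
        n_features: int,
        hidden_dims: tuple[int, ...],
        latent_dim: int,
        rng: np.random.Generator,
    ) -> "EncoderParams":
        dims = [n_features, *hidden_dims]
        trunk = [_glorot(rng, dims[i], dims[i + 1]) for i in range(len(hidden_dims))]
        return cls(
            trunk=trunk,
            w_mu=_glorot(rng, dims[-1], latent_dim),
            w_logsig=_glorot(rng, dims[-1], latent_dim),
        )


@dataclass
class LatentEncoding:
    """Per-node Gaussian latents and the reparameterized sample."""

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray | None = None
    epsilon: np.ndarray | None = None


@dataclass
class LossTerms:
    recon: float
    kl: float
    beta: float = 1.0
    disc: float = 0.0
    gen: float = 0.0
    adv_weight: float = 0.0

    @property
    def total(self) -> float:
        return self.recon + self.beta * self.kl + self.adv_weight * self.gen


@dataclass
class ReconstructedAdjacency:
    """Edge-probability matrix sigmoid(Z Z^T); diagonal present but ignored."""

    probs: np.ndarray
    threshold: float = 0.5

    def binarize(self, threshold: float | None = None) -> np.ndarray:
        t = self.threshold if threshold is None else threshold
        out = (self.probs >= t).astype(float)
        np.fill_diagonal(out, 0)
        return out

    def to_thresholded_mtx(self, path, threshold: float | None = None) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(self.binarize(threshold)))

    def ranked_edges(self, node_ids: list[str] | None = None) -> pd.DataFrame:
        n = self.probs.shape[0]
        ids = node_ids or [str(i) for i in range(n)]
        ii, jj = np.triu_indices(n, k=1)
        df = pd.DataFrame(
            {
                "node_i": [ids[i] for i in ii],
                "node_j": [ids[j] for j in jj],
                "probability": self.probs[ii, jj],
            }
        )
        return df.sort_values("probability", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Forward passes (module-level, usable without the model object)
# ---------------------------------------------------------------------------

def encode(X: np.ndarray, A_hat: np.ndarray, params: EncoderParams) -> LatentEncoding:
    """Deterministic encoder forward pass: mu and log sigma (no sampling)."""
    X = np.asarray(X, float)
    if X.shape[0] != A_hat.shape[0]:
        raise ValueError(
            f"feature rows ({X.shape[0]}) != adjacency size ({A_hat.shape[0]})"
        )
    h = X
    for l, w in enumerate(params.trunk):
        if h.shape[1] != w.shape[0]:
            raise ValueError(f"trunk layer {l}: input dim {h.shape[1]} != {w.shape[0]}")
        h = np.maximum(A_hat @ h @ w, 0.0)
    m = A_hat @ h
    mu = m @ params.w_mu
    log_sigma = np.clip(m @ params.w_logsig, -_LOGSIG_CLIP, _LOGSIG_CLIP)
    return LatentEncoding(mu=mu, log_sigma=log_sigma)


def reparameterize(
    mu: np.ndarray, log_sigma: np.ndarray, seed: int | np.random.Generator = 0
) -> LatentEncoding:
    """Z = mu + exp(log sigma) * eps with eps ~ N(0, I); seed-reproducible."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(mu.shape)
    z = mu + np.exp(log_sigma) * eps
    return LatentEncoding(mu=mu, log_sigma=log_sigma, z=z, epsilon=eps)


def decode(z: np.ndarray) -> ReconstructedAdjacency:
    """Inner-product decoder: probs[i, j] = sigmoid(z_i . z_j)."""
    return ReconstructedAdjacency(_sigmoid(z @ z.T))


def reconstruction_loss(
    A: Adjacency | np.ndarray,
    probs: ReconstructedAdjacency | np.ndarray,
    pos_weight: float | str = 1.0,
) -> float:
    """Mean binary cross-entropy of edge probabilities against A, diagonal
    excluded.

    ``pos_weight`` multiplies the positive-class term; ``"auto"`` uses the
    sparse-graph ratio (#off-diagonal non-edges / #edges counted directed).
    """
    a = A.matrix if isinstance(A, Adjacency) else np.asarray(A, float)
    p = probs.probs if isinstance(probs, ReconstructedAdjacency) else np.asarray(probs, float)
    mask = 1.0 - np.eye(a.shape[0])
    if pos_weight == "auto":
        n_pos = (a * mask).sum()
        pos_weight = (mask.sum() - n_pos) / max(n_pos, 1.0)
    p = np.clip(p, 1e-10, 1 - 1e-10)
    ll = -(pos_weight * a * np.log(p) + (1 - a) * np.log(1 - p))
    return float((ll * mask).sum() / mask.sum())


def kl_loss(mu: np.ndarray, log_sigma: np.ndarray) -> float:
    """Gaussian KL(q || N(0, I)), summed over latent dims, averaged over nodes:
    (1/n) sum_i 1/2 sum_j (mu_ij^2 + sigma_ij^2 - 1 - 2 log sigma_ij)."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma shapes differ")
    s2 = np.exp(2 * log_sigma)
    return float(0.5 * (mu**2 + s2 - 1.0 - 2.0 * log_sigma).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# Adversarial regularizer: 2-layer MLP discriminator with logistic loss
# ---------------------------------------------------------------------------

@dataclass
class DiscriminatorParams:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    @classmethod
    def init(cls, latent_dim: int, hidden: int, rng: np.random.Generator) -> "DiscriminatorParams":
        return cls(
            w1=_glorot(rng, latent_dim, hidden),
            b1=np.zeros(hidden),
            w2=_glorot(rng, hidden, 1),
            b2=0.0,
        )

    def flat(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, np.atleast_1d(np.asarray(self.b2, float))]


def _disc_forward(z: np.ndarray, dp: DiscriminatorParams):
    h_pre = z @ dp.w1 + dp.b1
    h = np.maximum(h_pre, 0.0)
    logit = (h @ dp.w2).ravel() + dp.b2
    return h_pre, h, logit


def _disc_bce_grads(z, labels, dp: DiscriminatorParams):
    """Mean logistic loss of D(z) against labels, with grads wrt disc params
    and wrt the input z."""
    n = z.shape[0]
    h_pre, h, logit = _disc_forward(z, dp)
    p = _sigmoid(logit)
    loss = float(-(labels * np.log(np.clip(p, 1e-12, 1)) +
                   (1 - labels) * np.log(np.clip(1 - p, 1e-12, 1))).mean())
    dlogit = (p - labels) / n
    gw2 = h.T @ dlogit[:, None]
    gb2 = float(dlogit.sum())
    dh = np.outer(dlogit, dp.w2.ravel()) * (h_pre > 0)
    gw1 = z.T @ dh
    gb1 = dh.sum(axis=0)
    dz = dh @ dp.w1.T
    return loss, (gw1, gb1, gw2, gb2), dz


def adversarial_step(
    z: np.ndarray,
    prior_samples: np.ndarray,
    disc_params: DiscriminatorParams,
    optimizer: "Adam | None" = None,
    lr: float = 0.01,
):
    """One discriminator update (prior = real, z = fake) followed by the
    generator-loss evaluation D(z) vs label 1.

    Returns (disc_loss, gen_loss, dgen_dz, disc_params); the caller adds
    ``adv_weight * dgen_dz`` to the encoder's dL/dZ.
    """
    if z.shape != prior_samples.shape:
        raise ValueError("z and prior_samples must have the same shape")
    both = np.vstack([prior_samples, z])
    labels = np.concatenate([np.ones(len(prior_samples)), np.zeros(len(z))])
    disc_loss, grads, _ = _disc_bce_grads(both, labels, disc_params)
    gw1, gb1, gw2, gb2 = grads
    if optimizer is None:
        optimizer = Adam([disc_params.w1, disc_params.b1, disc_params.w2], lr=lr)
    updates = optimizer.step([gw1, gb1, gw2])
    disc_params.w1 += updates[0]
    disc_params.b1 += updates[1]
    disc_params.w2 += updates[2]
    disc_params.b2 -= lr * gb2
    gen_loss, _, dgen_dz = _disc_bce_grads(z, np.ones(len(z)), disc_params)
    return disc_loss, gen_loss, dgen_dz, disc_params


class Adam:
    """Minimal Adam optimizer over a list of same-shaped parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(np.atleast_1d(p), dtype=float) for p in params]
        self.v = [np.zeros_like(np.atleast_1d(p), dtype=float) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> list[np.ndarray]:
        """Return the parameter increments for the given gradients."""
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            g = np.atleast_1d(np.asarray(g, float))
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(-self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class VGAE:
    """Variational graph autoencoder model specification.

    Parameters
    ----------
    X : (n, f) array or ExpressionMatrix-like with ``.values``
        Node features.
    adjacency : Adjacency
        Observed (training) interaction graph.
    hidden_dims : tuple of int
        Widths of the three ReLU GCN trunk layers.
    latent_dim : int
        Latent dimensionality of mu / log sigma.
    pos_weight : "auto" or float
        Positive-class weight in the reconstruction BCE; "auto" uses the
        non-edge/edge ratio, appropriate for sparse graphs.
    """

    def __init__(
        self,
        X,
        adjacency: Adjacency,
        hidden_dims: tuple[int, ...] = (64, 64, 32),
        latent_dim: int = 16,
        pos_weight: float | str = "auto",
    ):
        self.X = np.asarray(getattr(X, "values", X), dtype=float)
        self.adjacency = adjacency
        if self.X.shape[0] != adjacency.n_nodes:
            raise ValueError(
                f"feature rows ({self.X.shape[0]}) != graph nodes ({adjacency.n_nodes})"
            )
        self.A_hat = adjacency.normalized
        self.hidden_dims = tuple(hidden_dims)
        self.latent_dim = int(latent_dim)
        mask = 1.0 - np.eye(adjacency.n_nodes)
        if pos_weight == "auto":
            n_pos = (adjacency.matrix * mask).sum()
            pos_weight = (mask.sum() - n_pos) / max(n_pos, 1.0)
        self.pos_weight = float(pos_weight)
        self._mask = mask

    # -- gradient core -----------------------------------------------------

    def _forward_backward(self, params: EncoderParams, eps: np.ndarray,
                          beta: float, dz_extra: np.ndarray | None = None):
        """Full forward pass and hand-derived backward pass.

        Returns (recon, kl, grads-in-params-order, latent, probs).
        """
        A, A_hat, X = self.adjacency.matrix, self.A_hat, self.X
        n = A.shape[0]
        mask, w_pos = self._mask, self.pos_weight

        # forward
        pre, acts, m_in = [], [X], []
        h = X
        for w in params.trunk:
            m = A_hat @ h
            m_in.append(m)
            p = m @ w
            pre.append(p)
            h = np.maximum(p, 0.0)
            acts.append(h)
        m_last = A_hat @ h
        mu = m_last @ params.w_mu
        ls_raw = m_last @ params.w_logsig
        ls = np.clip(ls_raw, -_LOGSIG_CLIP, _LOGSIG_CLIP)
        sig = np.exp(ls)
        z = mu + sig * eps
        logits = z @ z.T
        probs = _sigmoid(logits)

        # losses (diagonal excluded, mean over off-diagonal entries)
        pc = np.clip(probs, 1e-10, 1 - 1e-10)
        recon = float(
            (-(w_pos * A * np.log(pc) + (1 - A) * np.log(1 - pc)) * mask).sum()
            / mask.sum()
        )
        kl = kl_loss(mu, ls)

        # backward: d recon / d logits
        dS = mask * ((w_pos * A + (1 - A)) * probs - w_pos * A) / mask.sum()
        dz = (dS + dS.T) @ z
        if dz_extra is not None:
            dz = dz + dz_extra
        dmu = dz + beta * mu / n
        dls = dz * sig * eps + beta * (np.exp(2 * ls) - 1.0) / n
        dls = dls * (np.abs(ls_raw) < _LOGSIG_CLIP)  # clip mask

        g_wmu = (A_hat @ acts[-1]).T @ dmu
        g_wls = (A_hat @ acts[-1]).T @ dls
        dm_last = dmu @ params.w_mu.T + dls @ params.w_logsig.T
        dh = A_hat @ dm_last  # A_hat symmetric
        g_trunk = [None] * len(params.trunk)
        for l in range(len(params.trunk) - 1, -1, -1):
            dp = dh * (pre[l] > 0)
            g_trunk[l] = m_in[l].T @ dp
            if l > 0:
                dh = A_hat @ (dp @ params.trunk[l].T)
        grads = [*g_trunk, g_wmu, g_wls]
        latent = LatentEncoding(mu=mu, log_sigma=ls, z=z, epsilon=eps)
        return recon, kl, grads, latent, ReconstructedAdjacency(probs)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        epochs: int = 30,
        lr: float = 0.01,
        beta: float = 1.0,
        adv_weight: float = 1.0,
        disc_hidden: int = 64,
        seed: int = 0,
        callback=None,
    ) -> "VGAEResults":
        """Full-batch Adam training; deterministic for a fixed seed.

        The run seed controls weight initialization, the per-epoch eps draws
        and (when ``adv_weight > 0``) the discriminator stream; the
        adversarial stream is independent, so ``adv_weight=0`` reproduces a
        plain VGAE trajectory exactly.
        """
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng([int(seed), 0])
        params = EncoderParams.init(self.X.shape[1], self.hidden_dims, self.latent_dim, rng)
        opt = Adam(params.flat(), lr=lr)

        disc = disc_opt = adv_rng = None
        if adv_weight > 0:
            adv_rng = np.random.default_rng([int(seed), 1])
            disc = DiscriminatorParams.init(self.latent_dim, disc_hidden, adv_rng)
            disc_opt = Adam([disc.w1, disc.b1, disc.w2], lr=lr)

        history: list[LossTerms] = []
        latent = recon_adj = None
        for epoch in range(1, epochs + 1):
            eps = rng.standard_normal((self.X.shape[0], self.latent_dim))
            dz_extra = None
            disc_loss = gen_loss = 0.0
            if adv_weight > 0:
                enc = encode(self.X, self.A_hat, params)
                z_now = enc.mu + np.exp(enc.log_sigma) * eps
                prior = adv_rng.standard_normal(z_now.shape)
                disc_loss, gen_loss, dgen_dz, disc = adversarial_step(
                    z_now, prior, disc, optimizer=disc_opt, lr=lr
                )
                dz_extra = adv_weight * dgen_dz
            recon, kl, grads, latent, recon_adj = self._forward_backward(
                params, eps, beta, dz_extra
            )
            terms = LossTerms(recon=recon, kl=kl, beta=beta,
                              disc=disc_loss, gen=gen_loss, adv_weight=adv_weight)
            if not np.isfinite(terms.total):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            history.append(terms)
            if callback is not None:
                callback(epoch, terms, latent, recon_adj)
            flat = params.flat()
            for p, upd in zip(flat, opt.step(grads)):
                p += upd
        return VGAEResults(self, params, latent, recon_adj, history,
                           config=dict(epochs=epochs, lr=lr, beta=beta,
                                       adv_weight=adv_weight, seed=int(seed),
                                       hidden_dims=self.hidden_dims,
                                       latent_dim=self.latent_dim,
                                       pos_weight=self.pos_weight))


class VGAEResults:
    """Fit results: trained encoder, final latents, reconstruction, history."""

    def __init__(self, model: VGAE, params: EncoderParams, latent: LatentEncoding,
                 reconstruction: ReconstructedAdjacency,
                 history: list[LossTerms], config: dict):
        self.model = model
        self.params = params
        self.latent = latent
        self.reconstruction = reconstruction
        self.history = history
        self.config = config

    @property
    def loss_history(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": range(1, len(self.history) + 1),
                "recon": [t.recon for t in self.history],
                "kl": [t.kl for t in self.history],
                "disc": [t.disc for t in self.history],
                "gen": [t.gen for t in self.history],
                "total": [t.total for t in self.history],
            }
        )

    def predict_proba(self, use_mean: bool = True) -> ReconstructedAdjacency:
        """Edge probabilities from the trained encoder; ``use_mean`` decodes
        mu directly (the conventional deterministic read-out)."""
        enc = encode(self.model.X, self.model.A_hat, self.params)
        z = enc.mu if use_mean else self.latent.z
        return decode(z)

    def save(self, path) -> None:
        """Write a versioned JSON checkpoint (weights + config)."""
        import json

        payload = {
            "format": "spatialcci-vgae-checkpoint",
            "version": 1,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in self.config.items()},
            "trunk": [w.tolist() for w in self.params.trunk],
            "w_mu": self.params.w_mu.tolist(),
            "w_logsig": self.params.w_logsig.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load_params(path) -> tuple[EncoderParams, dict]:
        """Read a checkpoint back into (EncoderParams, config)."""
        import json

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "spatialcci-vgae-checkpoint":
            raise ValueError(f"{path} is not a spatialcci checkpoint")
        params = EncoderParams(
            trunk=[np.asarray(w, float) for w in payload["trunk"]],
            w_mu=np.asarray(payload["w_mu"], float),
            w_logsig=np.asarray(payload["w_logsig"], float),
        )
        return params, payload["config"]

    def summary(self) -> str:
        c, h = self.config, self.history
        lines = [
            "Variational Graph Autoencoder Results",
            "=" * 46,
            f"nodes {self.model.X.shape[0]:>6d}   features {self.model.X.shape[1]:>6d}",
            f"edges {self.model.adjacency.n_edges:>6d}   latent   {c['latent_dim']:>6d}",
            f"hidden dims    {c['hidden_dims']}",
            f"epochs {c['epochs']:>5d}   lr {c['lr']:<8g} beta {c['beta']:<6g}",
            f"adv_weight {c['adv_weight']:<6g} pos_weight {c['pos_weight']:.3f}",
            f"seed {c['seed']}",
            "-" * 46,
            f"final recon loss {h[-1].recon:10.4f}",
            f"final KL loss    {h[-1].kl:10.4f}",
            f"final total      {h[-1].total:10.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
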