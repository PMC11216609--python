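"""Amortized variational inference and the training loop.

Each document's topic proportions get a logistic-normal variational
posterior: an inference network maps the normalized bag-of-words vector
(concatenated with the slice's prior mean eta_t) to a Gaussian mean and
scale; a reparameterized sample pushed through softmax lands on the
K-simplex.  The per-batch evidence lower bound is

    ELBO = sum_d [ sum_w count_dw * log(sum_k theta_dk beta_tkw) ]
           - sum_d KL( N(mu_d, diag sigma_d^2) || N(eta_t, eps^2 I) )

scaled by N_t / batch_size so every minibatch step is an unbiased estimate
of the full-data objective.  Topic embeddings alpha and prior means eta are
point-estimated (MAP): their Gaussian random-walk priors enter the loss as a
quadratic dynamics penalty.  A DETM-style amortized posterior for eta (a
recurrent network over per-slice mean BOW summaries) is available behind
``TrainConfig.eta_posterior = "amortized"``.

Gradients are computed with autograd; the optimizer is Adam with a small
weight decay.  All randomness flows from a single seed, so a run is
reproducible bit for bit.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp
from autograd import value_and_grad

from .corpus_io import TimeSlicedCorpus
from .generative import ModelParameters, compute_beta, softmax
from .losses import (
    ClassifierHead,
    classifier_forward,
    cross_entropy_from_scores,
    topic_diversity_loss,
    total_objective,
)

logger = logging.getLogger(__name__)

_LOG_EPS = 1e-10  # numeric floor inside the reconstruction log


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    Defaults follow the reference setting for grant-corpus experiments:
    learning rate 1e-3 with a small weight decay, batch size 1024, dropout
    0.1, 500 epochs, lambda1 = 1, lambda2 = 0.5 and eps = delta = gamma =
    0.01.  ``K`` (topics) and ``L`` (embedding dimension) must match the
    word-embedding table when one is supplied.
    """

    K: int = 50
    L: int = 200
    learning_rate: float = 1e-3
    weight_decay: float = 1.2e-6
    batch_size: int = 1024
    dropout: float = 0.1
    epochs: int = 500
    lambda1: float = 1.0
    lambda2: float = 0.5
    eps: float = 0.01
    delta: float = 0.01
    gamma: float = 0.01
    hidden: int = 256
    head_hidden: int = 64
    n_mc: int = 1
    seed: int = 0
    eta_posterior: str = "map"  # "map" or "amortized"
    freeze_embeddings: bool = False
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.K < 2 or self.L < 1:
            raise ValueError("K must be >= 2 and L >= 1")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.eps, self.delta, self.gamma) <= 0:
            raise ValueError("eps, delta and gamma must be positive")
        if self.eta_posterior not in ("map", "amortized"):
            raise ValueError("eta_posterior must be 'map' or 'amortized'")


@dataclass
class VariationalState:
    """Trainable inference-network and classifier parameters.

    ``theta_net`` maps (normalized BOW, eta_t) to the mean and softplus
    scale of q(theta logits); ``classifier`` scores labels from sampled
    theta; ``eta_net`` (amortized mode only) is a recurrent network over
    per-slice summaries producing q(eta_t).
    """

    theta_net: dict[str, np.ndarray]
    classifier: ClassifierHead
    eta_net: dict[str, np.ndarray] | None = None
    dropout: float = 0.1

    @classmethod
    def init(cls, V: int, K: int, n_labels: int, hidden: int = 256,
             head_hidden: int = 64, dropout: float = 0.1,
             eta_posterior: str = "map",
             seed: int | np.random.Generator = 0) -> "VariationalState":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        d_in = V + K
        def init_w(n_in, n_out):
            return rng.standard_normal((n_in, n_out)) * math.sqrt(2.0 / n_in)
        net = {
            "W1": init_w(d_in, hidden), "b1": np.zeros(hidden),
            "W2": init_w(hidden, hidden), "b2": np.zeros(hidden),
            "Wm": init_w(hidden, K), "bm": np.zeros(K),
            "Ws": init_w(hidden, K), "bs": np.full(K, -1.0),
        }
        head = ClassifierHead.init(K, n_labels, hidden=head_hidden, seed=rng)
        eta_net = None
        if eta_posterior == "amortized":
            h = max(32, 2 * K)
            eta_net = {
                "Wx": init_w(V, h), "Wh": init_w(h, h), "bh": np.zeros(h),
                "Um": init_w(h, K), "um": np.zeros(K),
                "Us": init_w(h, K), "us": np.full(K, -1.0),
            }
        return cls(theta_net=net, classifier=head, eta_net=eta_net, dropout=dropout)


def softplus(x: anp.ndarray) -> anp.ndarray:
    return anp.logaddexp(0.0, x)


def kl_diag_gaussians(mu_q, sigma_q, mu_p, sigma_p) -> float:
    """KL( N(mu_q, diag sigma_q^2) || N(mu_p, diag sigma_p^2) ), closed form.

    Inputs broadcast; the result sums over every coordinate.  Zero iff the
    two distributions coincide.
    """
    mu_q, sigma_q = anp.asarray(mu_q, dtype=float), anp.asarray(sigma_q, dtype=float)
    mu_p, sigma_p = anp.asarray(mu_p, dtype=float), anp.asarray(sigma_p, dtype=float)
    if (np.asarray(sigma_q) <= 0).any() or (np.asarray(sigma_p) <= 0).any():
        raise ValueError("sigma values must be strictly positive")
    return float(anp.sum(_kl_terms(mu_q, sigma_q, mu_p, sigma_p)))


def _kl_terms(mu_q, sigma_q, mu_p, sigma_p):
    var_ratio = (sigma_q / sigma_p) ** 2
    return 0.5 * (var_ratio + ((mu_q - mu_p) / sigma_p) ** 2 - 1.0) - anp.log(sigma_q / sigma_p)


# ---------------------------------------------------------------------------
# Differentiable forward passes
# ---------------------------------------------------------------------------

def _theta_net_forward(net: dict, x: anp.ndarray, masks=None):
    """Inference network: x -> (mu, sigma); ``masks`` apply inverted dropout."""
    h1 = anp.maximum(0.0, anp.dot(x, net["W1"]) + net["b1"])
    if masks is not None:
        h1 = h1 * masks[0]
    h2 = anp.maximum(0.0, anp.dot(h1, net["W2"]) + net["b2"])
    if masks is not None:
        h2 = h2 * masks[1]
    mu = anp.dot(h2, net["Wm"]) + net["bm"]
    sigma = softplus(anp.dot(h2, net["Ws"]) + net["bs"]) + 1e-6
    return mu, sigma


def _eta_net_forward(net: dict, summaries: anp.ndarray):
    """Recurrent q(eta): tanh RNN over per-slice summaries -> (mu, sigma) per slice."""
    T = summaries.shape[0]
    h = anp.zeros(net["Wh"].shape[0])
    mus, sigmas = [], []
    for t in range(T):
        h = anp.tanh(anp.dot(summaries[t], net["Wx"]) + anp.dot(h, net["Wh"]) + net["bh"])
        mus.append(anp.dot(h, net["Um"]) + net["um"])
        sigmas.append(softplus(anp.dot(h, net["Us"]) + net["us"]) + 1e-6)
    return anp.stack(mus), anp.stack(sigmas)


def _reconstruction(counts: anp.ndarray, theta: anp.ndarray, beta_t: anp.ndarray):
    """sum_d sum_w count * log(theta_d . beta[:, w]), batch total."""
    mix = anp.dot(theta, beta_t)  # N x V
    return anp.sum(counts * anp.log(mix + _LOG_EPS))


def _elbo_parts(net, counts, x, eta_t, beta_t, eps, noise, masks, n_mc):
    """Reconstruction and KL totals for one batch (autograd-traceable)."""
    mu, sigma = _theta_net_forward(net, x, masks)
    recon = 0.0
    for m in range(n_mc):
        theta = softmax(mu + sigma * noise[m], axis=1)
        recon = recon + _reconstruction(counts, theta, beta_t) / n_mc
    kl = anp.sum(_kl_terms(mu, sigma, eta_t, eps))
    return recon, kl, mu, sigma


def dynamics_penalty(params_or_alpha, eta=None, gamma=None, delta=None) -> float:
    """Negative log of the random-walk priors (additive constants dropped).

    ``sum_t ||alpha_t - alpha_{t-1}||^2 / (2 gamma^2) + ||alpha_0||^2 / 2``
    plus the analogous eta terms with scale delta.  Accepts either a
    :class:`ModelParameters` or raw ``(alpha, eta, gamma, delta)`` arrays
    (the latter form is autograd-traceable).
    """
    if isinstance(params_or_alpha, ModelParameters):
        p = params_or_alpha
        alpha, eta, gamma, delta = p.alpha, p.eta, p.gamma, p.delta
    else:
        alpha = params_or_alpha
        if eta is None or gamma is None or delta is None:
            raise ValueError("array form needs alpha, eta, gamma and delta")
    pen = 0.5 * anp.sum(alpha[0] ** 2) + 0.5 * anp.sum(eta[0] ** 2)
    if alpha.shape[0] > 1:
        da = alpha[1:] - alpha[:-1]
        de = eta[1:] - eta[:-1]
        pen = pen + anp.sum(da * da) / (2.0 * gamma ** 2) + anp.sum(de * de) / (2.0 * delta ** 2)
    return pen


# ---------------------------------------------------------------------------
# Public single-document / single-batch APIs
# ---------------------------------------------------------------------------

def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("empty document (zero token count)")
    return counts / totals


def _net_input(counts: np.ndarray, eta_t: np.ndarray) -> np.ndarray:
    x = _normalize_rows(counts)
    return np.hstack([x, np.broadcast_to(eta_t, (x.shape[0], eta_t.shape[-1])).copy()])


def infer_theta(doc_counts: np.ndarray, state: VariationalState, eta_t: np.ndarray,
                n_samples: int = 1, seed: int | np.random.Generator = 0):
    """Variational posterior of one document's topic proportions.

    Returns ``(mu, sigma, samples)`` where samples are ``n_samples x K``
    points on the simplex obtained by the reparameterization
    ``softmax(mu + sigma * standard_normal)``.  Deterministic under ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x = _net_input(doc_counts, np.asarray(eta_t, dtype=float))
    mu, sigma = _theta_net_forward(state.theta_net, x)
    mu, sigma = mu[0], sigma[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal((n_samples, mu.shape[0]))
    samples = softmax(mu + sigma * noise, axis=1)
    return mu, sigma, samples


def theta_means(counts: np.ndarray, state: VariationalState, eta_t: np.ndarray) -> np.ndarray:
    """Deterministic topic proportions softmax(mu(d)) for a batch (``N x K``)."""
    x = _net_input(counts, np.asarray(eta_t, dtype=float))
    mu, _ = _theta_net_forward(state.theta_net, x)
    return softmax(mu, axis=1)


def elbo_batch(counts: np.ndarray | sp.spmatrix, t: int, state: VariationalState,
               params: ModelParameters, n_mc: int = 1,
               seed: int | np.random.Generator = 0, scale: float = 1.0):
    """Monte-Carlo ELBO of a batch of documents from slice ``t``.

    Returns ``(elbo, breakdown)`` where the breakdown holds the
    reconstruction and KL totals (both already multiplied by ``scale``, the
    minibatch inflation factor N_t / batch size).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if t >= params.n_slices:
        raise ValueError(f"slice {t} has no prior mean (model has T={params.n_slices})")
    if sp.issparse(counts):
        counts = np.asarray(counts.todense(), dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    eta_t = params.eta[t]
    x = _net_input(counts, eta_t)
    beta_t = compute_beta(params.alpha[t], params.rho)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal((n_mc, counts.shape[0], params.n_topics))
    recon, kl, mu, sigma = _elbo_parts(
        state.theta_net, counts, x, eta_t, beta_t, params.eps, noise, None, n_mc
    )
    recon, kl = float(recon) * scale, float(kl) * scale
    return recon - kl, {"recon": recon, "kl": kl, "elbo": recon - kl,
                        "mu": np.asarray(mu), "sigma": np.asarray(sigma)}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _trainable_dict(rho, alpha, eta, state: VariationalState, freeze_rho: bool):
    d = {"alpha": alpha, "eta": eta}
    if not freeze_rho:
        d["rho"] = rho
    d.update(state.theta_net)
    d.update({k: v for k, v in state.classifier.weights.items()})
    if state.eta_net is not None:
        d.update({f"eta_{k}": v for k, v in state.eta_net.items()})
    return d


def _unpack(p: dict, state_template: VariationalState):
    net = {k: p[k] for k in ("W1", "b1", "W2", "b2", "Wm", "bm", "Ws", "bs")}
    head = {k: p[k] for k in ("C1", "c1", "C2", "c2")}
    eta_net = None
    if state_template.eta_net is not None:
        eta_net = {k[4:]: v for k, v in p.items() if k.startswith("eta_W") or k.startswith("eta_b")
                   or k.startswith("eta_U") or k.startswith("eta_u")}
    return net, head, eta_net


class _Adam:
    """Adam over a dict of arrays with decoupled-style L2 weight decay."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = np.asarray(grads[k]) + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def train(
    corpus: TimeSlicedCorpus,
    config: TrainConfig,
    valid_corpus: TimeSlicedCorpus | None = None,
    init_rho: np.ndarray | None = None,
):
    """Fit the model by stochastic gradient descent on the combined objective.

    Minibatches are drawn within one slice per step (so each batch has a
    well-defined eta_t) and rescaled by N_t / batch size.  The per-epoch log
    records the smoothed full-scale ELBO, its reconstruction/KL parts, the
    topic-diversity and classification terms and (when ``valid_corpus`` is
    given) a deterministic validation ELBO evaluated at the variational
    mean.  Returns ``(ModelParameters, VariationalState, log)`` for the
    best-validation epoch (final epoch when no validation corpus is given).

    Raises ``RuntimeError`` naming the epoch and batch if the loss diverges.
    """
    T, V, M = corpus.n_slices, corpus.n_words, corpus.n_labels
    K, L = config.K, config.L
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_shuffle, rng_noise, rng_drop = [np.random.default_rng(s) for s in ss.spawn(4)]

    if init_rho is not None:
        rho = np.array(init_rho, dtype=float)
        if rho.shape != (L, V):
            raise ValueError(f"init_rho shape {rho.shape} != ({L}, {V})")
    else:
        rho = rng_init.standard_normal((L, V)) * 0.1
    alpha = rng_init.standard_normal((T, K, L)) * 0.1
    eta = np.zeros((T, K))
    state = VariationalState.init(
        V, K, M, hidden=config.hidden, head_hidden=config.head_hidden,
        dropout=config.dropout, eta_posterior=config.eta_posterior, seed=rng_init,
    )
    amortized = config.eta_posterior == "amortized"
    slice_summaries = None
    if amortized:
        slice_summaries = np.vstack([
            _normalize_rows(np.maximum(corpus.dense_counts(t).sum(axis=0, keepdims=True), 1e-12))
            for t in range(T)
        ])

    dense = [corpus.dense_counts(t) for t in range(T)]
    labels = [corpus.labels[t] for t in range(T)]
    lam1, lam2 = config.lambda1, config.lambda2
    eps, delta, gamma = config.eps, config.delta, config.gamma
    dropout = config.dropout
    n_mc = config.n_mc

    def loss_fn(p, counts, x, y, t, scale, noise, masks, eta_noise):
        net, head, eta_net = _unpack(p, state)
        rho_ = p.get("rho", rho)
        if amortized:
            emu, esig = _eta_net_forward(eta_net, slice_summaries)
            eta_all = emu + esig * eta_noise
            # chain KL: q(eta_t) vs random walk from the previous posterior mean
            prev_mu = anp.concatenate([anp.zeros((1, K)), emu[:-1]], axis=0)
            prev_scale = anp.concatenate(
                [anp.ones((1, K)), anp.full((T - 1, K), delta)], axis=0
            )
            eta_pen = anp.sum(_kl_terms(emu, esig, prev_mu, prev_scale))
        else:
            eta_all = p["eta"]
            eta_pen = None
        eta_t = eta_all[t]
        x_full = anp.concatenate(
            [x, anp.zeros((x.shape[0], K)) + eta_t.reshape((1, K))], axis=1
        )
        beta_t = compute_beta(p["alpha"][t], rho_)
        mu, sigma = _theta_net_forward(net, x_full, masks)
        recon = 0.0
        theta0 = None
        for m in range(noise.shape[0]):
            theta = softmax(mu + sigma * noise[m], axis=1)
            if theta0 is None:
                theta0 = theta
            recon = recon + _reconstruction(counts, theta, beta_t) / noise.shape[0]
        kl = anp.sum(_kl_terms(mu, sigma, eta_t, eps))
        elbo = (recon - kl) * scale
        td = topic_diversity_loss(p["alpha"])
        ce = cross_entropy_from_scores(classifier_forward(head, theta0), y)
        if amortized:
            dyn = (0.5 * anp.sum(p["alpha"][0] ** 2)
                   + anp.sum((p["alpha"][1:] - p["alpha"][:-1]) ** 2) / (2 * gamma ** 2)
                   + eta_pen)
        else:
            dyn = dynamics_penalty(p["alpha"], p["eta"], gamma, delta)
        return total_objective(elbo, td, ce, dyn, lam1, lam2)

    vgrad_fn = value_and_grad(loss_fn)
    params_dict = _trainable_dict(rho, alpha, eta, state, config.freeze_embeddings)
    opt = _Adam(params_dict, config.learning_rate, config.weight_decay)
    norm_cache = [_normalize_rows(dense[t]) if dense[t].shape[0] else None for t in range(T)]

    def current_model(p) -> tuple[ModelParameters, VariationalState]:
        net, head, eta_net = _unpack(p, state)
        if amortized:
            emu, _ = _eta_net_forward(eta_net, slice_summaries)
            eta_arr = np.asarray(emu)
        else:
            eta_arr = np.asarray(p["eta"])
        mp = ModelParameters(
            rho=np.asarray(p.get("rho", rho)), alpha=np.asarray(p["alpha"]),
            eta=eta_arr, eps=eps, delta=delta, gamma=gamma,
        )
        vs = VariationalState(
            theta_net={k: np.asarray(v) for k, v in net.items()},
            classifier=ClassifierHead({k: np.asarray(v) for k, v in head.items()}),
            eta_net=None if eta_net is None else {k: np.asarray(v) for k, v in eta_net.items()},
            dropout=dropout,
        )
        return mp, vs

    def validation_elbo(p) -> float:
        mp, vs = current_model(p)
        total, n_tok = 0.0, 0
        for t in range(valid_corpus.n_slices):
            c = valid_corpus.dense_counts(t)
            if not c.shape[0]:
                continue
            x = _net_input(c, mp.eta[t])
            beta_t = compute_beta(mp.alpha[t], mp.rho)
            mu, sigma = _theta_net_forward(vs.theta_net, x)
            theta = softmax(mu, axis=1)  # variational mean: deterministic
            recon = float(_reconstruction(c, theta, beta_t))
            kl = float(anp.sum(_kl_terms(mu, sigma, mp.eta[t], eps)))
            total += recon - kl
            n_tok += int(c.sum())
        return total / max(n_tok, 1)

    log: list[dict] = []
    best = {"val": -np.inf, "params": None}
    for epoch in range(config.epochs):
        slice_order = rng_shuffle.permutation(T)
        for t in slice_order:
            n_t = dense[t].shape[0]
            if n_t == 0:
                continue
            perm = rng_shuffle.permutation(n_t)
            for start in range(0, n_t, config.batch_size):
                idx = perm[start:start + config.batch_size]
                counts_b = dense[t][idx]
                x_b = norm_cache[t][idx]
                y_b = labels[t][idx]
                scale = n_t / idx.shape[0]
                noise = rng_noise.standard_normal((n_mc, idx.shape[0], K))
                eta_noise = rng_noise.standard_normal((T, K)) if amortized else None
                if dropout > 0:
                    masks = [
                        (rng_drop.random((idx.shape[0], config.hidden)) >= dropout)
                        / (1 - dropout)
                        for _ in range(2)
                    ]
                else:
                    masks = None
                where = f"epoch {epoch}, slice {t}, batch {start // config.batch_size}"
                try:
                    val, g = vgrad_fn(params_dict, counts_b, x_b, y_b, int(t), scale,
                                      noise, masks, eta_noise)
                except (FloatingPointError, ValueError) as exc:
                    raise RuntimeError(f"training diverged at {where}: {exc}") from exc
                if not np.isfinite(val):
                    raise RuntimeError(f"non-finite loss at {where}")
                params_dict = opt.step(params_dict, g)
        # epoch-level diagnostics on the full data at current parameters
        mp, vs = current_model(params_dict)
        diag = _full_diagnostics(corpus, dense, norm_cache, labels, mp, vs, lam1, lam2)
        row = {"epoch": epoch, **diag}
        if valid_corpus is not None:
            row["val_elbo"] = validation_elbo(params_dict)
            if row["val_elbo"] > best["val"]:
                best["val"] = row["val_elbo"]
                best["params"] = copy.deepcopy(params_dict)
        log.append(row)
        if epoch % max(1, config.epochs // 10) == 0:
            logger.info("epoch %d: %s", epoch, {k: round(v, 3) for k, v in diag.items()})

    final = best["params"] if best["params"] is not None else params_dict
    mp, vs = current_model(final)
    return mp, vs, log


def _full_diagnostics(corpus, dense, norm_cache, labels, mp, vs, lam1, lam2):
    """Deterministic full-data ELBO/TD/CE at the variational mean."""
    recon_tot, kl_tot, ce_num, n_docs = 0.0, 0.0, 0.0, 0
    for t in range(corpus.n_slices):
        c = dense[t]
        if not c.shape[0]:
            continue
        x = np.hstack([norm_cache[t], np.broadcast_to(mp.eta[t], (c.shape[0], mp.n_topics))])
        mu, sigma = _theta_net_forward(vs.theta_net, x)
        theta = softmax(mu, axis=1)
        beta_t = compute_beta(mp.alpha[t], mp.rho)
        recon_tot += float(_reconstruction(c, theta, beta_t))
        kl_tot += float(anp.sum(_kl_terms(mu, sigma, mp.eta[t], mp.eps)))
        scores = classifier_forward(vs.classifier.weights, theta)
        ce_num += float(cross_entropy_from_scores(scores, labels[t])) * c.shape[0]
        n_docs += c.shape[0]
    td = float(topic_diversity_loss(mp.alpha))
    ce = ce_num / max(n_docs, 1)
    elbo = recon_tot - kl_tot
    dyn = float(dynamics_penalty(mp))
    return {
        "elbo": elbo, "recon": recon_tot, "kl": kl_tot, "td": td, "ce": ce,
        "objective": float(total_objective(elbo, td, ce, dyn, lam1, lam2)),
    }


def write_training_log(log: Sequence[dict], path) -> None:
    """Write the per-epoch training log as CSV."""
    import csv

    keys = sorted({k for row in log for k in row}, key=lambda k: (k != "epoch", k))
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for row in log:
            w.writerow(row)
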