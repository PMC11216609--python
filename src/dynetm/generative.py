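"""Generative model: embedded topics, random-walk dynamics and a simulator.

The model places K topics in an L-dimensional word-embedding space.  Each
word w has an embedding rho[:, w]; each topic k at time slice t has an
embedding alpha[t, k].  The topic's word distribution is

    beta[t, k] = softmax(rho^T alpha[t, k])          (a point on the V-simplex)

Topics and the per-slice prior mean of topic proportions evolve by Gaussian
random walks: alpha[t] = alpha[t-1] + gamma * noise, eta[t] = eta[t-1] +
delta * noise, with standard-normal draws at t = 0.  A document d in slice t
draws logistic-normal topic proportions theta_d = softmax(N(eta[t],
eps^2 I)); each token draws a topic z ~ Cat(theta_d) then a word
w ~ Cat(beta[t, z]).

The simulator in :func:`sample_corpus` runs this process forward and records
every latent variable, so inference can be validated against known truth.
Synthetic labels are attached through a pluggable mechanism whose default
makes the label a (noiseless) linear readout of theta_d, giving the
label-classification loss learnable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp

from .corpus_io import TimeSlicedCorpus, Vocabulary


class ModelError(ValueError):
    """Raised for invalid model parameters or latent states."""


def softmax(x: anp.ndarray, axis: int = -1) -> anp.ndarray:
    """Numerically stabilized softmax (max-subtracted; autograd-compatible)."""
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=axis, keepdims=True)


@dataclass
class ModelParameters:
    """Parameters of the time-aware embedded topic model.

    rho : ``L x V`` word embeddings.
    alpha : ``T x K x L`` per-slice topic embeddings.
    eta : ``T x K`` per-slice prior means of topic-proportion logits.
    eps, delta, gamma : positive scales of the theta prior and of the eta and
    alpha random walks.
    """

    rho: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray
    eps: float = 0.01
    delta: float = 0.01
    gamma: float = 0.01

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.rho.ndim != 2 or self.alpha.ndim != 3 or self.eta.ndim != 2:
            raise ModelError("rho must be L x V, alpha T x K x L, eta T x K")
        T, K, L = self.alpha.shape
        if self.rho.shape[0] != L:
            raise ModelError(f"rho has embedding dim {self.rho.shape[0]}, alpha has {L}")
        if self.eta.shape != (T, K):
            raise ModelError(f"eta shape {self.eta.shape} != ({T}, {K})")
        if K < 1:
            raise ModelError("need at least one topic")
        if min(self.eps, self.delta, self.gamma) <= 0:
            raise ModelError("eps, delta, gamma must be positive")
        if not (np.isfinite(self.rho).all() and np.isfinite(self.alpha).all()
                and np.isfinite(self.eta).all()):
            raise ModelError("non-finite model parameters")

    @property
    def n_slices(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_topics(self) -> int:
        return self.alpha.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.alpha.shape[2]

    @property
    def n_words(self) -> int:
        return self.rho.shape[1]

    def beta(self) -> np.ndarray:
        """Full ``T x K x V`` array of topic-word distributions."""
        return np.stack([compute_beta(self.alpha[t], self.rho) for t in range(self.n_slices)])


def compute_beta(alpha_t: anp.ndarray, rho: anp.ndarray) -> anp.ndarray:
    """Topic-word distributions ``softmax(rho^T alpha_k)`` for one slice.

    Parameters are a ``K x L`` topic-embedding block and the ``L x V`` word
    embeddings; the result is ``K x V`` with strictly positive rows summing
    to 1.  Autograd-compatible (used inside the training objective).
    """
    if alpha_t.ndim == 1:
        alpha_t = alpha_t.reshape((1, -1))
    if alpha_t.shape[1] != rho.shape[0]:
        raise ModelError(
            f"embedding dim mismatch: alpha has {alpha_t.shape[1]}, rho has {rho.shape[0]}"
        )
    if not (np.isfinite(_value_of(alpha_t)).all() and np.isfinite(_value_of(rho)).all()):
        raise ModelError("non-finite embeddings")
    scores = anp.dot(alpha_t, rho)  # K x V
    return softmax(scores, axis=1)


def _value_of(x):
    """Underlying numpy value of a (possibly autograd-boxed) array."""
    while hasattr(x, "_value"):
        x = x._value
    return np.asarray(x)


def sample_dynamics(
    K: int,
    L: int,
    T: int,
    delta: float,
    gamma: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw random-walk trajectories for topic embeddings and prior means.

    Slice 0 is standard Gaussian; slice t adds ``gamma`` (for alpha) or
    ``delta`` (for eta) times standard-normal increments to slice t-1.
    Returns ``(alpha, eta)`` of shapes ``T x K x L`` and ``T x K``.
    """
    if min(delta, gamma) < 0:
        raise ModelError("noise scales must be non-negative")
    if min(K, L, T) < 1:
        raise ModelError("K, L, T must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = np.empty((T, K, L))
    eta = np.empty((T, K))
    alpha[0] = rng.standard_normal((K, L))
    eta[0] = rng.standard_normal(K)
    for t in range(1, T):
        alpha[t] = alpha[t - 1] + gamma * rng.standard_normal((K, L))
        eta[t] = eta[t - 1] + delta * rng.standard_normal(K)
    return alpha, eta


def marginal_word_prob(theta_d: np.ndarray, beta_t: np.ndarray) -> np.ndarray:
    """Word distribution of a document: ``sum_k theta_k beta[k]``.

    ``theta_d`` must lie on the K-simplex and every row of ``beta_t`` on the
    V-simplex; the result is again a probability vector, linear in theta.
    """
    theta_d = np.asarray(theta_d, dtype=float)
    beta_t = np.asarray(beta_t, dtype=float)
    if abs(theta_d.sum() - 1.0) > 1e-6 or (theta_d < -1e-12).any():
        raise ModelError("theta is not on the simplex")
    if np.abs(beta_t.sum(axis=1) - 1.0).max() > 1e-6:
        raise ModelError("beta rows are not on the simplex")
    return theta_d @ beta_t


@dataclass
class LinearLabelMechanism:
    """Labels as a linear readout of topic proportions.

    A fixed ``M x K`` weight matrix maps theta to class scores.  With
    ``temperature == 0`` the label is the argmax (deterministic, perfectly
    predictable from theta); with a positive temperature the label is drawn
    from ``Cat(softmax(scores / temperature))``.
    """

    weights: np.ndarray
    temperature: float = 0.0

    @classmethod
    def random(cls, n_labels: int, K: int, seed: int | np.random.Generator = 0,
               temperature: float = 0.0) -> "LinearLabelMechanism":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(weights=rng.standard_normal((n_labels, K)), temperature=temperature)

    @property
    def n_labels(self) -> int:
        return self.weights.shape[0]

    def draw(self, theta: np.ndarray, rng: np.random.Generator) -> int:
        scores = self.weights @ theta
        if self.temperature <= 0:
            return int(np.argmax(scores))
        p = softmax(scores / self.temperature)
        return int(rng.choice(self.n_labels, p=p))


@dataclass
class SyntheticTruth:
    """Latent record of a simulated corpus.

    ``theta`` holds one ``N_t x K`` array per slice; ``z`` one list (per
    slice) of per-document integer token-topic arrays; ``labels`` one array
    per slice.  ``label_map`` is the mechanism that produced the labels.
    """

    params: ModelParameters
    theta: list[np.ndarray]
    z: list[list[np.ndarray]]
    labels: list[np.ndarray]
    label_map: LinearLabelMechanism
    seed: int | None = None

    def theta_matrix(self) -> np.ndarray:
        """All documents' theta stacked, slice by slice (``N x K``)."""
        return np.vstack(self.theta)


def _synthetic_vocabulary(V: int) -> Vocabulary:
    width = max(4, len(str(V - 1)))
    return Vocabulary(tuple(f"w{i:0{width}d}" for i in range(V)))


def sample_corpus(
    params: ModelParameters,
    docs_per_slice: Sequence[int],
    tokens_per_doc: int | Callable[[np.random.Generator], int] = 60,
    label_mechanism: LinearLabelMechanism | None = None,
    seed: int = 0,
    n_labels: int = 5,
    vocabulary: Vocabulary | None = None,
) -> tuple[TimeSlicedCorpus, SyntheticTruth]:
    """Simulate a labeled time-sliced corpus from the generative model.

    For every document in slice t: theta = softmax(N(eta[t], eps^2 I)); each
    token draws topic z ~ Cat(theta) and word w ~ Cat(beta[t, z]).  Labels
    come from ``label_mechanism`` (default: a seeded
    :class:`LinearLabelMechanism` with ``n_labels`` classes and argmax
    readout).  Returns the corpus together with a full latent record.
    """
    T = params.n_slices
    if len(docs_per_slice) != T:
        raise ModelError(f"docs_per_slice has length {len(docs_per_slice)}, model has T={T}")
    rng = np.random.default_rng(seed)
    if label_mechanism is None:
        label_mechanism = LinearLabelMechanism.random(n_labels, params.n_topics, rng)
    if vocabulary is None:
        vocabulary = _synthetic_vocabulary(params.n_words)
    if len(vocabulary) != params.n_words:
        raise ModelError("vocabulary size does not match rho")

    def doc_length(r: np.random.Generator) -> int:
        n = tokens_per_doc(r) if callable(tokens_per_doc) else int(tokens_per_doc)
        if n < 1:
            raise ModelError(f"tokens_per_doc produced {n} < 1")
        return n

    K, V = params.n_topics, params.n_words
    beta = params.beta()
    counts, labels, thetas, zs = [], [], [], []
    for t in range(T):
        n_t = int(docs_per_slice[t])
        theta_t = softmax(
            params.eta[t] + params.eps * rng.standard_normal((n_t, K)), axis=1
        )
        rows = sp.lil_matrix((n_t, V), dtype=np.int64)
        z_t: list[np.ndarray] = []
        lab_t = np.empty(n_t, dtype=np.int64)
        for j in range(n_t):
            n_tok = doc_length(rng)
            z = rng.choice(K, size=n_tok, p=theta_t[j])
            words = np.empty(n_tok, dtype=np.int64)
            for k in np.unique(z):
                mask = z == k
                words[mask] = rng.choice(V, size=int(mask.sum()), p=beta[t, k])
            uniq, cnt = np.unique(words, return_counts=True)
            rows[j, uniq] = cnt
            z_t.append(z)
            lab_t[j] = label_mechanism.draw(theta_t[j], rng)
        counts.append(rows.tocsr())
        labels.append(lab_t)
        thetas.append(theta_t)
        zs.append(z_t)

    label_names = [f"label{m}" for m in range(label_mechanism.n_labels)]
    corpus = TimeSlicedCorpus(counts, labels, vocabulary, label_names, list(range(T)))
    truth = SyntheticTruth(params, thetas, zs, labels, label_mechanism, seed=seed)
    return corpus, truth


def random_parameters(
    K: int,
    V: int,
    L: int,
    T: int,
    eps: float = 0.01,
    delta: float = 0.01,
    gamma: float = 0.01,
    seed: int = 0,
) -> ModelParameters:
    """Draw a full parameter set: Gaussian rho plus random-walk alpha/eta."""
    rng = np.random.default_rng(seed)
    rho = rng.standard_normal((L, V))
    alpha, eta = sample_dynamics(K, L, T, delta, gamma, rng)
    return ModelParameters(rho=rho, alpha=alpha, eta=eta, eps=eps, delta=delta, gamma=gamma)


@dataclass
class TopicSummary:
    """Per-slice topic-word distributions and ranked top-word lists."""

    beta: np.ndarray  # T x K x V
    top_words: list[list[list[str]]]  # [t][k] -> p words
    p: int

    @classmethod
    def from_parameters(
        cls, params: ModelParameters, vocabulary: Vocabulary, p: int = 10
    ) -> "TopicSummary":
        beta = params.beta()
        return cls.from_beta(beta, vocabulary, p)

    @classmethod
    def from_beta(cls, beta: np.ndarray, vocabulary: Vocabulary, p: int = 10) -> "TopicSummary":
        beta = np.asarray(beta, dtype=float)
        if beta.ndim == 2:
            beta = beta[None]
        T, K, V = beta.shape
        if V != len(vocabulary):
            raise ModelError("beta width does not match vocabulary")
        if np.abs(beta.sum(axis=2) - 1.0).max() > 1e-8:
            raise ModelError("beta rows must sum to 1")
        top = [
            [top_words_of(beta[t, k], vocabulary, p) for k in range(K)]
            for t in range(T)
        ]
        return cls(beta=beta, top_words=top, p=p)


def top_words_of(beta_row: np.ndarray, vocabulary: Vocabulary, p: int) -> list[str]:
    """Top-p words of one topic, ties broken lexicographically (stable)."""
    order = sorted(range(len(beta_row)), key=lambda i: (-beta_row[i], vocabulary.terms[i]))
    return [vocabulary.terms[i] for i in order[:p]]
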