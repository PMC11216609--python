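"""Auxiliary training losses and the combined multitask objective.

Two extra terms supplement the variational bound during training:

* a topic-diversity term — the sum of pairwise Euclidean distances between
  topic embeddings within each slice, which the optimizer *increases* to keep
  topics spread out in embedding space;
* a label-classification term — cross-entropy of a small feed-forward head
  applied to inferred topic proportions, which ties topics to the document
  labels (e.g. funding institutes).

The combined scalar that gradient descent minimizes is

    (-ELBO) + dynamics_penalty - lambda1 * TD + lambda2 * CE

so the ELBO and the topic spread are maximized while the classification
error is minimized.  Defaults lambda1 = 1 and lambda2 = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

_NORM_EPS = 1e-18  # keeps sqrt differentiable at coincident topic pairs


def topic_diversity_loss(alpha: anp.ndarray, distance: str = "euclidean") -> float:
    """Sum over slices and unordered topic pairs of embedding distances.

    ``alpha`` is ``T x K x L`` (a single ``K x L`` slice is also accepted).
    Zero iff all topics coincide within every slice; invariant under a joint
    rigid translation of a slice's topic embeddings.  Autograd-compatible.
    """
    if distance != "euclidean":
        raise ValueError(f"unsupported distance {distance!r}")
    a = alpha if hasattr(alpha, "ndim") else anp.asarray(alpha)
    if a.ndim == 2:
        a = a.reshape((1,) + a.shape)
    if a.ndim != 3:
        raise ValueError("alpha must be K x L or T x K x L")
    K = a.shape[1]
    if K < 2:
        warnings.warn("topic diversity needs K >= 2 topics; returning 0", stacklevel=2)
        return 0.0
    iu, ju = np.triu_indices(K, k=1)
    diff = a[:, iu, :] - a[:, ju, :]  # T x P x L
    return anp.sum(anp.sqrt(anp.sum(diff * diff, axis=2) + _NORM_EPS))


@dataclass
class ClassifierHead:
    """Feed-forward scorer from topic proportions to label logits.

    One hidden tanh layer (default width 64).  Weights live in a plain dict
    so the head can be trained jointly with the model through autograd.
    """

    weights: dict[str, np.ndarray]
    n_labels: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_labels = self.weights["c2"].shape[0]

    @classmethod
    def init(cls, K: int, n_labels: int, hidden: int = 64,
             seed: int | np.random.Generator = 0) -> "ClassifierHead":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        w = {
            "C1": rng.standard_normal((K, hidden)) * np.sqrt(1.0 / K),
            "c1": np.zeros(hidden),
            "C2": rng.standard_normal((hidden, n_labels)) * np.sqrt(1.0 / hidden),
            "c2": np.zeros(n_labels),
        }
        return cls(weights=w)

    def scores(self, theta: np.ndarray) -> np.ndarray:
        """Label logits for a batch of topic proportions (``N x K``)."""
        return classifier_forward(self.weights, anp.atleast_2d(theta))


def classifier_forward(weights: dict, theta: anp.ndarray) -> anp.ndarray:
    if theta.ndim == 1:
        theta = theta.reshape((1, -1))
    h = anp.tanh(anp.dot(theta, weights["C1"]) + weights["c1"])
    return anp.dot(h, weights["C2"]) + weights["c2"]


def cross_entropy_from_scores(scores: anp.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmaxed score rows vs labels."""
    if scores.ndim == 1:
        scores = scores.reshape((1, -1))
    labels = np.asarray(labels, dtype=int)
    M = scores.shape[1]
    if labels.min() < 0 or labels.max() >= M:
        raise ValueError(f"label out of range [0, {M})")
    shifted = scores - anp.max(scores, axis=1, keepdims=True)
    log_z = anp.log(anp.sum(anp.exp(shifted), axis=1))
    picked = shifted[anp.arange(scores.shape[0]), labels]
    return anp.mean(log_z - picked)


def ic_classification_loss(theta_batch: np.ndarray, labels: np.ndarray,
                           head: ClassifierHead) -> float:
    """Cross-entropy of the label head on a batch of topic proportions."""
    return cross_entropy_from_scores(classifier_forward(head.weights, theta_batch), labels)


def total_objective(elbo: float, td: float, ce: float, dynamics_penalty: float,
                    lambda1: float = 1.0, lambda2: float = 0.5) -> float:
    """Scalar the optimizer minimizes.

    ``(-elbo) + dynamics_penalty - lambda1 * td + lambda2 * ce``: maximize
    the evidence bound and the topic spread, minimize classification error,
    and keep trajectories smooth under their random-walk priors.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be non-negative")
    return -elbo + dynamics_penalty - lambda1 * td + lambda2 * ce
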