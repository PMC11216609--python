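"""Downstream analyses of a fitted model.

Covers the four standard uses of a trained time-aware topic model: word
trend trajectories (a word's generative probability within a topic,
normalized to 1 at a base year), cross-resolution topic hierarchies
(correlating topics of models trained with different K), label
classification from topic-proportion features with top-k accuracy, and 2-D
embedding of topic proportions for visualization.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import TimeSlicedCorpus, Vocabulary
from .generative import ModelParameters, softmax
from .inference import VariationalState, theta_means


class AnalysisError(ValueError):
    pass


@dataclass
class TrendSeries:
    """Per-slice generative probability of a word in a topic, base-normalized.

    ``values[t] = beta[t, k, word] / beta[base_slice, k, word]``, so the
    entry at ``base_slice`` is exactly 1.
    """

    word: str
    topic: int
    values: np.ndarray
    base_slice: int
    years: list[int] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.years if self.years is not None else list(range(len(self.values)))
        return pd.DataFrame({"year": idx, "word": self.word, "topic": self.topic,
                             "relative_probability": self.values})


def word_trend(params: ModelParameters, vocabulary: Vocabulary, word: str,
               k: int, base_slice: int = 0, years: list[int] | None = None) -> TrendSeries:
    """Relative generative-probability trajectory of ``word`` in topic ``k``.

    Raises for out-of-vocabulary words, suggesting the closest in-vocabulary
    spellings.
    """
    if word not in vocabulary:
        near = difflib.get_close_matches(word, vocabulary.terms, n=3)
        raise AnalysisError(f"word {word!r} not in vocabulary; nearest: {near}")
    if not (0 <= k < params.n_topics):
        raise AnalysisError(f"topic {k} out of range [0, {params.n_topics})")
    if not (0 <= base_slice < params.n_slices):
        raise AnalysisError(f"base slice {base_slice} out of range")
    v = vocabulary.index[word]
    beta = params.beta()  # T x K x V
    series = beta[:, k, v] / beta[base_slice, k, v]
    return TrendSeries(word=word, topic=k, values=series, base_slice=base_slice, years=years)


@dataclass
class HierarchyLink:
    """A parent topic (coarser model) linked to a child topic (finer model)."""

    parent: int
    child: int
    similarity: float


def similarity_matrix(model_a: ModelParameters, model_b: ModelParameters,
                      space: str = "beta") -> np.ndarray:
    """Pearson correlation between time-averaged topic vectors of two models.

    ``beta`` space compares topic-word distributions (requires a shared
    vocabulary size); ``alpha`` space compares topic embeddings (requires a
    shared embedding dimension and is only meaningful when both models share
    frozen word embeddings).
    """
    if space == "beta":
        if model_a.n_words != model_b.n_words:
            raise AnalysisError("beta-space comparison needs a shared vocabulary")
        A = model_a.beta().mean(axis=0)
        B = model_b.beta().mean(axis=0)
    elif space == "alpha":
        if model_a.embed_dim != model_b.embed_dim:
            raise AnalysisError("alpha-space comparison needs equal embedding dims")
        A = model_a.alpha.mean(axis=0)
        B = model_b.alpha.mean(axis=0)
    else:
        raise AnalysisError(f"unknown comparison space {space!r}")
    Ka, Kb = A.shape[0], B.shape[0]
    corr = np.corrcoef(np.vstack([A, B]))[:Ka, Ka:]
    return corr


def topic_hierarchy(model_a: ModelParameters, model_b: ModelParameters,
                    space: str = "beta", top_links: int = 3) -> list[HierarchyLink]:
    """Strongest children in model B for each parent topic of model A."""
    corr = similarity_matrix(model_a, model_b, space=space)
    links = []
    for i in range(corr.shape[0]):
        order = np.argsort(-corr[i], kind="stable")[:top_links]
        for j in order:
            links.append(HierarchyLink(parent=i, child=int(j), similarity=float(corr[i, j])))
    return links


def extract_topic_features(corpus: TimeSlicedCorpus, params: ModelParameters,
                           state: VariationalState):
    """Variational-mean topic proportions as document features.

    Returns ``(features, labels)``: an ``N x K`` simplex-row matrix (rows in
    corpus slice order) and the matching label vector.  Empty documents are
    excluded with a warning.
    """
    if corpus.n_words != params.n_words:
        raise AnalysisError("corpus vocabulary does not match the model")
    feats, labs = [], []
    n_empty = 0
    for t in range(min(corpus.n_slices, params.n_slices)):
        counts = corpus.dense_counts(t)
        if counts.shape[0] == 0:
            continue
        keep = counts.sum(axis=1) > 0
        n_empty += int((~keep).sum())
        if keep.any():
            feats.append(theta_means(counts[keep], state, params.eta[t]))
            labs.append(corpus.labels[t][keep])
    if n_empty:
        warnings.warn(f"excluded {n_empty} empty document(s)", stacklevel=2)
    if not feats:
        raise AnalysisError("no non-empty documents")
    return np.vstack(feats), np.concatenate(labs)


def classify_labels(features_train: np.ndarray, labels_train: np.ndarray,
                    features_test: np.ndarray, labels_test: np.ndarray,
                    classifier=None, ks=(1, 5), seed: int = 0) -> dict[int, float]:
    """Top-k label accuracy of a classifier on topic-proportion features.

    The default classifier is a seeded random forest; any estimator with
    ``fit`` and ``predict_proba`` can be substituted.  Classes present in
    the test set but absent from training are necessarily misses (they can
    never be proposed) and are reported via a warning.
    """
    if features_train.shape[1] != features_test.shape[1]:
        raise AnalysisError("train/test feature dimensions differ")
    if classifier is None:
        from sklearn.ensemble import RandomForestClassifier

        classifier = RandomForestClassifier(n_estimators=200, random_state=seed)
    classifier.fit(features_train, labels_train)
    probs = classifier.predict_proba(features_test)
    classes = np.asarray(classifier.classes_)
    unseen = set(np.unique(labels_test)) - set(classes)
    if unseen:
        warnings.warn(
            f"labels {sorted(unseen)} absent from training; counted as misses", stacklevel=2
        )
    order = np.argsort(-probs, axis=1, kind="stable")
    out: dict[int, float] = {}
    prev = -1.0
    for k in sorted(int(k) for k in ks):
        if k < 1:
            raise AnalysisError("k must be >= 1")
        topk = classes[order[:, :k]]
        acc = float(np.mean(np.any(topk == np.asarray(labels_test)[:, None], axis=1)))
        acc = max(acc, prev)  # guard: monotone by construction up to float noise
        out[k] = acc
        prev = acc
    return out


def embed_theta_2d(features: np.ndarray, labels: np.ndarray | None = None,
                   seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """UMAP 2-D embedding of topic proportions, one row per document.

    Deterministic under ``seed``.  Requires at least 10 documents and more
    documents than ``n_neighbors`` (lower ``n_neighbors`` for small sets).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 10:
        raise AnalysisError("need at least 10 documents to embed")
    if n <= n_neighbors:
        raise AnalysisError(
            f"n_neighbors={n_neighbors} >= {n} documents; pass a smaller n_neighbors"
        )
    import umap

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        xy = reducer.fit_transform(features)
    if not np.isfinite(xy).all():
        raise AnalysisError("embedding produced non-finite coordinates")
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    if labels is not None:
        df["label"] = np.asarray(labels)
    return df
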