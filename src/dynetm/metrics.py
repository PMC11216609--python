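"""Topic-quality metrics: coherence (NPMI, C_A, C_P), diversity, perplexity.

Topic coherence scores a topic's top-p words by their pairwise association
in a reference corpus.  Three association measures are supported:

* ``npmi`` — normalized pointwise mutual information on document-level
  co-occurrence counts, in [-1, 1];
* ``ca`` — the same NPMI confirmation evaluated on sliding context-window
  counts (default width 5), with each word paired against every
  higher-ranked word;
* ``cp`` — Fitelson's confirmation measure
  ``[P(j|i) - P(j|not i)] / [P(j|i) + P(j|not i)]`` on document-level
  counts, again with one-preceding-word pairing.

Per-topic coherence is the mean over the p(p-1)/2 word pairs; model-level
coherence is the mean over topics.  Topic diversity is the fraction of
distinct words among the K*p top words.  Held-out perplexity uses the
document-completion protocol: theta is inferred from half of each test
document (alternating token positions) and the other half is scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import TimeSlicedCorpus
from .generative import ModelParameters, top_words_of, softmax
from .inference import VariationalState, _theta_net_forward, _net_input

_SMOOTH = 1e-12


class MetricError(ValueError):
    pass


@dataclass
class CooccurrenceStats:
    """Exact unit-level co-occurrence counts over a reference corpus.

    A "unit" is either a whole document or a sliding context window of
    ``window`` tokens.  ``doc_freq[w]`` counts units containing w; joint
    counts are computed on demand from the stored per-word unit sets and are
    symmetric, with ``joint <= min(marginals)`` by construction.
    """

    n_units: int
    mode: str  # "document" or "window"
    window: int | None
    _units: dict[str, set[int]] = field(repr=False)

    @property
    def doc_freq(self) -> dict[str, int]:
        return {w: len(s) for w, s in self._units.items()}

    def count(self, word: str) -> int:
        return len(self._units.get(word, ()))

    def joint(self, w1: str, w2: str) -> int:
        a = self._units.get(w1)
        b = self._units.get(w2)
        if not a or not b:
            return 0
        if len(b) < len(a):
            a, b = b, a
        return sum(1 for u in a if u in b)

    def __contains__(self, word: str) -> bool:
        return word in self._units


def _token_streams(reference) -> Iterable[list[str]]:
    """Documents as word lists; BOW documents expand in vocabulary order."""
    if isinstance(reference, TimeSlicedCorpus):
        terms = reference.vocabulary.terms
        for t in range(reference.n_slices):
            mat = reference.counts[t]
            for j in range(mat.shape[0]):
                row = mat.getrow(j).tocoo()
                stream: list[str] = []
                for v, c in zip(row.col, row.data):
                    stream.extend([terms[v]] * int(c))
                yield stream
    else:
        for doc in reference:
            yield [str(w) for w in doc]


def build_cooccurrence(reference, window: int | None = None) -> CooccurrenceStats:
    """Count document-level (``window=None``) or sliding-window co-occurrence.

    Each word/pair is counted at most once per unit.  For bag-of-words input
    in window mode the token stream is the canonical vocabulary-order
    expansion of the counts (BOW corpora carry no word order).
    """
    if window is not None and window < 2:
        raise MetricError("window must be >= 2 (or None for document mode)")
    units: dict[str, set[int]] = {}
    uid = 0
    empty = True
    for stream in _token_streams(reference):
        empty = False
        if window is None:
            groups = [stream]
        elif len(stream) <= window:
            groups = [stream]
        else:
            groups = [stream[i:i + window] for i in range(len(stream) - window + 1)]
        for g in groups:
            for w in set(g):
                units.setdefault(w, set()).add(uid)
            uid += 1
    if empty:
        raise MetricError("empty reference corpus")
    return CooccurrenceStats(
        n_units=uid, mode="document" if window is None else "window",
        window=window, _units=units,
    )


def npmi(pair: tuple[str, str], stats: CooccurrenceStats,
         smoothing: float = _SMOOTH, strict: bool = False) -> float:
    """Normalized pointwise mutual information of a word pair in [-1, 1].

    ``log[(P(i,j)+s) / (P(i) P(j))] / -log(P(i,j)+s)`` with unit-level
    probabilities.  A pair that always co-occurs wherever either word
    appears scores 1; independent words score 0; never co-occurring words
    approach -1 as the smoothing vanishes.  Words absent from the reference
    score 0 with a warning (or raise in strict mode).
    """
    w1, w2 = pair
    if w1 not in stats or w2 not in stats:
        missing = [w for w in (w1, w2) if w not in stats]
        if strict:
            raise MetricError(f"word(s) {missing} absent from reference corpus")
        warnings.warn(f"word(s) {missing} absent from reference; NPMI set to 0", stacklevel=2)
        return 0.0
    n = stats.n_units
    p1, p2 = stats.count(w1) / n, stats.count(w2) / n
    pj = stats.joint(w1, w2) / n
    if pj >= 1.0:
        return 1.0
    num = np.log((pj + smoothing) / (p1 * p2))
    den = -np.log(pj + smoothing)
    return float(num / den)


def _cp_pair(confirmed: str, given: str, stats: CooccurrenceStats,
             smoothing: float = _SMOOTH) -> float:
    """Fitelson confirmation of ``confirmed`` by ``given`` on unit counts."""
    n = stats.n_units
    n_g = stats.count(given)
    n_c = stats.count(confirmed)
    nj = stats.joint(confirmed, given)
    p_cond = (nj + smoothing) / (n_g + smoothing)
    p_not = (n_c - nj + smoothing) / (n - n_g + smoothing)
    return float((p_cond - p_not) / (p_cond + p_not))


def coherence(top_words: Sequence[str], stats: CooccurrenceStats, measure: str = "npmi",
              smoothing: float = _SMOOTH) -> float:
    """Mean pairwise association of one topic's ranked top words.

    ``npmi`` and ``ca`` average NPMI over the p(p-1)/2 unordered pairs
    (``ca`` requires window-mode stats); ``cp`` averages Fitelson's
    confirmation of each word by every higher-ranked word.  Topics with
    fewer than 2 distinct words trigger a warning and are scored on the
    available pairs (0.0 when none).
    """
    words = list(dict.fromkeys(top_words))  # dedupe, preserve rank order
    if len(words) < len(top_words):
        warnings.warn("duplicate top words; scoring distinct words only", stacklevel=2)
    if len(words) < 2:
        warnings.warn("fewer than 2 distinct top words; coherence set to 0", stacklevel=2)
        return 0.0
    if measure == "ca" and stats.mode != "window":
        raise MetricError("CA coherence needs window-mode co-occurrence stats")
    vals = []
    for j in range(1, len(words)):
        for i in range(j):
            if measure in ("npmi", "ca"):
                vals.append(npmi((words[i], words[j]), stats, smoothing))
            elif measure == "cp":
                vals.append(_cp_pair(words[j], words[i], stats, smoothing))
            else:
                raise MetricError(f"unknown coherence measure {measure!r}")
    return float(np.mean(vals))


def topic_diversity(top_word_lists: Sequence[Sequence[str]],
                    K: int | None = None, p: int | None = None) -> float:
    """Fraction of distinct words among the K lists of p top words each.

    Equals 1 iff all K*p words are distinct and 1/K when every topic repeats
    the same p words.
    """
    K = len(top_word_lists) if K is None else K
    if K != len(top_word_lists):
        raise MetricError(f"expected {K} topic lists, got {len(top_word_lists)}")
    lengths = {len(lst) for lst in top_word_lists}
    if len(lengths) != 1:
        raise MetricError(f"ragged top-word lists (lengths {sorted(lengths)})")
    p_actual = lengths.pop()
    if p is not None and p != p_actual:
        raise MetricError(f"expected p={p} words per topic, got {p_actual}")
    union = set()
    for lst in top_word_lists:
        union.update(lst)
    return len(union) / (K * p_actual)


def perplexity(test: TimeSlicedCorpus, params: ModelParameters,
               state: VariationalState, protocol: str = "completion",
               return_excluded: bool = False):
    """Held-out perplexity ``exp(-log-likelihood / tokens)``; lower is better.

    ``completion``: each document's canonical token expansion is split by
    alternating positions; theta is the variational mean inferred from the
    first half and the second half is scored under the mixture
    ``sum_k theta_k beta[t, k]``.  Documents too short to split are excluded
    (their count is available via ``return_excluded``).  ``bound`` scores
    whole documents at the variational mean instead (an ELBO-style
    alternative, no splitting).
    """
    if protocol not in ("completion", "bound"):
        raise MetricError(f"unknown perplexity protocol {protocol!r}")
    if test.n_words != params.n_words:
        raise MetricError("test corpus vocabulary does not match the model")
    V = params.n_words
    total_ll, total_tokens, excluded = 0.0, 0, 0
    for t in range(min(test.n_slices, params.n_slices)):
        beta_t = softmax(params.alpha[t] @ params.rho, axis=1)
        counts = test.dense_counts(t)
        for j in range(counts.shape[0]):
            row = counts[j]
            n_tok = int(row.sum())
            if protocol == "bound":
                if n_tok == 0:
                    excluded += 1
                    continue
                theta = _variational_mean(row, state, params.eta[t])
                total_ll += float(row @ np.log(theta @ beta_t))
                total_tokens += n_tok
                continue
            if n_tok < 2:
                excluded += 1
                continue
            tokens = np.repeat(np.arange(V), row.astype(int))
            first, second = tokens[0::2], tokens[1::2]
            obs = np.bincount(first, minlength=V).astype(float)
            held = np.bincount(second, minlength=V).astype(float)
            theta = _variational_mean(obs, state, params.eta[t])
            total_ll += float(held @ np.log(theta @ beta_t))
            total_tokens += int(held.sum())
    if total_tokens == 0:
        raise MetricError("no scorable documents in the test corpus")
    ppl = float(np.exp(-total_ll / total_tokens))
    if return_excluded:
        return ppl, excluded
    return ppl


def _variational_mean(counts_row: np.ndarray, state: VariationalState,
                      eta_t: np.ndarray) -> np.ndarray:
    x = _net_input(counts_row[None, :], eta_t)
    mu, _ = _theta_net_forward(state.theta_net, x)
    return softmax(mu, axis=1)[0]


@dataclass
class TopicQualityReport:
    """Coherence, diversity and perplexity of one fitted model."""

    per_topic: dict[str, list[float]]
    mean: dict[str, float]
    td: float
    perplexity: float | None
    top_words_tc: list[list[str]]
    top_words_td: list[list[str]]
    p_coherence: int
    p_diversity: int

    def to_json(self) -> str:
        payload = {
            "coherence_per_topic": self.per_topic,
            "coherence_mean": self.mean,
            "topic_diversity": self.td,
            "perplexity": self.perplexity,
            "p_coherence": self.p_coherence,
            "p_diversity": self.p_diversity,
            "top_words": self.top_words_tc,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_rows(self) -> list[dict]:
        rows = []
        for measure, vals in sorted(self.per_topic.items()):
            for k, v in enumerate(vals):
                rows.append({"topic": k, "measure": measure, "score": v})
        return rows


def evaluate_model(
    params: ModelParameters,
    state: VariationalState,
    vocabulary,
    reference: TimeSlicedCorpus,
    test: TimeSlicedCorpus | None = None,
    measures: Sequence[str] = ("ca", "cp", "npmi"),
    p_coherence: int = 10,
    p_diversity: int = 25,
    window: int = 5,
    slice_index: int | None = None,
) -> TopicQualityReport:
    """Full topic-quality evaluation of a fitted model.

    Topic-word distributions are averaged over time slices unless
    ``slice_index`` picks one.  Coherence uses the given reference corpus
    (conventionally the training split); perplexity needs ``test``.
    """
    beta = params.beta()
    beta_k = beta[slice_index] if slice_index is not None else beta.mean(axis=0)
    K = beta_k.shape[0]
    tops_tc = [top_words_of(beta_k[k], vocabulary, p_coherence) for k in range(K)]
    tops_td = [top_words_of(beta_k[k], vocabulary, p_diversity) for k in range(K)]

    doc_stats = build_cooccurrence(reference, window=None)
    win_stats = build_cooccurrence(reference, window=window) if "ca" in measures else None
    per_topic: dict[str, list[float]] = {}
    for m in measures:
        stats = win_stats if m == "ca" else doc_stats
        per_topic[m] = [coherence(tops_tc[k], stats, measure=m) for k in range(K)]
    mean = {m: float(np.mean(v)) for m, v in per_topic.items()}
    td = topic_diversity(tops_td)
    ppl = perplexity(test, params, state) if test is not None else None
    return TopicQualityReport(
        per_topic=per_topic, mean=mean, td=td, perplexity=ppl,
        top_words_tc=tops_tc, top_words_td=tops_td,
        p_coherence=p_coherence, p_diversity=p_diversity,
    )
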