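"""Corpus ingestion, preprocessing and time-sliced bag-of-words containers.

A corpus is a set of documents, each carrying raw text (or pre-tokenized
words), an integer year and a categorical label (e.g. the funding institute a
grant was submitted to).  Preprocessing lowercases and tokenizes the text,
optionally lemmatizes, removes stop words, and filters the vocabulary by
document frequency (words in more than ``max_df`` of documents are dropped)
and corpus-wide count (words seen fewer than ``min_count`` times are
dropped); documents left with fewer than ``min_doc_len`` tokens are removed.
Because removing documents changes document frequencies, the filters are
iterated to a fixpoint so that preprocessing is idempotent.

The resulting :class:`TimeSlicedCorpus` stores one sparse count matrix per
time slice (years are mapped to contiguous slice indices in ascending order;
years with no surviving documents are dropped) together with integer labels
drawn from a single global category set.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z][a-z0-9'\-]*")

#: Minimal built-in English stop word list.  Users analysing real corpora are
#: expected to supply their own, larger list.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been by for from has have in is it its of on or
    that the this to was were which will with we our not can may these those
    between during more other such than then there when who also into each
    both their they them he she his her you your i but if do does did so no
    nor only own same too very just about above after again against all any
    because before below further here how most off once over under until up
    what where why out few down being having most""".split()
)


class CorpusError(ValueError):
    """Raised for malformed corpora or corpus files."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered vocabulary with a word -> column-index bijection."""

    terms: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise CorpusError("vocabulary must contain at least one word")
        idx = {w: i for i, w in enumerate(self.terms)}
        if len(idx) != len(self.terms):
            raise CorpusError("vocabulary terms must be unique")
        object.__setattr__(self, "index", idx)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, word: str) -> bool:
        return word in self.index


@dataclass
class RawDocument:
    """A document before bag-of-words conversion.

    ``text`` may be a raw string (tokenized by the default lowercasing
    tokenizer) or an already-tokenized sequence of words.
    """

    text: str | Sequence[str]
    year: int
    label: str

    def tokens(self) -> list[str]:
        if isinstance(self.text, str):
            return _TOKEN_RE.findall(self.text.lower())
        return [str(t).lower() for t in self.text]


@dataclass
class BowDocument:
    """One document as a dense count vector with its slice and label."""

    counts: np.ndarray
    slice: int
    label: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise CorpusError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise CorpusError("counts must be non-negative")
        if self.slice < 0:
            raise CorpusError("slice index must be non-negative")

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())


class TimeSlicedCorpus:
    """Bag-of-words corpus partitioned into consecutive time slices.

    Parameters
    ----------
    counts
        One ``N_t x V`` sparse count matrix per slice.
    labels
        One integer label array of length ``N_t`` per slice, indexing into
        ``label_names``.
    vocabulary
        Shared vocabulary of size ``V``.
    label_names
        Global ordered category list of size ``M``.
    years
        Calendar year of each slice, ascending.
    """

    def __init__(
        self,
        counts: Sequence[sp.spmatrix],
        labels: Sequence[np.ndarray],
        vocabulary: Vocabulary,
        label_names: Sequence[str],
        years: Sequence[int],
    ) -> None:
        if len(counts) < 1:
            raise CorpusError("corpus needs at least one time slice")
        if not (len(counts) == len(labels) == len(years)):
            raise CorpusError("counts, labels and years must have equal length")
        if list(years) != sorted(set(int(y) for y in years)):
            raise CorpusError("slice years must be strictly ascending")
        V = len(vocabulary)
        self.counts: list[sp.csr_matrix] = []
        self.labels: list[np.ndarray] = []
        for t, (c, y) in enumerate(zip(counts, labels)):
            c = sp.csr_matrix(c)
            if c.shape[1] != V:
                raise CorpusError(
                    f"slice {t}: count matrix has {c.shape[1]} columns, vocabulary has {V}"
                )
            y = np.asarray(y, dtype=np.int64)
            if c.shape[0] != y.shape[0]:
                raise CorpusError(f"slice {t}: {c.shape[0]} documents but {y.shape[0]} labels")
            if y.size and (y.min() < 0 or y.max() >= len(label_names)):
                raise CorpusError(f"slice {t}: label index out of range")
            if c.nnz and c.data.min() < 0:
                raise CorpusError(f"slice {t}: negative counts")
            self.counts.append(c)
            self.labels.append(y)
        self.vocabulary = vocabulary
        self.label_names = list(label_names)
        self.years = [int(y) for y in years]

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return len(self.counts)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    @property
    def n_docs(self) -> int:
        return sum(c.shape[0] for c in self.counts)

    @property
    def docs_per_slice(self) -> list[int]:
        return [c.shape[0] for c in self.counts]

    def total_tokens(self) -> int:
        return int(sum(c.sum() for c in self.counts))

    def year_of_slice(self, t: int) -> int:
        return self.years[t]

    def slice_of_year(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise CorpusError(f"no slice for year {year}") from None

    def dense_counts(self, t: int) -> np.ndarray:
        return np.asarray(self.counts[t].todense(), dtype=np.float64)

    def subset(self, indices_per_slice: Sequence[np.ndarray]) -> "TimeSlicedCorpus":
        """Corpus restricted to the given per-slice document indices."""
        counts = [self.counts[t][np.asarray(ix, dtype=int)] for t, ix in enumerate(indices_per_slice)]
        labels = [self.labels[t][np.asarray(ix, dtype=int)] for t, ix in enumerate(indices_per_slice)]
        return TimeSlicedCorpus(counts, labels, self.vocabulary, self.label_names, self.years)

    def iter_docs(self) -> Iterable[BowDocument]:
        """Yield every document as a :class:`BowDocument`, slice by slice."""
        for t, (c, y) in enumerate(zip(self.counts, self.labels)):
            dense = np.asarray(c.todense())
            for j in range(c.shape[0]):
                yield BowDocument(counts=dense[j], slice=t, label=int(y[j]))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_corpus(
    raw: Sequence[RawDocument],
    stopwords: Iterable[str] | None = None,
    max_df: float = 0.8,
    min_count: int = 10,
    min_doc_len: int = 10,
    lemmatizer: Callable[[str], str] | None = None,
) -> TimeSlicedCorpus:
    """Filter, lemmatize and convert raw documents to a time-sliced BOW corpus.

    Words appearing in more than ``max_df`` (fraction) of documents, seen
    fewer than ``min_count`` times corpus-wide, or present in ``stopwords``
    are removed; documents with fewer than ``min_doc_len`` surviving tokens
    are dropped.  The two filters interact (dropping documents changes
    document frequencies), so they are applied repeatedly until the corpus is
    stable; this makes the operation idempotent.
    """
    if not raw:
        raise CorpusError("empty corpus")
    if not (0 < max_df <= 1):
        raise ValueError(f"max_df must be in (0, 1], got {max_df}")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    stop = frozenset(stopwords) if stopwords is not None else DEFAULT_STOPWORDS
    lemma = lemmatizer if lemmatizer is not None else (lambda w: w)

    docs: list[Counter] = []
    meta: list[tuple[int, str]] = []
    for i, doc in enumerate(raw):
        try:
            year = int(doc.year)
        except (TypeError, ValueError):
            raise CorpusError(f"document {i}: year {doc.year!r} is not an integer") from None
        toks = [lemma(t) for t in doc.tokens() if t not in stop]
        toks = [t for t in toks if t not in stop]  # lemma may map onto a stop word
        if not toks:
            continue
        docs.append(Counter(toks))
        meta.append((year, str(doc.label)))

    # Iterate the vocabulary/document filters to a fixpoint.
    while True:
        n_docs = len(docs)
        if n_docs == 0:
            raise CorpusError("all documents removed by preprocessing")
        df: Counter = Counter()
        total: Counter = Counter()
        for d in docs:
            for w, c in d.items():
                df[w] += 1
                total[w] += c
        vocab_set = {
            w for w in df if df[w] <= max_df * n_docs and total[w] >= min_count
        }
        new_docs, new_meta = [], []
        changed = False
        for d, m in zip(docs, meta):
            kept = Counter({w: c for w, c in d.items() if w in vocab_set})
            if sum(kept.values()) < min_doc_len:
                changed = True
                continue
            if len(kept) != len(d):
                changed = True
            new_docs.append(kept)
            new_meta.append(m)
        docs, meta = new_docs, new_meta
        if not changed:
            break
    if not docs:
        raise CorpusError("all documents removed by preprocessing")

    vocabulary = Vocabulary(tuple(sorted(vocab_set)))
    years = sorted({y for y, _ in meta})
    label_names = sorted({lab for _, lab in meta})
    label_index = {lab: i for i, lab in enumerate(label_names)}
    year_index = {y: t for t, y in enumerate(years)}

    per_slice_rows: list[list[Counter]] = [[] for _ in years]
    per_slice_labels: list[list[int]] = [[] for _ in years]
    for d, (y, lab) in zip(docs, meta):
        per_slice_rows[year_index[y]].append(d)
        per_slice_labels[year_index[y]].append(label_index[lab])

    counts = []
    for rows in per_slice_rows:
        mat = sp.lil_matrix((len(rows), len(vocabulary)), dtype=np.int64)
        for j, d in enumerate(rows):
            for w, c in d.items():
                mat[j, vocabulary.index[w]] = c
        counts.append(mat.tocsr())
    labels = [np.asarray(lab, dtype=np.int64) for lab in per_slice_labels]
    return TimeSlicedCorpus(counts, labels, vocabulary, label_names, years)


def split_corpus(
    corpus: TimeSlicedCorpus,
    fractions: tuple[float, float, float] = (0.85, 0.05, 0.10),
    seed: int = 0,
) -> tuple[TimeSlicedCorpus, TimeSlicedCorpus, TimeSlicedCorpus]:
    """Split into train/validation/test, stratified within each time slice.

    Per-slice sizes follow the fractions by largest-remainder rounding, so
    exactly representable proportions are honoured exactly.  Slices with
    fewer documents than splits go entirely to training (with a warning).
    Deterministic for a fixed ``seed``.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three positive numbers summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for t, c in enumerate(corpus.counts):
        n = c.shape[0]
        perm = rng.permutation(n)
        if n < 3:
            if n:
                warnings.warn(
                    f"slice {t} has only {n} document(s); assigning all to training",
                    stacklevel=2,
                )
            sizes = [n, 0, 0]
        else:
            exact = fr * n
            base = np.floor(exact).astype(int)
            rem = n - base.sum()
            order = np.argsort(-(exact - base), kind="stable")
            for i in range(rem):
                base[order[i]] += 1
            if base[0] == 0:  # every non-empty slice contributes to training
                donor = int(np.argmax(base))
                base[donor] -= 1
                base[0] += 1
            sizes = base.tolist()
        offsets = np.cumsum([0] + sizes)
        for p in range(3):
            parts[p].append(np.sort(perm[offsets[p]:offsets[p + 1]]))
    return tuple(corpus.subset(parts[p]) for p in range(3))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# File input / output
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, format: str = "jsonl") -> list[RawDocument]:
    """Read raw documents from a JSONL or 3-column TSV file.

    JSONL rows must carry ``text``, ``year`` and ``label`` keys; TSV files
    must have a header naming those three columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    docs: list[RawDocument] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}:{lineno}: invalid JSON ({exc})") from None
                missing = {"text", "year", "label"} - obj.keys()
                if missing:
                    raise CorpusError(f"{path}:{lineno}: missing key(s) {sorted(missing)}")
                docs.append(RawDocument(obj["text"], int(obj["year"]), str(obj["label"])))
    elif format == "tsv":
        import csv

        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = {"text", "year", "label"} - set(reader.fieldnames or [])
        if missing:
            raise CorpusError(f"{path}: missing column(s) {sorted(missing)}")
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=2):
                if row["text"] is None or row["year"] is None or row["label"] is None:
                    raise CorpusError(f"{path}:{lineno}: incomplete row")
                try:
                    year = int(row["year"])
                except ValueError:
                    raise CorpusError(f"{path}:{lineno}: year {row['year']!r} not an integer") from None
                docs.append(RawDocument(row["text"], year, row["label"]))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not docs:
        raise CorpusError(f"{path}: no documents")
    return docs


_BOW_FORMAT_VERSION = 1


def write_bow(corpus: TimeSlicedCorpus, path: str | Path) -> None:
    """Write a BOW corpus as matrix-market counts plus plain-text sidecars.

    Layout under ``path`` (a directory): ``counts.mtx`` (all documents
    stacked, slice by slice), ``vocabulary.txt`` (one word per line) and
    ``metadata.json`` (years, per-document slice and label, label names).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stacked = sp.vstack([c.tocoo() for c in corpus.counts]).tocoo()
    mmwrite(str(path / "counts.mtx"), stacked, field="integer")
    (path / "vocabulary.txt").write_text("\n".join(corpus.vocabulary.terms) + "\n", encoding="utf-8")
    slice_of_doc = np.concatenate(
        [np.full(c.shape[0], t, dtype=int) for t, c in enumerate(corpus.counts)]
    )
    meta = {
        "format_version": _BOW_FORMAT_VERSION,
        "years": corpus.years,
        "label_names": corpus.label_names,
        "slice_of_doc": slice_of_doc.tolist(),
        "labels": np.concatenate(corpus.labels).tolist() if corpus.n_docs else [],
    }
    (path / "metadata.json").write_text(json.dumps(meta), encoding="utf-8")


def read_bow(path: str | Path) -> TimeSlicedCorpus:
    """Load a corpus written by :func:`write_bow`, validating the sidecars."""
    path = Path(path)
    for name in ("counts.mtx", "vocabulary.txt", "metadata.json"):
        if not (path / name).exists():
            raise CorpusError(f"{path}: missing {name}")
    stacked = sp.csr_matrix(mmread(str(path / "counts.mtx")))
    terms = tuple(
        w for w in (path / "vocabulary.txt").read_text(encoding="utf-8").splitlines() if w
    )
    meta = json.loads((path / "metadata.json").read_text(encoding="utf-8"))
    if len(terms) != stacked.shape[1]:
        raise CorpusError(
            f"{path}: vocabulary has {len(terms)} words but matrix has {stacked.shape[1]} columns"
        )
    slice_of_doc = np.asarray(meta["slice_of_doc"], dtype=int)
    labels_flat = np.asarray(meta["labels"], dtype=int)
    if slice_of_doc.shape[0] != stacked.shape[0] or labels_flat.shape[0] != stacked.shape[0]:
        raise CorpusError(f"{path}: metadata row count does not match matrix")
    years = [int(y) for y in meta["years"]]
    counts, labels = [], []
    for t in range(len(years)):
        rows = np.nonzero(slice_of_doc == t)[0]
        counts.append(stacked[rows])
        labels.append(labels_flat[rows])
    return TimeSlicedCorpus(counts, labels, Vocabulary(terms), meta["label_names"], years)


def load_embeddings(
    path: str | Path,
    vocabulary: Vocabulary,
    dim: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Load a whitespace word-embedding table restricted to ``vocabulary``.

    Returns an ``L x V`` array.  Words absent from the table are initialized
    from a seeded standard Gaussian (reported via a warning), matching the
    random initialization used when no table is given at all.
    """
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split()
            if not fields:
                continue
            if len(fields) < 2:
                raise CorpusError(f"{path}:{lineno}: malformed embedding row")
            word, vec = fields[0], np.asarray(fields[1:], dtype=float)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise CorpusError(
                    f"{path}:{lineno}: embedding of length {vec.size}, expected {dim}"
                )
            if word in vocabulary:
                table[word] = vec
    if dim is None:
        raise CorpusError(f"{path}: no embedding rows")
    rng = np.random.default_rng(seed)
    rho = np.empty((dim, len(vocabulary)))
    n_missing = 0
    for i, w in enumerate(vocabulary.terms):
        if w in table:
            rho[:, i] = table[w]
        else:
            rho[:, i] = rng.standard_normal(dim)
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing}/{len(vocabulary)} vocabulary words missing from {path}; "
            "initialized randomly",
            stacklevel=2,
        )
    return rho
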