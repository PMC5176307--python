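"""Bag-of-words feature extraction for child-level evaluation documents.

The pipeline mirrors standard clinical text-mining practice: lower-case,
drop digits and punctuation, stem, extract contiguous 1-3 word phrases,
keep phrases occurring in at least a minimum fraction of children's files
(3% by default), and weight counts by term-frequency x inverse-document-
frequency.  Document frequency is always computed on child-level aggregated
documents, never on individual evaluations, and the vocabulary (terms, df,
N) fitted on a training year is frozen when transforming a later year.

TF-IDF variant: relative term frequency within the child's file times
log2(N / df).  A term present in every file therefore carries zero weight.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from pydantic import BaseModel, Field, model_validator

from .corpus import Corpus, aggregate_child_text
from .stem import get_stemmer

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

# corpora repeat a small set of distinct words millions of times; memoize
# stems per (stemmer, word)
_STEM_CACHE: dict[tuple[str, str], str] = {}


class VocabularySpec(BaseModel):
    """Parameters that define the n-gram vocabulary."""

    ngram_min: int = Field(default=1, ge=1)
    ngram_max: int = Field(default=3, ge=1)
    min_df_fraction: float = Field(default=0.03, gt=0.0, le=1.0)
    stemmer_id: str = "porter"

    @model_validator(mode="after")
    def _ordered(self) -> "VocabularySpec":
        if self.ngram_min > self.ngram_max:
            raise ValueError("ngram_min must not exceed ngram_max")
        return self


@dataclass
class Vocabulary:
    """Frozen term list with training document frequencies.

    ``terms`` are unique stemmed n-grams in lexicographic order; ``df[j]``
    is the number of distinct child documents containing ``terms[j]`` at
    least once in the corpus of ``n_documents`` children the vocabulary was
    built from.
    """

    terms: list[str]
    document_frequency: np.ndarray
    n_documents: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.document_frequency = np.asarray(self.document_frequency,
                                             dtype=np.int64)
        if len(self.terms) != len(self.document_frequency):
            raise ValueError("terms and document_frequency length mismatch")
        if np.any(self.document_frequency < 1):
            raise ValueError("document frequencies must be >= 1")
        self._index = {t: j for j, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def index(self, term: str) -> int:
        return self._index[term]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"#n_documents={self.n_documents}\n")
            fh.write("term\tdf\n")
            for t, d in zip(self.terms, self.document_frequency):
                fh.write(f"{t}\t{int(d)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        n_documents = int(lines[0].split("=", 1)[1])
        terms, dfs = [], []
        for row in lines[2:]:
            t, d = row.split("\t")
            terms.append(t)
            dfs.append(int(d))
        return cls(terms=terms, document_frequency=np.array(dfs),
                   n_documents=n_documents)


@dataclass
class TermDocumentMatrix:
    """Children x terms matrix, count- or TF-IDF-weighted."""

    child_ids: list[str]
    vocabulary: Vocabulary
    weights: sp.csr_matrix
    weighting: str  # "count" | "tfidf"

    def __post_init__(self):
        self.weights = sp.csr_matrix(self.weights)
        if self.weights.shape != (len(self.child_ids), len(self.vocabulary)):
            raise ValueError(
                f"matrix shape {self.weights.shape} does not match "
                f"{len(self.child_ids)} children x "
                f"{len(self.vocabulary)} terms"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.weights.todense())

    def save(self, stem_path: str | Path) -> None:
        """Write <stem>.mtx plus <stem>.rows.txt / <stem>.cols.txt sidecars."""
        stem_path = Path(stem_path)
        scipy.io.mmwrite(str(stem_path.with_suffix(".mtx")),
                         sp.coo_matrix(self.weights))
        stem_path.with_suffix(".rows.txt").write_text(
            "\n".join(self.child_ids) + "\n", encoding="utf-8")
        stem_path.with_suffix(".cols.txt").write_text(
            "\n".join(self.vocabulary.terms) + "\n", encoding="utf-8")


def normalize_and_tokenize(text: str, stemmer_id: str = "porter") -> list[str]:
    """Lower-case, strip digits/punctuation, split into words, and stem.

    Splitting keeps runs of letters only (hyphens, apostrophes and any
    other non-letter characters act as separators), so "3 words: playing"
    yields the stemmed tokens of "words" and "playing".
    """
    stemmer = get_stemmer(stemmer_id)
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        key = (stemmer_id, tok)
        stem = _STEM_CACHE.get(key)
        if stem is None:
            stem = _STEM_CACHE[key] = stemmer(tok)
        out.append(stem)
    return out


def extract_ngrams(tokens: Sequence[str], ngram_min: int = 1,
                   ngram_max: int = 3) -> list[str]:
    """All contiguous n-grams of the token list, space-joined, with multiplicity.

    N-grams never span document boundaries because tokenization is applied
    per aggregated child document.
    """
    if not 1 <= ngram_min <= ngram_max:
        raise ValueError("require 1 <= ngram_min <= ngram_max")
    out: list[str] = []
    n_tok = len(tokens)
    for n in range(ngram_min, ngram_max + 1):
        for i in range(n_tok - n + 1):
            out.append(" ".join(tokens[i:i + n]))
    return out


def min_df_count(n_documents: int, min_df_fraction: float) -> int:
    """Smallest document count satisfying the minimum-df fraction rule.

    Ceiling of n_documents x fraction (with a tiny guard against binary
    floating-point overshoot, so 100 x 0.03 -> 3, not 4), floored at 1.
    """
    if n_documents < 1:
        raise ValueError("n_documents must be >= 1")
    return max(1, math.ceil(n_documents * min_df_fraction - 1e-9))


def tokenize_corpus(corpus: Corpus, spec: VocabularySpec
                    ) -> tuple[list[str], list[list[str]]]:
    """Aggregate and tokenize every child: (child_ids, token documents)."""
    ids, docs = [], []
    for child in corpus.children:
        ids.append(child.child_id)
        docs.append(normalize_and_tokenize(aggregate_child_text(child),
                                           spec.stemmer_id))
    return ids, docs


def build_vocabulary(documents: Sequence[Sequence[str]],
                     spec: VocabularySpec) -> Vocabulary:
    """N-grams occurring in at least ``min_df_count`` distinct documents."""
    if len(documents) == 0:
        raise ValueError("need at least one document")
    df: Counter[str] = Counter()
    for tokens in documents:
        df.update(set(extract_ngrams(tokens, spec.ngram_min, spec.ngram_max)))
    threshold = min_df_count(len(documents), spec.min_df_fraction)
    terms = sorted(t for t, d in df.items() if d >= threshold)
    return Vocabulary(
        terms=terms,
        document_frequency=np.array([df[t] for t in terms], dtype=np.int64),
        n_documents=len(documents),
    )


def build_count_matrix(documents: Sequence[Sequence[str]],
                       vocabulary: Vocabulary,
                       child_ids: Sequence[str] | None = None,
                       spec: VocabularySpec | None = None
                       ) -> TermDocumentMatrix:
    """Occurrence counts of vocabulary terms per document (OOV terms ignored)."""
    if len(vocabulary) == 0:
        raise ValueError("vocabulary is empty")
    spec = spec or VocabularySpec()
    if child_ids is None:
        child_ids = [f"doc{i}" for i in range(len(documents))]
    rows, cols, vals = [], [], []
    for i, tokens in enumerate(documents):
        counts = Counter(
            extract_ngrams(tokens, spec.ngram_min, spec.ngram_max))
        for term, c in counts.items():
            j = vocabulary._index.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    mat = sp.csr_matrix(
        (np.asarray(vals, dtype=np.float64), (rows, cols)),
        shape=(len(documents), len(vocabulary)),
    )
    return TermDocumentMatrix(child_ids=list(child_ids), vocabulary=vocabulary,
                              weights=mat, weighting="count")


def apply_tfidf(counts: TermDocumentMatrix,
                df_source: Vocabulary | None = None) -> TermDocumentMatrix:
    """Weight counts by relative term frequency x log2(N / df).

    ``df_source`` supplies N and per-term df — the training vocabulary when
    transforming a new surveillance year (frozen statistics), or the counts'
    own vocabulary when fitting.  Rows with zero counted tokens map to zero
    rows.
    """
    if counts.weighting != "count":
        raise ValueError("apply_tfidf expects a count-weighted matrix")
    vocab = df_source if df_source is not None else counts.vocabulary
    if len(vocab) != counts.shape[1]:
        raise ValueError("df_source vocabulary does not match matrix columns")
    df = vocab.document_frequency.astype(np.float64)
    if np.any(df <= 0):
        raise ValueError("document frequency must be positive for all terms")
    idf = np.log2(vocab.n_documents / df)
    row_totals = np.asarray(counts.weights.sum(axis=1)).ravel()
    inv_tot = np.divide(1.0, row_totals, out=np.zeros_like(row_totals),
                        where=row_totals > 0)
    weights = sp.diags(inv_tot) @ counts.weights @ sp.diags(idf)
    weights = sp.csr_matrix(weights)
    weights.eliminate_zeros()
    return TermDocumentMatrix(child_ids=counts.child_ids, vocabulary=vocab,
                              weights=weights, weighting="tfidf")


def fit_tdm(corpus: Corpus, spec: VocabularySpec
            ) -> tuple[TermDocumentMatrix, Vocabulary]:
    """Fit vocabulary on a training corpus and return its TF-IDF matrix."""
    ids, docs = tokenize_corpus(corpus, spec)
    vocab = build_vocabulary(docs, spec)
    counts = build_count_matrix(docs, vocab, child_ids=ids, spec=spec)
    return apply_tfidf(counts, vocab), vocab


def transform_tdm(corpus: Corpus, vocabulary: Vocabulary,
                  spec: VocabularySpec) -> TermDocumentMatrix:
    """Vectorize any corpus with a frozen training vocabulary (df and N)."""
    ids, docs = tokenize_corpus(corpus, spec)
    counts = build_count_matrix(docs, vocabulary, child_ids=ids, spec=spec)
    return apply_tfidf(counts, vocabulary)


def restrict_terms(tdm: TermDocumentMatrix,
                   terms: Sequence[str]) -> TermDocumentMatrix:
    """Column-subset a matrix to the given terms (training df retained)."""
    vocab = tdm.vocabulary
    idx = np.array([vocab.index(t) for t in terms], dtype=np.int64)
    sub = Vocabulary(terms=list(terms),
                     document_frequency=vocab.document_frequency[idx],
                     n_documents=vocab.n_documents)
    return TermDocumentMatrix(child_ids=tdm.child_ids, vocabulary=sub,
                              weights=sp.csr_matrix(tdm.weights[:, idx]),
                              weighting=tdm.weighting)
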