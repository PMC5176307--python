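"""Tokenization, n-grams, DF filtering and TF-IDF against brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdsurv.textprep import (TermDocumentMatrix, Vocabulary, VocabularySpec,
                              apply_tfidf, build_count_matrix,
                              build_vocabulary, extract_ngrams, fit_tdm,
                              min_df_count, normalize_and_tokenize,
                              transform_tdm)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain dict/set comprehensions)
# ---------------------------------------------------------------------------

def oracle_ngrams(tokens, lo, hi):
    return [" ".join(tokens[i:i + n])
            for n in range(lo, hi + 1)
            for i in range(len(tokens) - n + 1)]


def oracle_vocabulary(docs, spec):
    threshold = math.ceil(len(docs) * spec.min_df_fraction - 1e-9)
    df = Counter()
    for d in docs:
        df.update(set(oracle_ngrams(d, spec.ngram_min, spec.ngram_max)))
    return sorted(t for t, c in df.items() if c >= max(threshold, 1))


def oracle_counts(docs, terms, spec):
    out = np.zeros((len(docs), len(terms)))
    for i, d in enumerate(docs):
        grams = oracle_ngrams(d, spec.ngram_min, spec.ngram_max)
        for j, t in enumerate(terms):
            out[i, j] = sum(g == t for g in grams)
    return out


def oracle_tfidf(counts, df, n_docs):
    out = np.zeros_like(counts, dtype=float)
    for i in range(counts.shape[0]):
        total = counts[i].sum()
        if total == 0:
            continue
        for j in range(counts.shape[1]):
            out[i, j] = counts[i, j] / total * math.log2(n_docs / df[j])
    return out


def random_docs(rng, n_docs=8, max_tokens=30, alphabet=("a", "b", "c", "d")):
    return [
        [alphabet[k] for k in rng.integers(0, len(alphabet),
                                           rng.integers(1, max_tokens))]
        for _ in range(n_docs)
    ]


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def test_tokenize_lowercases_and_strips_punctuation():
    # "eye" loses its final e under the reference algorithm ("ey"), like
    # any m=1 stem not ending consonant-vowel-consonant
    assert normalize_and_tokenize("Eye contact!!") == ["ey", "contact"]
    assert normalize_and_tokenize("EYE CONTACT", "identity") == \
        ["eye", "contact"]


def test_tokenize_stems_inflections():
    assert normalize_and_tokenize("playing, played") == ["play", "play"]
    # digits vanish, every surviving word is stemmed
    assert normalize_and_tokenize("3 words: playing, played") == \
        ["word", "play", "play"]


def test_tokenize_empty_and_symbol_only():
    assert normalize_and_tokenize("") == []
    assert normalize_and_tokenize("42 --- !!") == []


def test_tokenize_hyphens_and_apostrophes_split():
    assert normalize_and_tokenize("mother's follow-up") == \
        ["mother", "s", "follow", "up"]


# ---------------------------------------------------------------------------
# n-grams
# ---------------------------------------------------------------------------

def test_ngrams_exhaustive_enumeration():
    assert set(extract_ngrams(["a", "b", "c"], 1, 3)) == \
        {"a", "b", "c", "a b", "b c", "a b c"}


def test_ngrams_short_document():
    assert extract_ngrams(["a"], 1, 3) == ["a"]


def test_ngrams_counting_oracle():
    rng = np.random.default_rng(0)
    tokens = [f"t{k}" for k in rng.integers(0, 5, 12)]
    grams = extract_ngrams(tokens, 1, 3)
    assert len(grams) == 12 + 11 + 10
    assert Counter(grams) == Counter(oracle_ngrams(tokens, 1, 3))


def test_ngram_bounds_validated():
    with pytest.raises(ValueError):
        extract_ngrams(["a"], 2, 1)
    with pytest.raises(ValueError):
        extract_ngrams(["a"], 0, 2)


# ---------------------------------------------------------------------------
# DF threshold
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,frac,expect", [
    (1162, 0.03, 35),   # the 3%-of-1162 surveillance threshold
    (100, 0.03, 3),
    (33, 0.03, 1),
    (10, 1.0, 10),
    (5, 0.001, 1),
])
def test_min_df_count(n, frac, expect):
    assert min_df_count(n, frac) == expect


def test_min_df_count_requires_documents():
    with pytest.raises(ValueError):
        min_df_count(0, 0.03)


def test_vocabulary_boundary_at_threshold():
    """A term in 34 of 1162 docs is dropped; in 35 it is kept."""
    spec = VocabularySpec(ngram_max=1)
    docs = [["filler"] for _ in range(1162)]
    for i in range(34):
        docs[i] = docs[i] + ["borderline"]
    for i in range(40, 75):
        docs[i] = docs[i] + ["kept"]
    vocab = build_vocabulary(docs, spec)
    assert "borderline" not in vocab
    assert "kept" in vocab and "filler" in vocab


def test_identical_documents_keep_all_ngrams():
    docs = [["eye", "contact", "poor"]] * 3
    vocab = build_vocabulary(docs, VocabularySpec())
    assert set(vocab.terms) == set(oracle_ngrams(docs[0], 1, 3))
    assert all(df == 3 for df in vocab.document_frequency)


def test_vocabulary_monotone_in_threshold():
    rng = np.random.default_rng(3)
    docs = random_docs(rng)
    previous = None
    for frac in (0.05, 0.2, 0.4, 0.7, 1.0):
        vocab = set(build_vocabulary(
            docs, VocabularySpec(min_df_fraction=frac)).terms)
        if previous is not None:
            assert vocab <= previous
        previous = vocab


# ---------------------------------------------------------------------------
# counts and TF-IDF
# ---------------------------------------------------------------------------

def test_hand_counts():
    vocab = Vocabulary(terms=["a", "a b", "b"], document_frequency=[1, 1, 1],
                       n_documents=1)
    tdm = build_count_matrix([["a", "b", "a"]], vocab)
    assert tdm.to_dense().tolist() == [[2.0, 1.0, 1.0]]


def test_out_of_vocabulary_document_is_zero_row():
    vocab = Vocabulary(terms=["x"], document_frequency=[1], n_documents=1)
    tdm = build_count_matrix([["a", "b"]], vocab)
    assert tdm.to_dense().tolist() == [[0.0]]


def test_empty_vocabulary_rejected():
    vocab = Vocabulary(terms=[], document_frequency=[], n_documents=1)
    with pytest.raises(ValueError, match="empty"):
        build_count_matrix([["a"]], vocab)


def test_counts_match_sklearn_countvectorizer():
    """Independent library oracle for the n-gram counting."""
    from sklearn.feature_extraction.text import CountVectorizer
    rng = np.random.default_rng(11)
    docs = random_docs(rng)
    spec = VocabularySpec(min_df_fraction=0.2)
    vocab = build_vocabulary(docs, spec)
    tdm = build_count_matrix(docs, vocab, spec=spec)
    cv = CountVectorizer(analyzer=lambda d: oracle_ngrams(d, 1, 3),
                         vocabulary=vocab.terms)
    ref = cv.transform(docs).toarray()
    np.testing.assert_array_equal(tdm.to_dense(), ref)


def test_tfidf_hand_example():
    """count 2 in a 4-token row with df=1 of N=2 gives (2/4)*log2(2)=0.5."""
    vocab = Vocabulary(terms=["rare", "common"], document_frequency=[1, 2],
                       n_documents=2)
    counts = build_count_matrix(
        [["rare", "rare", "common", "common"], ["common"]], vocab,
        spec=VocabularySpec(ngram_max=1))
    tfidf = apply_tfidf(counts, vocab)
    dense = tfidf.to_dense()
    assert dense[0, 0] == pytest.approx(0.5)
    assert dense[0, 1] == 0.0  # df = N: ubiquitous term annihilated
    assert dense[1, 1] == 0.0


def test_tfidf_zero_row_stays_zero():
    vocab = Vocabulary(terms=["x"], document_frequency=[1], n_documents=2)
    counts = build_count_matrix([["y"], ["x"]], vocab,
                                spec=VocabularySpec(ngram_max=1))
    assert apply_tfidf(counts, vocab).to_dense()[0, 0] == 0.0


def test_tfidf_requires_count_weighting():
    vocab = Vocabulary(terms=["x"], document_frequency=[1], n_documents=2)
    counts = build_count_matrix([["x"]], vocab,
                                spec=VocabularySpec(ngram_max=1))
    tfidf = apply_tfidf(counts, vocab)
    with pytest.raises(ValueError):
        apply_tfidf(tfidf, vocab)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_full_textprep_oracle_equivalence(seed):
    """Vocabulary, counts and TF-IDF match brute force on small corpora."""
    rng = np.random.default_rng(seed)
    docs = random_docs(rng, n_docs=int(rng.integers(2, 11)))
    spec = VocabularySpec(min_df_fraction=float(rng.uniform(0.05, 0.5)))
    vocab = build_vocabulary(docs, spec)
    assert vocab.terms == oracle_vocabulary(docs, spec)
    counts = build_count_matrix(docs, vocab, spec=spec)
    ref_counts = oracle_counts(docs, vocab.terms, spec)
    np.testing.assert_array_equal(counts.to_dense(), ref_counts)
    tfidf = apply_tfidf(counts, vocab)
    ref_tfidf = oracle_tfidf(ref_counts, vocab.document_frequency,
                             vocab.n_documents)
    np.testing.assert_allclose(tfidf.to_dense(), ref_tfidf, rtol=0,
                               atol=1e-15)


def test_sparsity_preserved():
    rng = np.random.default_rng(7)
    docs = random_docs(rng)
    spec = VocabularySpec(min_df_fraction=0.1)
    vocab = build_vocabulary(docs, spec)
    counts = build_count_matrix(docs, vocab, spec=spec)
    tfidf = apply_tfidf(counts, vocab)
    zero_count = counts.to_dense() == 0
    assert np.all(tfidf.to_dense()[zero_count] == 0)


def test_matrix_and_vocab_serialization(tmp_path, toy_corpus):
    import scipy.io
    tdm, vocab = fit_tdm(toy_corpus, VocabularySpec(min_df_fraction=0.3))
    tdm.save(tmp_path / "tdm")
    back = scipy.io.mmread(tmp_path / "tdm.mtx")
    np.testing.assert_allclose(np.asarray(back.todense()), tdm.to_dense())
    rows = (tmp_path / "tdm.rows.txt").read_text().split()
    assert rows == tdm.child_ids
    vocab.to_tsv(tmp_path / "vocab.tsv")
    back_v = Vocabulary.from_tsv(tmp_path / "vocab.tsv")
    assert back_v.terms == vocab.terms
    assert back_v.n_documents == vocab.n_documents
    np.testing.assert_array_equal(back_v.document_frequency,
                                  vocab.document_frequency)


def test_transform_consistency(toy_corpus):
    """Fit-then-transform equals transforming with the frozen vocabulary."""
    spec = VocabularySpec(min_df_fraction=0.3)
    fitted, vocab = fit_tdm(toy_corpus, spec)
    frozen = transform_tdm(toy_corpus, vocab, spec)
    assert frozen.child_ids == fitted.child_ids
    assert (frozen.weights != fitted.weights).nnz == 0
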