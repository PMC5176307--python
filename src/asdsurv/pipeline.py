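"""End-to-end classifier: fit on a labeled training year, score new years.

The centrepiece is the statsmodels-style pair
:class:`SurveillanceTextModel` (built from a labeled corpus) and
:class:`SurveillanceTextResults` (returned by ``fit()``), which carries the
frozen vocabulary, the selected terms with their importance scores, the
calibrated vote cutoff, OOB diagnostics, and ``summary()`` /
``predict()`` / ``save()``.

Fitting composes: aggregate evaluations -> tokenize/stem -> 1-3-gram
vocabulary with 3% document-frequency floor -> TF-IDF -> importance-ranking
forest -> OOB permutation importance -> nested-subset term selection ->
final forest refit on the selected terms -> vote cutoff calibrated to the
training class balance.  Scoring a new corpus reuses the frozen training
vocabulary, document frequencies and N; children whose documents contain
no in-vocabulary term are still scored (on an all-zero row) and logged.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import sklearn

from . import __version__
from .corpus import Corpus, require_labeled
from .forest import (CASE, ForestConfig, ImportanceRanking, SelectionTrace,
                     compute_cutoff, oob_accuracy, permutation_importance,
                     select_features, train_forest, _tree_votes)
from .metrics import PerformanceSummary, confusion, roc_auc, summarize
from .textprep import (TermDocumentMatrix, Vocabulary, VocabularySpec,
                       fit_tdm, restrict_terms, transform_tdm)

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    """Per-child classification scores (fraction of trees voting case)."""

    child_ids: list[str]
    scores: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    def predicted_statuses(self, cutoff: float | None = None
                           ) -> dict[str, str]:
        """Status per child: case iff score >= cutoff (ties count as case)."""
        cut = self.cutoff if cutoff is None else cutoff
        return {cid: ("case" if s >= cut else "noncase")
                for cid, s in zip(self.child_ids, self.scores)}

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.child_ids, self.scores))

    def to_dataframe(self):
        import pandas as pd
        pred = self.predicted_statuses()
        return pd.DataFrame({
            "child_id": self.child_ids,
            "score": self.scores,
            "predicted_status": [pred[c] for c in self.child_ids],
        })


@dataclass
class TrainedClassifier:
    """Frozen scoring pipeline: vocabulary + IDF + terms + forest + cutoff."""

    vocabulary_spec: VocabularySpec
    frozen_vocabulary: Vocabulary
    selected_terms: list[str]          # importance (rank) order
    forest: object                     # fitted final ensemble
    cutoff: float
    config: ForestConfig
    importance: ImportanceRanking | None = None
    selection_trace: SelectionTrace | None = None
    training_summary: PerformanceSummary | None = None

    def __post_init__(self):
        missing = [t for t in self.selected_terms
                   if t not in self.frozen_vocabulary]
        if missing:
            raise ValueError(
                f"selected terms not in vocabulary: {missing[:5]}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly between 0 and 1")

    @property
    def model_terms(self) -> list[str]:
        """Selected terms in the canonical (lexicographic) column order."""
        return sorted(self.selected_terms)

    def vectorize(self, corpus: Corpus) -> TermDocumentMatrix:
        """Frozen transform: training vocabulary/df/N, selected columns."""
        full = transform_tdm(corpus, self.frozen_vocabulary,
                             self.vocabulary_spec)
        return restrict_terms(full, self.model_terms)


def vote_scores(forest, X) -> np.ndarray:
    """Fraction of trees voting case for each row of X."""
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    votes = np.zeros(X32.shape[0])
    for tree in forest.estimators_:
        votes += forest.classes_[_tree_votes(tree, X32)] == CASE
    return votes / len(forest.estimators_)


def fit_pipeline(train_corpus: Corpus,
                 spec: VocabularySpec | None = None,
                 config: ForestConfig | None = None
                 ) -> tuple[TrainedClassifier, ScoreSet]:
    """Train the full pipeline on a labeled corpus.

    Returns the frozen classifier and the training-corpus OOB score set
    (the honest, internally cross-validated scores used for the training
    row of the performance table).
    """
    spec = spec or VocabularySpec()
    config = config or ForestConfig()
    require_labeled(train_corpus)

    tdm, vocab = fit_tdm(train_corpus, spec)
    y = np.array([c.status for c in train_corpus.children])
    X = tdm.to_dense()
    logger.info("vocabulary: %d terms over %d children",
                len(vocab), tdm.shape[0])

    sel_forest, _ = train_forest(X, y, config.n_trees_selection,
                                 config.stage_seed("selection"),
                                 **config.forest_kwargs)
    ranking = permutation_importance(sel_forest, X, y, vocab.terms,
                                     seed=config.stage_seed("importance"))
    selected, trace = select_features(ranking, X, y, config)
    logger.info("selected %d of %d candidate terms",
                len(selected), min(config.k_candidates, len(vocab)))

    model_terms = sorted(selected)
    reduced = restrict_terms(tdm, model_terms)
    final_forest, oob = train_forest(reduced.to_dense(), y,
                                     config.n_trees_final,
                                     config.stage_seed("final"),
                                     **config.forest_kwargs)
    cutoff = compute_cutoff(train_corpus.n_case, train_corpus.n_children)
    logger.info("vote cutoff calibrated to %.3f (%d/%d non-cases)",
                cutoff, train_corpus.n_children - train_corpus.n_case,
                train_corpus.n_children)

    oob_scores = ScoreSet(child_ids=list(tdm.child_ids), scores=oob,
                          cutoff=cutoff)
    truth = train_corpus.statuses()
    training_summary = summarize(confusion(oob_scores, truth))
    training_summary.auc = roc_auc(
        oob, [truth[c] for c in oob_scores.child_ids])

    clf = TrainedClassifier(
        vocabulary_spec=spec, frozen_vocabulary=vocab,
        selected_terms=list(selected), forest=final_forest, cutoff=cutoff,
        config=config, importance=ranking, selection_trace=trace,
        training_summary=training_summary,
    )
    return clf, oob_scores


def predict_scores(classifier: TrainedClassifier, corpus: Corpus
                   ) -> ScoreSet:
    """Score a corpus with the frozen pipeline (labels not required)."""
    tdm = classifier.vectorize(corpus)
    X = tdm.to_dense()
    empty = np.asarray(tdm.weights.sum(axis=1)).ravel() == 0
    if empty.any():
        ids = [tdm.child_ids[i] for i in np.flatnonzero(empty)[:10]]
        logger.warning(
            "%d children have no in-vocabulary model terms (e.g. %s); "
            "they are scored on empty documents", int(empty.sum()), ids)
    scores = vote_scores(classifier.forest, X)
    return ScoreSet(child_ids=list(tdm.child_ids), scores=scores,
                    cutoff=classifier.cutoff)


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface
# ---------------------------------------------------------------------------

class SurveillanceTextModel:
    """Text-classification model for a labeled surveillance corpus.

    Parameters
    ----------
    corpus
        Training corpus; every child must carry a clinician status.
    vocabulary_spec
        N-gram range, document-frequency floor and stemmer (defaults:
        1-3-grams, 3%, Porter).
    forest_config
        Forest sizes, selection parameters and the master seed.
    """

    def __init__(self, corpus: Corpus,
                 vocabulary_spec: VocabularySpec | None = None,
                 forest_config: ForestConfig | None = None):
        require_labeled(corpus)
        self.corpus = corpus
        self.vocabulary_spec = vocabulary_spec or VocabularySpec()
        self.forest_config = forest_config or ForestConfig()

    @classmethod
    def from_jsonl(cls, path, **kwargs) -> "SurveillanceTextModel":
        from .corpus import read_corpus
        return cls(read_corpus(path), **kwargs)

    def fit(self) -> "SurveillanceTextResults":
        clf, oob_scores = fit_pipeline(self.corpus, self.vocabulary_spec,
                                       self.forest_config)
        return SurveillanceTextResults(self, clf, oob_scores)


class SurveillanceTextResults:
    """Fitted pipeline with diagnostics, prediction and persistence."""

    def __init__(self, model: SurveillanceTextModel | None,
                 classifier: TrainedClassifier, oob_scores: ScoreSet):
        self.model = model
        self.classifier = classifier
        self.oob_scores = oob_scores

    # -- estimates -----------------------------------------------------
    @property
    def cutoff(self) -> float:
        return self.classifier.cutoff

    @property
    def selected_terms(self) -> list[str]:
        return list(self.classifier.selected_terms)

    @property
    def vocabulary(self) -> Vocabulary:
        return self.classifier.frozen_vocabulary

    @property
    def training_summary(self) -> PerformanceSummary:
        return self.classifier.training_summary

    def importance_table(self):
        import pandas as pd
        r = self.classifier.importance
        if r is None:
            raise ValueError("importance ranking not available")
        return pd.DataFrame({
            "term": r.ranked_terms,
            "mean_decrease_accuracy": r.scores[r.order],
            "rank": np.arange(1, len(r.terms) + 1),
        })

    # -- application ---------------------------------------------------
    def predict(self, corpus: Corpus) -> ScoreSet:
        return predict_scores(self.classifier, corpus)

    def evaluate(self, corpus: Corpus) -> PerformanceSummary:
        """Score a labeled corpus and summarize concordance (with AUC)."""
        require_labeled(corpus, context="evaluation")
        scores = self.predict(corpus)
        truth = corpus.statuses()
        summary = summarize(confusion(scores, truth))
        summary.auc = roc_auc(scores.scores,
                              [truth[c] for c in scores.child_ids])
        return summary

    def plot_score_histogram(self, scores: ScoreSet | None = None,
                             truth: Mapping[str, str] | None = None,
                             ax=None):
        from .plotting import plot_score_histogram
        if scores is None:
            scores = self.oob_scores
            truth = self.model.corpus.statuses()
        return plot_score_histogram(scores, truth, ax=ax)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        clf = self.classifier
        s = self.training_summary
        lines = [
            "Surveillance text classification results",
            "=" * 44,
            f"children (training)        {len(self.oob_scores.child_ids)}",
            f"vocabulary terms           {len(clf.frozen_vocabulary)}",
            f"selected terms             {len(clf.selected_terms)}",
            f"vote cutoff                {clf.cutoff:.3f}",
            f"trees (selection/final)    {clf.config.n_trees_selection}/"
            f"{clf.config.n_trees_final}",
            "-" * 44,
            "training (out-of-bag) performance",
        ]
        r = s.rounded()
        for key, label in [("agreement", "agreement %"),
                           ("sensitivity", "sensitivity %"),
                           ("specificity", "specificity %"),
                           ("ppv", "PPV %"), ("npv", "NPV %"),
                           ("kappa", "kappa"), ("auc", "AUC")]:
            if key in r:
                lines.append(f"  {label:<24} {r[key]}")
        lines.append("-" * 44)
        lines.append("top terms: " + ", ".join(clf.selected_terms[:8]))
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, out_dir) -> None:
        save_classifier(self.classifier, out_dir,
                        oob_scores=self.oob_scores)

    @classmethod
    def load(cls, out_dir) -> "SurveillanceTextResults":
        clf, oob = load_classifier(out_dir)
        return cls(None, clf, oob)


def save_classifier(clf: TrainedClassifier, out_dir,
                    oob_scores: ScoreSet | None = None) -> None:
    """Persist a model artifact directory (vocab TSV, terms TSV, forest,
    JSON manifest with config, cutoff, seeds and versions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clf.frozen_vocabulary.to_tsv(out / "vocabulary.tsv")
    with (out / "selected_terms.tsv").open("w", encoding="utf-8") as fh:
        fh.write("rank\tterm\n")
        for i, t in enumerate(clf.selected_terms, start=1):
            fh.write(f"{i}\t{t}\n")
    joblib.dump(clf.forest, out / "forest.joblib")
    manifest = {
        "package_version": __version__,
        "sklearn_version": sklearn.__version__,
        "python_version": platform.python_version(),
        "vocabulary_spec": clf.vocabulary_spec.model_dump(),
        "forest_config": {
            "n_trees_selection": clf.config.n_trees_selection,
            "n_trees_final": clf.config.n_trees_final,
            "seed": clf.config.seed,
            "k_candidates": clf.config.k_candidates,
            "k_step": clf.config.k_step,
            "selection_tolerance": clf.config.selection_tolerance,
            "forest_kwargs": clf.config.forest_kwargs,
        },
        "forest_params": clf.forest.get_params(),
        "cutoff": clf.cutoff,
        "n_selected_terms": len(clf.selected_terms),
        "training_summary": (clf.training_summary.to_dict()
                             if clf.training_summary else None),
        "selection_trace": ({"ks": clf.selection_trace.ks,
                             "oob_accuracies":
                                 clf.selection_trace.oob_accuracies,
                             "chosen_k": clf.selection_trace.chosen_k}
                            if clf.selection_trace else None),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    if oob_scores is not None:
        oob_scores.to_dataframe().to_csv(out / "oob_scores.csv", index=False)


def load_classifier(out_dir) -> tuple[TrainedClassifier, ScoreSet | None]:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text("utf-8"))
    vocab = Vocabulary.from_tsv(out / "vocabulary.tsv")
    terms = []
    for row in (out / "selected_terms.tsv").read_text("utf-8") \
            .splitlines()[1:]:
        _, term = row.split("\t")
        terms.append(term)
    forest = joblib.load(out / "forest.joblib")
    fc = manifest["forest_config"]
    clf = TrainedClassifier(
        vocabulary_spec=VocabularySpec(**manifest["vocabulary_spec"]),
        frozen_vocabulary=vocab, selected_terms=terms, forest=forest,
        cutoff=manifest["cutoff"],
        config=ForestConfig(
            n_trees_selection=fc["n_trees_selection"],
            n_trees_final=fc["n_trees_final"], seed=fc["seed"],
            k_candidates=fc["k_candidates"], k_step=fc["k_step"],
            selection_tolerance=fc["selection_tolerance"],
            forest_kwargs=fc.get("forest_kwargs") or {}),
        training_summary=(
            PerformanceSummary(**{k: v for k, v in
                                  manifest["training_summary"].items()})
            if manifest.get("training_summary") else None),
    )
    oob = None
    oob_path = out / "oob_scores.csv"
    if oob_path.exists():
        import pandas as pd
        df = pd.read_csv(oob_path, dtype={"child_id": str})
        oob = ScoreSet(child_ids=list(df["child_id"]),
                       scores=df["score"].to_numpy(), cutoff=clf.cutoff)
    return clf, oob
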