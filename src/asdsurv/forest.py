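"""Random-forest training with Breiman-style out-of-bag machinery.

The classifier follows the original surveillance design: a large forest
over the full vocabulary ranks terms by permutation importance (mean
decrease in OOB classification accuracy), a nested-subset search picks a
parsimonious term set, and a smaller forest refit on those terms does the
actual classification, with the vote-share cutoff calibrated to the
training class balance instead of the default 0.5.

scikit-learn's forest exposes neither per-tree OOB vote fractions nor
per-tree OOB permutation importance, so both are computed here by
reconstructing each tree's bootstrap sample (the same
``RandomState(tree.random_state).randint(0, n, n)`` draw the library
makes) and traversing the fitted trees directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

#: integer class codes used throughout: 0 = noncase, 1 = case
NONCASE, CASE = 0, 1


@dataclass
class ForestConfig:
    """Forest sizes and the master seed.

    Defaults follow the surveillance method: 10,000 trees for the
    importance-ranking forest, 3,000 for the reduced-term refits; every
    other hyperparameter is the library's classification default.
    """

    n_trees_selection: int = 10_000
    n_trees_final: int = 3_000
    seed: int = 0
    k_candidates: int = 175
    k_step: int = 5
    selection_tolerance: float = 0.005
    forest_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_trees_selection < 1 or self.n_trees_final < 1:
            raise ValueError("tree counts must be >= 1")

    def stage_seed(self, stage: str) -> int:
        """Fan the master seed out to a reproducible per-stage seed."""
        return int(
            np.random.SeedSequence([self.seed, _STAGE_CODES[stage]])
            .generate_state(1)[0] % (2**31 - 1)
        )


_STAGE_CODES = {"selection": 1, "subset": 2, "final": 3, "importance": 4}


def compute_cutoff(n_case: int, n_total: int) -> float:
    """Vote-share cutoff calibrated to the training class balance.

    Returns the non-case class fraction (n_total - n_case) / n_total, e.g.
    561/1162 = 0.483 for a 601-case cohort of 1162, replacing the default
    majority rule of 0.5.
    """
    if not 0 < n_case < n_total:
        raise ValueError(
            f"training data must contain both classes; got {n_case} cases "
            f"of {n_total}"
        )
    return (n_total - n_case) / n_total


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "US O":
        y = np.where(y == "case", CASE, np.where(y == "noncase", NONCASE, -1))
        if np.any(y == -1):
            raise ValueError("labels must be 'case' or 'noncase'")
    y = y.astype(np.int64)
    if set(np.unique(y)) != {NONCASE, CASE}:
        raise ValueError("labels must contain both classes")
    return y


def _bootstrap_in_bag(tree_seed: int, n: int) -> np.ndarray:
    """Boolean in-bag mask for one tree, replicating the library's draw."""
    idx = np.random.RandomState(tree_seed).randint(0, n, n)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def _tree_votes(tree, X32: np.ndarray) -> np.ndarray:
    """Predicted class codes of one fitted tree, no validation overhead."""
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:
        proba = proba[:, 0, :]
    return np.argmax(proba, axis=1)


def train_forest(X, y, n_trees: int, seed: int, **forest_kwargs
                 ) -> tuple[RandomForestClassifier, np.ndarray]:
    """Fit a forest and return it with per-row OOB case-vote fractions.

    The OOB score of row i is the fraction of trees for which i was
    out-of-bag that vote "case".  Rows never out-of-bag (vanishingly rare
    for forests of hundreds of trees) receive score 0.5 and a warning.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = _check_labels(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("rows of X must align with labels")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, bootstrap=True,
        **forest_kwargs,
    )
    forest.fit(X, y)
    oob = oob_case_scores(forest, X)
    return forest, oob


def oob_case_scores(forest: RandomForestClassifier, X32: np.ndarray
                    ) -> np.ndarray:
    n = X32.shape[0]
    case_col = int(np.where(forest.classes_ == CASE)[0][0])
    votes = np.zeros(n)
    counts = np.zeros(n)
    for tree in forest.estimators_:
        oob_mask = ~_bootstrap_in_bag(tree.random_state, n)
        if not oob_mask.any():
            continue
        pred = _tree_votes(tree, X32[oob_mask])
        votes[oob_mask] += (forest.classes_[pred] == CASE)
        counts[oob_mask] += 1
    never = counts == 0
    if never.any():
        logger.warning("%d rows were never out-of-bag; scored 0.5",
                       int(never.sum()))
    scores = np.full(n, 0.5)
    np.divide(votes, counts, out=scores, where=~never)
    return scores


def oob_accuracy(oob_scores: np.ndarray, y, cutoff: float = 0.5) -> float:
    """Accuracy of the OOB majority (or cutoff) vote against the labels."""
    y = _check_labels(y)
    pred = (oob_scores >= cutoff).astype(np.int64)
    return float(np.mean(pred == y))


@dataclass
class ImportanceRanking:
    """Permutation importance scores with a deterministic rank order."""

    terms: list[str]
    scores: np.ndarray  # mean decrease in OOB accuracy, aligned with terms
    order: np.ndarray   # indices into terms, descending score

    @property
    def ranked_terms(self) -> list[str]:
        return [self.terms[i] for i in self.order]

    def top(self, k: int) -> list[str]:
        return self.ranked_terms[:k]


def permutation_importance(forest: RandomForestClassifier, X, y,
                           terms: list[str], seed: int = 0
                           ) -> ImportanceRanking:
    """Breiman OOB permutation importance: mean decrease in accuracy.

    For each tree, the accuracy on its out-of-bag rows is compared with the
    accuracy after shuffling one term's column within those rows; the
    importance of the term is the mean drop over all trees.  Only terms a
    tree actually splits on can change its predictions, so other terms are
    skipped for that tree (their contribution is exactly zero).  Ties in
    the ranking are broken lexicographically by term.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = _check_labels(y)
    n, p = X.shape
    if p != len(terms):
        raise ValueError("terms must align with matrix columns")
    rng = np.random.RandomState(seed)
    totals = np.zeros(p)
    class_codes = forest.classes_
    for tree in forest.estimators_:
        oob_mask = ~_bootstrap_in_bag(tree.random_state, n)
        m = int(oob_mask.sum())
        if m == 0:
            continue
        X_oob = np.ascontiguousarray(X[oob_mask])
        y_oob = y[oob_mask]
        base_correct = np.sum(
            class_codes[_tree_votes(tree, X_oob)] == y_oob)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(m)
        for j in used:
            saved = X_oob[:, j].copy()
            X_oob[:, j] = saved[perm]
            perm_correct = np.sum(
                class_codes[_tree_votes(tree, X_oob)] == y_oob)
            X_oob[:, j] = saved
            totals[j] += (base_correct - perm_correct) / m
    scores = totals / len(forest.estimators_)
    # descending score, lexicographic tie-break on the term string
    order = np.array(
        sorted(range(p), key=lambda j: (-scores[j], terms[j])),
        dtype=np.int64,
    )
    return ImportanceRanking(terms=list(terms), scores=scores, order=order)


@dataclass
class SelectionTrace:
    """k-vs-OOB-accuracy trace from the nested-subset search."""

    ks: list[int]
    oob_accuracies: list[float]
    chosen_k: int


def select_features(ranking: ImportanceRanking, X, y,
                    config: ForestConfig) -> tuple[list[str], SelectionTrace]:
    """Pick a parsimonious term subset from the importance ranking.

    Nested top-k subsets (k = k_step, 2*k_step, ..., k_candidates) are each
    scored by the OOB accuracy of a forest refit on those columns alone;
    the smallest k whose accuracy is within ``selection_tolerance`` of the
    best observed wins.  Returns the chosen terms (in ranking order) and
    the full trace.
    """
    if len(ranking.terms) == 0:
        raise ValueError("empty importance ranking")
    k_max = min(config.k_candidates, len(ranking.terms))
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = _check_labels(y)
    term_index = {t: j for j, t in enumerate(ranking.terms)}
    ks = list(range(config.k_step, k_max + 1, config.k_step))
    if not ks or ks[-1] != k_max:
        ks.append(k_max)
    accs = []
    seed = ForestConfig(seed=config.seed).stage_seed("subset")
    for k in ks:
        cols = [term_index[t] for t in ranking.top(k)]
        _, oob = train_forest(X[:, cols], y, config.n_trees_final, seed,
                              **config.forest_kwargs)
        accs.append(oob_accuracy(oob, y))
    best = max(accs)
    chosen_k = next(k for k, a in zip(ks, accs)
                    if a >= best - config.selection_tolerance)
    logger.info("feature selection: chose k=%d (best OOB acc %.4f)",
                chosen_k, best)
    return ranking.top(chosen_k), SelectionTrace(ks=ks, oob_accuracies=accs,
                                                 chosen_k=chosen_k)
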