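"""Surveillance evaluation layer.

Concordance of algorithm vs clinician classification (2x2 counts),
agreement / sensitivity / specificity / PPV / NPV, Cohen's kappa,
rank-based ROC AUC, cutoff sweeps, prevalence per 1,000 with Poisson
log-normal confidence intervals, and Table-style concordance profiling of
the four prediction x truth cells.

All summary metrics are computed in exact rational arithmetic from the
confusion counts and only rounded for display; machine-readable output
always carries the unrounded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .corpus import Corpus

_CELLS = ("TP", "FP", "FN", "TN")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 concordance table: truth = clinician status, rows = algorithm."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValueError("confusion table must contain at least one child")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass
class PerformanceSummary:
    """Agreement metrics on the percentage scale, kappa and optional AUC.

    Undefined metrics (zero denominator) are NaN and listed in
    ``undefined`` rather than fabricated.
    """

    agreement: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def rounded(self) -> dict:
        """Display-precision values: percentages to 1 dp, kappa/AUC to 2-3."""
        out = {
            k: (round(getattr(self, k), 1)
                if not math.isnan(getattr(self, k)) else float("nan"))
            for k in ("agreement", "sensitivity", "specificity", "ppv", "npv")
        }
        out["kappa"] = round(self.kappa, 2)
        if self.auc is not None:
            out["auc"] = round(self.auc, 3)
        return out

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("agreement", "sensitivity", "specificity", "ppv", "npv",
              "kappa", "auc")}
        d["undefined"] = list(self.undefined)
        return d


def _statuses_of(scores_or_statuses) -> Mapping[str, str]:
    if hasattr(scores_or_statuses, "predicted_statuses"):
        return scores_or_statuses.predicted_statuses()
    return dict(scores_or_statuses)


def confusion(scores_or_statuses, truth: Mapping[str, str]) -> ConfusionCounts:
    """Cross-tabulate predicted status against clinician status."""
    pred = _statuses_of(scores_or_statuses)
    if set(pred) != set(truth):
        missing = set(pred) ^ set(truth)
        raise ValueError(
            f"prediction and truth child_id sets differ ({len(missing)} "
            f"mismatched ids, e.g. {sorted(missing)[:5]})")
    tp = fp = fn = tn = 0
    for cid, t in truth.items():
        if t not in ("case", "noncase"):
            raise ValueError(f"truth status for {cid!r} is {t!r}; "
                             "labels must be case/noncase")
        p = pred[cid]
        if p == "case":
            tp += t == "case"
            fp += t == "noncase"
        else:
            fn += t == "case"
            tn += t == "noncase"
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def summarize(counts: ConfusionCounts) -> PerformanceSummary:
    """Agreement, sensitivity, specificity, PPV, NPV (percent) and kappa."""
    tp, fp, fn, tn = counts.as_tuple()
    n = counts.n
    undefined: list[str] = []

    def pct(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return float(Fraction(100 * num, den))

    agreement = pct(tp + tn, n, "agreement")
    sensitivity = pct(tp, tp + fn, "sensitivity")
    specificity = pct(tn, tn + fp, "specificity")
    ppv = pct(tp, tp + fp, "ppv")
    npv = pct(tn, tn + fn, "npv")

    p_o = Fraction(tp + tn, n)
    p_e = (Fraction(tp + fp, n) * Fraction(tp + fn, n)
           + Fraction(fn + tn, n) * Fraction(fp + tn, n))
    if p_e == 1:
        kappa = 1.0 if p_o == 1 else float("nan")
        if p_o != 1:
            undefined.append("kappa")
    else:
        kappa = float((p_o - p_e) / (1 - p_e))
    return PerformanceSummary(agreement=agreement, sensitivity=sensitivity,
                              specificity=specificity, ppv=ppv, npv=npv,
                              kappa=kappa, undefined=undefined)


def roc_auc(scores: Sequence[float], truth: Sequence[str] | np.ndarray
            ) -> float:
    """Probability a random case outscores a random non-case, ties at 1/2.

    The Mann-Whitney rank formulation, identical to the trapezoidal area
    under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([t == "case" if isinstance(t, str) else bool(t)
                    for t in truth])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in the truth labels")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cutoff_sweep(scores: Mapping[str, float] | Sequence[float],
                 truth: Mapping[str, str] | Sequence[str],
                 grid: Sequence[float]) -> pd.DataFrame:
    """Re-summarize the classification at each cutoff in the grid.

    Returns one row per cutoff with the full metric set; a child is
    predicted "case" iff score >= cutoff, so sensitivity is non-increasing
    and the sweep reproduces the cutoff-exploration curves.
    """
    if len(grid) == 0:
        raise ValueError("cutoff grid must be non-empty")
    if not all(0.0 <= g <= 1.0 for g in grid):
        raise ValueError("cutoffs must lie in [0, 1]")
    if isinstance(scores, Mapping):
        ids = sorted(scores)
        s = np.array([scores[i] for i in ids])
        t = [truth[i] for i in ids]
    else:
        s = np.asarray(scores, dtype=np.float64)
        t = list(truth)
    rows = []
    for cut in grid:
        pred = {i: ("case" if si >= cut else "noncase")
                for i, si in enumerate(s)}
        summary = summarize(confusion(pred, dict(enumerate(t))))
        rows.append({"cutoff": cut, **summary.to_dict()})
    return pd.DataFrame(rows).drop(columns=["undefined", "auc"])


@dataclass
class PrevalenceEstimate:
    """Predicted-case prevalence per 1,000 with a Poisson log-normal CI."""

    predicted_cases: int
    population_denominator: int
    per_1000: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    def __str__(self) -> str:
        return (f"{self.per_1000:.1f} per 1,000 "
                f"({self.ci_low:.1f}-{self.ci_high:.1f})")


def prevalence(predicted_cases: int, denominator: int) -> PrevalenceEstimate:
    """Prevalence per 1,000 children from algorithm-predicted case counts.

    The 95% CI is the conventional surveillance interval for a Poisson
    count: rate x exp(+-1.96 / sqrt(cases)).  A zero count yields a
    degenerate (flagged) interval.
    """
    if denominator <= 0:
        raise ValueError("population denominator must be positive")
    if not 0 <= predicted_cases <= denominator:
        raise ValueError("predicted cases must lie in [0, denominator]")
    rate = predicted_cases / denominator * 1000.0
    if predicted_cases == 0:
        return PrevalenceEstimate(predicted_cases, denominator, 0.0,
                                  0.0, 0.0, degenerate=True)
    half = 1.96 / math.sqrt(predicted_cases)
    return PrevalenceEstimate(
        predicted_cases=predicted_cases,
        population_denominator=denominator,
        per_1000=rate,
        ci_low=rate * math.exp(-half),
        ci_high=rate * math.exp(half),
    )


def prevalence_ratio(algorithm_est: PrevalenceEstimate,
                     published_per_1000: float) -> float:
    """Algorithm : published prevalence ratio, to 2 decimals."""
    if published_per_1000 <= 0:
        raise ValueError("published prevalence must be positive")
    return round(algorithm_est.per_1000 / published_per_1000, 2)


def _wilson(k: int, n: int) -> tuple[float, float, float]:
    if n == 0:
        return float("nan"), float("nan"), float("nan")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return 100.0 * k / n, 100.0 * lo, 100.0 * hi


def concordance_profile(corpus: Corpus, scores) -> pd.DataFrame:
    """Characteristics of children by algorithm x clinician concordance cell.

    One row per cell (TP, FP, FN, TN): n; percentage (with Wilson 95% CI)
    of demographic / prior-diagnosis / source attributes; median and IQR of
    the evaluation count and of age at first evaluation.
    """
    pred = _statuses_of(scores)
    rows = {cell: [] for cell in _CELLS}
    for child in corpus.children:
        t, p = child.status, pred[child.child_id]
        if t == "unknown":
            raise ValueError(
                f"child {child.child_id!r} has unknown clinician status")
        cell = ("TP" if t == "case" else "FP") if p == "case" \
            else ("FN" if t == "case" else "TN")
        rows[cell].append(child)

    binary_attrs = {
        "white_nh": lambda c: c.race_eth == "white_nh",
        "male": lambda c: c.sex == "male",
        "iq_le_70": lambda c: c.iq_le_70 is True,
        "prior_asd_dx": lambda c: c.prior_asd_dx,
        "prior_asd_sped": lambda c: c.prior_asd_sped,
        "any_prior_asd": lambda c: c.prior_asd_dx or c.prior_asd_sped,
        "school_only": lambda c: c.sources == {"school"},
        "health_only": lambda c: c.sources == {"health"},
        "both_sources": lambda c: c.sources == {"school", "health"},
        "secondary_review": lambda c: c.secondary_review is True,
    }
    records = []
    for cell in _CELLS:
        kids = rows[cell]
        rec: dict = {"cell": cell, "n": len(kids)}
        for name, fn in binary_attrs.items():
            k = sum(bool(fn(c)) for c in kids)
            pct, lo, hi = _wilson(k, len(kids))
            rec[f"pct_{name}"] = pct
            rec[f"pct_{name}_ci_low"] = lo
            rec[f"pct_{name}_ci_high"] = hi
        for label, values in (
                ("evals", [c.n_evaluations for c in kids]),
                ("age_first", [c.age_first_eval for c in kids])):
            if kids:
                q1, med, q3 = np.percentile(values, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            rec[f"{label}_median"] = float(med)
            rec[f"{label}_q1"] = float(q1)
            rec[f"{label}_q3"] = float(q3)
        records.append(rec)
    return pd.DataFrame(records).set_index("cell")


def score_histogram(scores, truth: Mapping[str, str],
                    bins: int = 20) -> pd.DataFrame:
    """Histogram of prediction scores by clinician class (figure-ready CSV)."""
    if hasattr(scores, "scores"):
        ids = scores.child_ids
        s = dict(zip(ids, scores.scores))
    else:
        s = dict(scores)
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for cls in ("case", "noncase"):
        vals = [s[cid] for cid, t in truth.items() if t == cls]
        out[f"n_{cls}"], _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(out)
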