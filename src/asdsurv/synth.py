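"""Seeded synthetic surveillance corpora with known ground truth.

Real surveillance records are confidential, so every corpus this package
is tested on is simulated.  The generator emulates the statistical
structure the classification method relies on, not clinical prose:

* a roughly balanced case mix (default 601/1162 ~ 52% cases);
* more, and earlier, evaluations for cases than non-cases (evaluation
  counts negative-binomial per class targeting medians of 7 vs 4; age at
  first evaluation log-normal targeting medians of 40 vs 53 months);
* a per-class mix of school-only / health-only / both evaluation sources;
* token streams drawn from a Zipf-profiled noise vocabulary shared by both
  classes, plus a small set of planted discriminative terms whose usage
  odds differ between classes by a configurable log-odds effect;
* a child-level random effect on the planted-term propensities, standing
  in for the within-child correlation of real evaluation texts.

Planted terms may be multi-word phrases; they are emitted as contiguous
token runs so the n-gram extractor can rediscover them.  All tokens are
constructed to be stem-stable (Porter leaves them unchanged), which keeps
the planted-term strings identical to the post-stemming vocabulary terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .corpus import ChildRecord, Corpus, EvaluationRecord
from .stem import porter_stem

_CONSONANTS = "bdfgjkmnpqvwxz"
_VOWELS = "aeiou"


def _token_pool(n: int) -> list[str]:
    """First n stem-stable, letters-only synthetic word forms."""
    pool = []
    for c1, v1, c2, v2, c3 in itertools.product(
            _CONSONANTS, _VOWELS, _CONSONANTS, _VOWELS, _CONSONANTS):
        tok = c1 + v1 + c2 + v2 + c3
        if porter_stem(tok) == tok:
            pool.append(tok)
            if len(pool) == n:
                return pool
    raise ValueError(f"token pool exhausted before reaching {n}")


class ClassParams(BaseModel):
    """Per-class count/age/metadata parameters."""

    evals_mean: float
    evals_dispersion: float = 2.5
    age_first_median: float
    age_first_sigma: float = 0.45
    source_mix: tuple[float, float, float]  # school only, health only, both
    prior_dx_rate: float
    prior_sped_rate: float
    male_rate: float
    iq_le_70_rate: float
    secondary_review_rate: float
    race_probs: tuple[float, float, float, float] = (0.39, 0.34, 0.13, 0.14)


class SynthConfig(BaseModel):
    """Full parameterization of the synthetic corpus."""

    n_children: int = Field(default=1162, ge=2)
    case_fraction: float = Field(default=601 / 1162, ge=0.0, le=1.0)
    exact_n_case: int | None = None
    surveillance_year: int = 2008
    n_discriminative_terms: int = Field(default=10, ge=0)
    n_noise_terms: int = Field(default=6000, ge=10)
    effect_log_odds: float = Field(default=2.0, ge=0.0)
    disc_mass: float = Field(default=0.06, gt=0.0, lt=1.0)
    child_effect_sigma: float = Field(default=0.3, ge=0.0)
    zipf_exponent: float = 1.05
    tokens_per_eval_mean: float = 150.0
    tokens_per_eval_dispersion: float = 8.0
    labeled: bool = True
    seed: int = 0
    case_params: ClassParams = ClassParams(
        evals_mean=7.9, age_first_median=40.0,
        source_mix=(0.246, 0.138, 0.616),
        prior_dx_rate=0.75, prior_sped_rate=0.57, male_rate=0.825,
        iq_le_70_rate=0.32, secondary_review_rate=0.17,
    )
    noncase_params: ClassParams = ClassParams(
        evals_mean=4.6, age_first_median=53.0,
        source_mix=(0.417, 0.207, 0.376),
        prior_dx_rate=0.08, prior_sped_rate=0.03, male_rate=0.727,
        iq_le_70_rate=0.23, secondary_review_rate=0.35,
    )


def pooled_params() -> ClassParams:
    """Class-exchangeable metadata parameters for null-signal corpora.

    With zero planted effect the classes must be fully exchangeable for
    the corpus to carry no signal at all: the default per-class evaluation
    counts alone would otherwise make document length predictive.
    """
    return ClassParams(
        evals_mean=6.0, age_first_median=46.0,
        source_mix=(0.33, 0.17, 0.50),
        prior_dx_rate=0.4, prior_sped_rate=0.3, male_rate=0.78,
        iq_le_70_rate=0.28, secondary_review_rate=0.26,
    )


@dataclass
class SynthTruth:
    """Ground truth of a generated corpus: statuses and planted signal."""

    statuses: dict[str, str]
    planted_terms: list[str]
    effect_log_odds: list[float]


def _nbinom_counts(rng: np.random.Generator, mean: float, dispersion: float,
                   size: int, minimum: int) -> np.ndarray:
    """Shifted negative-binomial counts with the given pre-shift mean."""
    mu = max(mean - minimum, 1e-9)
    p = dispersion / (dispersion + mu)
    return minimum + rng.negative_binomial(dispersion, p, size=size)


def _draw_statuses(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    n = cfg.n_children
    if cfg.exact_n_case is not None:
        if not 0 <= cfg.exact_n_case <= n:
            raise ValueError("exact_n_case out of range")
        status = np.zeros(n, dtype=np.int64)
        status[: cfg.exact_n_case] = 1
        rng.shuffle(status)
        return status
    status = (rng.random(n) < cfg.case_fraction).astype(np.int64)
    if 0.0 < cfg.case_fraction < 1.0 and len(np.unique(status)) == 1:
        # both classes must be realized; flip one child
        status[rng.integers(n)] = 1 - status[0]
    return status


def generate_corpus(config: SynthConfig) -> tuple[Corpus, SynthTruth]:
    """Draw a fully reproducible corpus and its ground truth."""
    cfg = config
    if cfg.tokens_per_eval_mean <= 0:
        raise ValueError("tokens_per_eval_mean must be positive")
    rng = np.random.default_rng(cfg.seed)

    n_disc = cfg.n_discriminative_terms
    pool = _token_pool(cfg.n_noise_terms + 2 * n_disc)
    noise_tokens = pool[: cfg.n_noise_terms]
    # planted phrases cycle lengths 1, 2, 3 over the reserved tail tokens
    phrase_tokens: list[tuple[str, ...]] = []
    tail = iter(pool[cfg.n_noise_terms:])
    for d in range(n_disc):
        length = d % 3 + 1
        if length == 1:
            phrase_tokens.append((next(tail),))
        else:
            first = next(tail)
            phrase_tokens.append((first,) + tuple(
                noise_tokens[(7 * d + k) % 50] for k in range(length - 1)))
    planted_terms = [" ".join(t) for t in phrase_tokens]
    effects = [cfg.effect_log_odds] * n_disc

    zipf = np.arange(1, cfg.n_noise_terms + 1, dtype=np.float64) \
        ** (-cfg.zipf_exponent)
    zipf *= (1.0 - cfg.disc_mass) / zipf.sum()
    disc_base = cfg.disc_mass / max(n_disc, 1)

    statuses = _draw_statuses(rng, cfg)
    children = []
    for i in range(cfg.n_children):
        cid = f"ch{i:05d}"
        is_case = bool(statuses[i])
        params = cfg.case_params if is_case else cfg.noncase_params

        n_evals = int(_nbinom_counts(rng, params.evals_mean,
                                     params.evals_dispersion, 1, 1)[0])
        age_first = int(np.clip(round(
            np.exp(np.log(params.age_first_median)
                   + params.age_first_sigma * rng.standard_normal())), 2, 96))
        gaps = rng.gamma(1.5, 6.0, size=max(n_evals - 1, 0))
        ages = age_first + np.concatenate([[0], np.cumsum(gaps)])
        ages = np.clip(np.round(ages).astype(int), 2, 107)

        mix = rng.choice(3, p=params.source_mix)
        if mix == 0:
            sources = ["school"] * n_evals
        elif mix == 1:
            sources = ["health"] * n_evals
        else:
            sources = list(rng.choice(["school", "health"], size=n_evals))
            if n_evals >= 2 and len(set(sources)) == 1:
                sources[0] = "health" if sources[0] == "school" else "school"

        # per-child tilt on planted-term propensities (within-child
        # correlation of evaluation texts)
        if n_disc:
            mult = np.exp(cfg.child_effect_sigma
                          * rng.standard_normal(n_disc))
            shift = 0.5 if is_case else -0.5
            disc_w = disc_base * mult * np.exp(
                np.asarray(effects) * shift)
            probs = np.concatenate([zipf, disc_w])
            probs /= probs.sum()
        else:
            probs = zipf / zipf.sum()

        n_events = _nbinom_counts(rng, cfg.tokens_per_eval_mean,
                                  cfg.tokens_per_eval_dispersion,
                                  n_evals, 5)
        evaluations = []
        for e in range(n_evals):
            events = rng.choice(len(probs), size=int(n_events[e]), p=probs)
            toks: list[str] = []
            for ev_idx in events:
                if ev_idx < cfg.n_noise_terms:
                    toks.append(noise_tokens[ev_idx])
                else:
                    toks.extend(phrase_tokens[ev_idx - cfg.n_noise_terms])
            evaluations.append(EvaluationRecord(
                child_id=cid, source=sources[e],
                age_months=int(ages[e]), text=" ".join(toks)))

        iq_known = rng.random() < 0.85
        children.append(ChildRecord(
            child_id=cid,
            status=("case" if is_case else "noncase") if cfg.labeled
            else "unknown",
            evaluations=evaluations,
            sex="male" if rng.random() < params.male_rate else "female",
            race_eth=["white_nh", "black_nh", "hispanic", "other"][
                rng.choice(4, p=params.race_probs)],
            iq_le_70=bool(rng.random() < params.iq_le_70_rate)
            if iq_known else None,
            prior_asd_dx=bool(rng.random() < params.prior_dx_rate),
            prior_asd_sped=bool(rng.random() < params.prior_sped_rate),
            secondary_review=bool(
                rng.random() < params.secondary_review_rate),
        ))

    corpus = Corpus(surveillance_year=cfg.surveillance_year,
                    children=children)
    truth = SynthTruth(
        statuses={c.child_id: ("case" if statuses[i] else "noncase")
                  for i, c in enumerate(children)},
        planted_terms=planted_terms,
        effect_log_odds=effects,
    )
    return corpus, truth


def addm_like_pair(seed: int, **overrides
                   ) -> tuple[Corpus, Corpus, SynthTruth]:
    """A training/test corpus pair sized like the 2008/2010 cohorts.

    Both corpora share one generative configuration (same planted terms and
    effects); statuses are assigned by exact allocation: 601 cases of 1162
    children for the training year, 754 of 1450 for the test year.
    """
    base = dict(n_discriminative_terms=30, effect_log_odds=2.0)
    base.update(overrides)
    train_cfg = SynthConfig(n_children=1162, exact_n_case=601,
                            surveillance_year=2008, seed=seed, **base)
    test_cfg = SynthConfig(n_children=1450, exact_n_case=754,
                           surveillance_year=2010, seed=seed + 1, **base)
    train, truth = generate_corpus(train_cfg)
    test, truth_test = generate_corpus(test_cfg)
    truth.statuses.update(
        {f"y2010-{k}": v for k, v in truth_test.statuses.items()})
    return train, test, truth


def preset(name: str, seed: int = 0) -> SynthConfig:
    """Bundled configurations: addm2008, addm2010, null, strong-signal."""
    presets = {
        "addm2008": dict(n_children=1162, exact_n_case=601,
                         surveillance_year=2008,
                         n_discriminative_terms=30, effect_log_odds=2.0),
        "addm2010": dict(n_children=1450, exact_n_case=754,
                         surveillance_year=2010,
                         n_discriminative_terms=30, effect_log_odds=2.0),
        "null": dict(n_children=600, case_fraction=0.5,
                     n_discriminative_terms=10, effect_log_odds=0.0,
                     n_noise_terms=500, tokens_per_eval_mean=40.0,
                     case_params=pooled_params(),
                     noncase_params=pooled_params()),
        "strong-signal": dict(n_children=600, case_fraction=0.517,
                              n_discriminative_terms=10,
                              effect_log_odds=2.5, n_noise_terms=500,
                              tokens_per_eval_mean=40.0),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; have {sorted(presets)}")
    return SynthConfig(seed=seed, **presets[name])
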