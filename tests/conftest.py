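import numpy as np
import pytest

from asdsurv.corpus import ChildRecord, Corpus, EvaluationRecord
from asdsurv.forest import ForestConfig
from asdsurv.pipeline import SurveillanceTextModel
from asdsurv.synth import SynthConfig, generate_corpus


def make_child(cid, texts, status="case", ages=None, sources=None, **kwargs):
    ages = ages if ages is not None else list(range(30, 30 + len(texts)))
    sources = sources or ["school"] * len(texts)
    evals = [
        EvaluationRecord(child_id=cid, source=s, age_months=a, text=t)
        for t, a, s in zip(texts, ages, sources)
    ]
    return ChildRecord(child_id=cid, status=status, evaluations=evals,
                       **kwargs)


@pytest.fixture
def toy_corpus():
    """Six labeled children with hand-written evaluation texts."""
    children = [
        make_child("c1", ["poor eye contact and no speech",
                          "autism features noted"], "case"),
        make_child("c2", ["eye contact avoided, spins objects"], "case"),
        make_child("c3", ["speech delay, good eye contact"], "noncase"),
        make_child("c4", ["typical development reported"], "noncase"),
        make_child("c5", ["autism spectrum concerns raised twice",
                          "repetitive behaviors"], "case"),
        make_child("c6", ["attention difficulties only"], "noncase"),
    ]
    return Corpus(surveillance_year=2008, children=children)


SMALL_SYNTH = dict(n_noise_terms=300, tokens_per_eval_mean=25.0,
                   n_discriminative_terms=8, effect_log_odds=2.0)

SMALL_FOREST = dict(n_trees_selection=120, n_trees_final=120,
                    k_candidates=30, k_step=10)


@pytest.fixture(scope="session")
def small_fit():
    """One small fitted pipeline shared across read-only tests."""
    train, truth = generate_corpus(
        SynthConfig(n_children=250, seed=21, **SMALL_SYNTH))
    test, _ = generate_corpus(
        SynthConfig(n_children=200, seed=22, **SMALL_SYNTH))
    results = SurveillanceTextModel(
        train, forest_config=ForestConfig(seed=5, **SMALL_FOREST)).fit()
    return train, test, truth, results
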