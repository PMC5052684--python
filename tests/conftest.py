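"""Shared fixtures: small synthetic corpora and trained text models.

Everything is generated programmatically from fixed seeds; training the
study and sample classifiers is done once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from geosig.synthdata import SimConfig, build_default_vocabularies, simulate_corpus
from geosig.textclf import SampleControlModel, StudyCategoryModel

TRAIN_SEED = 11
EVAL_SEED = 42


@pytest.fixture(scope="session")
def training_corpus():
    cfg = SimConfig(n_studies=80, n_genes=50, seed=TRAIN_SEED)
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def eval_corpus():
    cfg = SimConfig(n_studies=30, n_genes=300, seed=EVAL_SEED)
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def study_model(training_corpus):
    studies, truth = training_corpus
    labels = [truth[s.study_id].category for s in studies]
    return StudyCategoryModel(model="gbm", seed=0).fit(studies, labels)


@pytest.fixture(scope="session")
def sample_model(training_corpus):
    studies, truth = training_corpus
    samples, is_ctrl = [], []
    for s in studies:
        t = truth[s.study_id]
        if t.category == "other":
            continue
        for smp in s.samples:
            samples.append(smp)
            is_ctrl.append(int(smp.sample_id in t.control_ids))
    return SampleControlModel(seed=0).fit(samples, is_ctrl)


@pytest.fixture(scope="session")
def vocabularies():
    return build_default_vocabularies()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
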