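"""Automatic signature extraction: study filtering, metadata clustering,
group labeling, entity tagging and the end-to-end pipeline."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from geosig.autoextract import (
    AutoExtractConfig,
    auto_extract,
    cluster_samples,
    enumerate_pairs,
    filter_studies,
    label_clusters,
    sample_distance_matrix,
    tag_entities,
)
from geosig.curation_qc import check_integrity
from geosig.geo_io import Study, Vocabulary


def test_config_threshold_ordering_validated():
    with pytest.raises(ValueError):
        AutoExtractConfig(control_mean_threshold=0.3, treatment_mean_threshold=0.7)


class _FixedClassifier:
    def __init__(self, probs):
        self.probs = probs

    def predict_categories(self, studies):
        return self.probs


def _bare_study(n, study_id="S1"):
    from geosig.geo_io import Sample

    return Study(study_id=study_id,
                 samples=[Sample(sample_id=f"{study_id}x{i}") for i in range(n)])


def test_filter_studies_threshold_is_strict():
    studies = [_bare_study(2, "A"), _bare_study(2, "B"), _bare_study(2, "C")]
    clf = _FixedClassifier([
        {"gene": 0.95, "other": 0.05},
        {"gene": 0.90, "other": 0.10},   # exactly 0.9 -> dropped
        {"other": 0.99, "gene": 0.01},   # 'other' never kept
    ])
    kept = filter_studies(studies, clf)
    assert [(s.study_id, c) for s, c, _ in kept] == [("A", "gene")]


def test_filter_studies_category_precision_on_generated_corpus(
    eval_corpus, study_model
):
    studies, truth = eval_corpus
    kept = filter_studies(studies, study_model)
    assert kept, "classifier should keep some studies"
    correct = sum(truth[s.study_id].category == c for s, c, _ in kept)
    assert correct / len(kept) > 0.9


def test_manhattan_distance_counts_differing_tokens():
    v = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]])
    d = sample_distance_matrix(v)
    assert d[0, 1] == 0
    assert d[0, 2] == 4
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def test_dbscan_two_tight_groups_and_all_noise():
    # two groups separated by more than eps
    d = np.array([
        [0, 1, 9, 9],
        [1, 0, 9, 9],
        [9, 9, 0, 1],
        [9, 9, 1, 0],
    ], float)
    labels = cluster_samples(d, eps=3)
    assert labels[0] == labels[1] != labels[2] == labels[3]
    far = np.full((4, 4), 10.0)
    np.fill_diagonal(far, 0.0)
    assert set(cluster_samples(far, eps=3)) == {-1}


@pytest.mark.parametrize("seed", range(30))
def test_dbscan_min_samples_two_equals_connected_components(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 15)
    pts = rng.integers(0, 2, (n, 8))
    d = sample_distance_matrix(pts)
    eps = float(rng.integers(1, 4))
    labels = cluster_samples(d, eps=eps, min_samples=2)
    # oracle: connected components of the eps-neighborhood graph over
    # points that have at least one neighbor within eps
    adj = (d <= eps) & ~np.eye(n, dtype=bool)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    isolated = ~adj.any(axis=1)
    ours = {}
    for lab in set(labels) - {-1}:
        ours[lab] = frozenset(np.flatnonzero(labels == lab))
    theirs = {}
    for c in range(n_comp):
        members = np.flatnonzero((comp == c) & ~isolated)
        if len(members):
            theirs[c] = frozenset(members)
    assert set(ours.values()) == set(theirs.values())
    assert set(np.flatnonzero(labels == -1)) == set(np.flatnonzero(isolated))


def test_label_clusters_mean_and_std_rules():
    labels = np.array([0, 0, 1, 1, 2, 2, -1])
    probs = np.array([0.9, 0.8, 0.1, 0.2, 0.1, 0.9, 0.99])
    controls, treatments, discarded = label_clusters(labels, probs)
    assert controls == [[0, 1]]       # mean 0.85, std 0.05
    assert treatments == [[2, 3]]     # mean 0.15
    assert discarded == [[4, 5]]      # std 0.4 > 0.2
    # noise sample (index 6) never contributes


def test_enumerate_pairs_cartesian_product_and_integrity():
    study = _bare_study(7)
    subs = enumerate_pairs(study, [[0], [1]], [[2, 3], [4], [5]], "drug", "imatinib")
    assert len(subs) == 6
    assert enumerate_pairs(study, [], [[2]], "drug", "x") == []
    index = {study.study_id: set(study.sample_ids)}
    assert all(check_integrity(s, index) == "valid" for s in subs)
    assert all(s.study_id == study.study_id for s in subs)


@pytest.fixture()
def drug_vocab():
    return {
        "drug": Vocabulary(
            "drug", frozenset({"imatinib", "dasatinib"}), {"gleevec": "imatinib"}
        )
    }


def test_tag_entities_counting_tie_break_and_synonyms(drug_vocab):
    counts, label, flagged = tag_entities(
        "imatinib response; imatinib and dasatinib compared", drug_vocab, "drug"
    )
    assert counts == {"imatinib": 2, "dasatinib": 1}
    assert label == "imatinib" and not flagged
    # tie broken by earliest mention
    _, label2, _ = tag_entities("dasatinib then imatinib", drug_vocab, "drug")
    assert label2 == "dasatinib"
    # synonyms map before counting
    counts3, label3, _ = tag_entities("Gleevec twice: gleevec. dasatinib once",
                                      drug_vocab, "drug")
    assert counts3["imatinib"] == 2 and label3 == "imatinib"
    _, label4, flagged4 = tag_entities("nothing relevant here", drug_vocab, "drug")
    assert flagged4 and label4 == "unknown:drug"


def test_auto_extract_recovers_planted_designs(eval_corpus, study_model,
                                               sample_model, vocabularies):
    studies, truth = eval_corpus
    sigs, audits = auto_extract(studies, study_model, sample_model, vocabularies,
                                seed=1)
    planted = {
        (s.study_id, frozenset(truth[s.study_id].control_ids),
         frozenset(truth[s.study_id].treatment_ids))
        for s in studies if truth[s.study_id].category != "other"
    }
    found = {(g.study_id, g.control_ids, g.perturbation_ids) for g in sigs}
    tp = len(planted & found)
    assert tp / len(found) >= 0.7   # precision
    assert tp / len(planted) >= 0.7  # recall
    # signatures carry confidence and the cd+sva tag; no cross-study mixing
    for g in sigs:
        assert g.provenance == "auto"
        assert g.method == "cd+sva"
        assert 0.0 <= g.confidence <= 1.0
        member_ids = set(next(s for s in studies
                              if s.study_id == g.study_id).sample_ids)
        assert (g.control_ids | g.perturbation_ids) <= member_ids


def test_auto_extract_is_deterministic(eval_corpus, study_model, sample_model,
                                       vocabularies):
    studies, _ = eval_corpus
    subset = studies[:6]
    a, _ = auto_extract(subset, study_model, sample_model, vocabularies, seed=3)
    b, _ = auto_extract(subset, study_model, sample_model, vocabularies, seed=3)
    assert [s.signature_id for s in a] == [s.signature_id for s in b]
    for sa, sb in zip(a, b):
        assert sa.coefficients == sb.coefficients


def test_auto_extract_empty_when_no_study_qualifies(study_model, sample_model,
                                                    vocabularies):
    clf = _FixedClassifier([{"gene": 0.2, "other": 0.8}])
    sigs, audits = auto_extract([_bare_study(4)], clf, sample_model, vocabularies)
    assert sigs == []
    assert audits[0].kept is False
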