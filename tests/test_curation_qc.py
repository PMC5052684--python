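"""Sanitization filters: integrity, gene symbols, swap detection,
the strict >10% curator rule, and the full pipeline on planted truth."""

import numpy as np
import pytest

from geosig.curation_qc import (
    apply_curator_filter,
    check_gene_symbol,
    check_integrity,
    detect_swapped_groups,
    sanitize,
)
from geosig.geo_io import Submission, Vocabulary
from geosig.synthdata import (
    SimConfig,
    build_default_vocabularies,
    simulate_corpus,
    simulate_submissions,
)


def _sub(ctrl, pert, stype="gene", entity="TP53", curator="c1",
         study="GSE1", direction=None):
    return Submission(curator_id=curator, study_id=study,
                      control_ids=frozenset(ctrl), perturbation_ids=frozenset(pert),
                      signature_type=stype, entity_label=entity,
                      perturbation_direction=direction)


INDEX = {"GSE1": {"s1", "s2", "s3", "s4"}}


def test_integrity_overlap_membership_and_unknown_study():
    assert check_integrity(_sub({"s1"}, {"s1", "s2"}), INDEX) == "invalid:overlap"
    assert check_integrity(_sub({"s1"}, {"s2"}), INDEX) == "valid"
    assert check_integrity(_sub({"s1"}, {"sX"}), INDEX) == "invalid:membership"
    assert check_integrity(_sub({"s1"}, {"s2"}, study="GSE9"), INDEX).startswith(
        "invalid:unknown-study"
    )


def test_gene_symbol_check_with_normalization():
    vocab = Vocabulary("gene", frozenset({"TP53"}), {"p53": "TP53"})
    assert check_gene_symbol(_sub({"s1"}, {"s2"}, entity="TP53"), vocab) == "valid"
    assert check_gene_symbol(_sub({"s1"}, {"s2"}, entity="tp53"), vocab) == "valid"
    assert check_gene_symbol(_sub({"s1"}, {"s2"}, entity="P53"), vocab) == "valid"
    assert (
        check_gene_symbol(_sub({"s1"}, {"s2"}, entity="NOTAGENE"), vocab)
        == "invalid:gene-symbol"
    )
    # non-gene submissions are exempt
    assert (
        check_gene_symbol(_sub({"s1"}, {"s2"}, stype="drug", entity="x"), vocab)
        == "valid"
    )


def _expression_study(diff):
    import pandas as pd

    from geosig.geo_io import Sample, Study

    expr = pd.DataFrame(
        {"s1": [5.0], "s2": [5.0], "s3": [5.0 + diff], "s4": [5.0 + diff]},
        index=["TP53"],
    )
    return Study(study_id="GSE1",
                 samples=[Sample(sample_id=s) for s in ["s1", "s2", "s3", "s4"]],
                 expression=expr)


@pytest.mark.parametrize(
    "direction,diff,expected",
    [
        ("knockdown", +2.5, "swapped"),   # target up after knockdown
        ("knockdown", -2.5, "ok"),
        ("overexpression", +3.0, "ok"),
        ("overexpression", -3.0, "swapped"),
        ("knockout", +0.2, "undecidable"),  # below tau
    ],
)
def test_swap_detection_rule(direction, diff, expected):
    sub = _sub({"s1", "s2"}, {"s3", "s4"}, direction=direction)
    assert detect_swapped_groups(sub, _expression_study(diff)) == expected


def test_swap_detection_undecidable_when_gene_unmeasured():
    sub = _sub({"s1", "s2"}, {"s3", "s4"}, entity="MISSING", direction="knockdown")
    assert detect_swapped_groups(sub, _expression_study(2.0)) == "undecidable"


def test_curator_filter_strict_ten_percent_boundary():
    flags = {
        "two_of_ten": [True] * 2 + [False] * 8,    # 20% -> removed
        "one_of_ten": [True] + [False] * 9,        # exactly 10% -> kept
        "zero_of_five": [False] * 5,               # kept
    }
    assert apply_curator_filter(flags) == ["two_of_ten"]


@pytest.fixture(scope="module")
def planted_pool():
    # 88 correct submissions from 8 good curators plus 12 violations split
    # over 2 bad curators whose every submission is a violation
    cfg = SimConfig(n_studies=88, n_genes=30, n_planted_degs=10,
                    category_mix={"gene": 0.6, "disease": 0.2, "drug": 0.2, "other": 0.0},
                    seed=17)
    studies, truths = simulate_corpus(cfg)
    violations = [("badA", "membership")] * 3 + [("badA", "overlap")] * 3 + \
                 [("badB", "bad_gene")] * 3 + [("badB", "swapped")] * 3
    submissions, planted = simulate_submissions(
        studies, truths, rng=7, violations=violations
    )
    index = {s.study_id: set(s.sample_ids) for s in studies}
    study_map = {s.study_id: s for s in studies}
    return studies, truths, submissions, planted, index, study_map


def test_sanitize_removes_exactly_the_planted_violations(planted_pool):
    _, _, submissions, planted, index, study_map = planted_pool
    vocabs = build_default_vocabularies()
    surviving, report = sanitize(submissions, index, vocabs, study_map)
    planted_idx = {i for i, _ in planted}
    # flagged set == planted set: invalid verdicts plus swap flags
    flagged = {
        i for i, v in enumerate(report.verdicts)
        if not v.is_valid or v.swap == "swapped"
    }
    assert flagged == planted_idx
    assert report.removed_curators == ["badA", "badB"]
    # survivors: every good-curator submission, all bad-curator ones gone
    assert report.n_surviving == len(submissions) - len(planted_idx)
    assert all(s.curator_id not in ("badA", "badB") for s in surviving)


def test_sanitize_corrects_swapped_groups_of_good_curators(planted_pool):
    studies, truths, submissions, planted, index, study_map = planted_pool
    # re-plant a swapped submission under a good curator with few submissions
    swap_idx = next(i for i, v in planted if v == "swapped")
    bad = submissions[swap_idx]
    fixed_pool = list(submissions[:88])  # only the correct ones
    fixed_pool.append(Submission(
        curator_id="curator01", study_id=bad.study_id,
        control_ids=bad.control_ids, perturbation_ids=bad.perturbation_ids,
        signature_type=bad.signature_type, entity_label=bad.entity_label,
        perturbation_direction=bad.perturbation_direction,
    ))
    surviving, report = sanitize(fixed_pool, index, build_default_vocabularies(),
                                 study_map)
    # curator01 has ~12 submissions, 1 swapped (<10% would be false: 1/12=8.3%)
    assert "curator01" not in report.removed_curators
    corrected = [s for s in surviving
                 if s.group_key() == fixed_pool[-1].swapped().group_key()]
    assert corrected, "swapped submission should survive with groups exchanged"


def test_sanitize_clean_pool_is_identity_and_idempotent(planted_pool):
    studies, truths, submissions, _, index, study_map = planted_pool
    clean = list(submissions[:88])
    vocabs = build_default_vocabularies()
    surviving, report = sanitize(clean, index, vocabs, study_map)
    assert surviving == clean
    assert report.removed_curators == []
    again, report2 = sanitize(surviving, index, vocabs, study_map)
    assert again == surviving and report2.n_surviving == report.n_surviving


def test_duplicate_submissions_collapsed_keeping_earliest(planted_pool):
    _, _, submissions, _, index, study_map = planted_pool
    dup = submissions[0]
    clone = Submission(curator_id="late", study_id=dup.study_id,
                       control_ids=dup.control_ids,
                       perturbation_ids=dup.perturbation_ids,
                       signature_type=dup.signature_type,
                       entity_label=dup.entity_label,
                       perturbation_direction=dup.perturbation_direction)
    surviving, report = sanitize([dup, clone], index,
                                 build_default_vocabularies(), study_map)
    assert report.n_duplicates_collapsed == 1
    assert [s.curator_id for s in surviving] == [dup.curator_id]
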