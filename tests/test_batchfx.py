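"""Batch inference, variance attribution and surrogate-variable correction."""

import numpy as np
import pandas as pd
import pytest

from geosig.batchfx import (
    batches_from_dates,
    correct_and_extract,
    estimate_surrogate_variables,
    pvca_lite,
    remove_surrogate_components,
)
from geosig.benchmark import roc
from geosig.diffexp import characteristic_direction
from geosig.errors import DegenerateContrastError, UndefinedAttributionError
from geosig.geo_io import Sample, Study, Submission
from geosig.synthdata import SimConfig, simulate_study


def _study_with_dates(dates):
    samples = [
        Sample(sample_id=f"GSM{i}", scan_date=d) for i, d in enumerate(dates, 1)
    ]
    return Study(study_id="GSE1", samples=samples)


def test_batches_from_dates_groups_by_date():
    ba = batches_from_dates(_study_with_dates(["2014-01-01", "2014-01-01",
                                               "2014-02-02", "2014-02-02"]))
    groups = ba.groups()
    assert len(groups) == 2
    assert sorted(len(v) for v in groups.values()) == [2, 2]
    assert ba.coverage == 1.0


def test_all_missing_dates_form_single_unknown_batch():
    ba = batches_from_dates(_study_with_dates([None, None, None]))
    assert set(ba.labels.values()) == {"unknown"}
    assert ba.coverage == 0.0


def test_planted_batch_partition_recovered_from_generated_study():
    cfg = SimConfig(n_studies=1, n_genes=30, seed=3)
    study, truth = simulate_study(cfg, "drug", np.random.default_rng(3))
    ba = batches_from_dates(study)
    assert ba.labels == truth.batches


def test_pvca_attributes_planted_structure(rng):
    n_genes, n = 300, 12
    batch = np.array([0] * 6 + [1] * 6)
    cond = np.tile([0, 1], 6)
    pure_batch = rng.normal(0, 0.2, (n_genes, n))
    pure_batch[:, batch == 1] += rng.normal(0, 2.0, n_genes)[:, None]
    vs = pvca_lite(pure_batch, batch, cond)
    assert vs.share_batch > 0.9
    pure_cond = rng.normal(0, 0.2, (n_genes, n))
    pure_cond[:, cond == 1] += rng.normal(0, 2.0, n_genes)[:, None]
    vs2 = pvca_lite(pure_cond, batch, cond)
    assert vs2.share_condition > 0.9
    for v in (vs, vs2):
        assert abs(v.share_batch + v.share_condition + v.share_residual - 1.0) < 1e-9


def test_pvca_white_noise_matches_permutation_null(rng):
    n_genes, n = 200, 12
    batch = np.array([0] * 6 + [1] * 6)
    cond = np.tile([0, 1], 6)
    x = rng.normal(0, 1, (n_genes, n))
    observed = pvca_lite(x, batch, cond)
    null = []
    for _ in range(30):
        vb = pvca_lite(x, rng.permutation(batch), rng.permutation(cond))
        null.append([vb.share_batch, vb.share_condition, vb.share_residual])
    null_mean = np.mean(null, axis=0)
    obs = np.array([observed.share_batch, observed.share_condition, observed.share_residual])
    assert np.all(np.abs(obs - null_mean) < 0.15)


def test_pvca_single_batch_and_condition_rejected(rng):
    x = rng.normal(size=(10, 4))
    with pytest.raises(UndefinedAttributionError):
        pvca_lite(x, [0, 0, 0, 0], ["a", "a", "a", "a"])


def test_surrogate_variable_recovers_planted_batch_vector(rng):
    n_genes, n = 500, 10
    batch = np.array([0] * 5 + [1] * 5)
    cond = np.array(["c"] * 3 + ["t"] * 2 + ["c"] * 2 + ["t"] * 3)
    x = rng.normal(0, 0.5, (n_genes, n))
    x[:, batch == 1] += rng.normal(0, 0.6, n_genes)[:, None]
    svs = estimate_surrogate_variables(x, cond, seed=1)
    assert svs.shape[1] >= 1
    assert abs(np.corrcoef(svs[:, 0], batch)[0, 1]) > 0.9


def test_no_surrogates_found_on_pure_noise_in_most_replicates():
    cond = ["c"] * 5 + ["t"] * 5
    zero = 0
    for i in range(50):
        x = np.random.default_rng(100 + i).normal(0, 1, (200, 10))
        svs = estimate_surrogate_variables(x, cond, seed=i)
        zero += svs.shape[1] == 0
    assert zero >= 45  # >= 90% of replicates


def test_forced_surrogate_is_orthonormal(rng):
    x = rng.normal(0, 1, (100, 8))
    cond = ["c"] * 4 + ["t"] * 4
    svs = estimate_surrogate_variables(x, cond, n_sv=2, seed=0)
    np.testing.assert_allclose(svs.T @ svs, np.eye(2), atol=1e-9)


def _confounded_study(seed):
    cfg = SimConfig(n_studies=1, samples_per_group=(5, 5), n_genes=1000,
                    n_planted_degs=50, effect_size=1.0, noise_sd=0.5,
                    batch_effect_size=1.0, batch_confound=0.6, seed=seed)
    return simulate_study(cfg, "drug", np.random.default_rng(seed))


def _planted_auc(coeffs, planted):
    scores = {g: abs(v) for g, v in coeffs.items()}
    labels = {g: int(g in planted) for g in coeffs}
    return roc(scores, labels).auc


def test_correction_improves_planted_deg_recovery_under_confounding():
    # partially confounded batches (phi ~ 0.6 with the condition): the
    # ordering is assessed on replicate studies to measure the population
    # effect rather than one noisy draw
    corrected_aucs, uncorrected_aucs = [], []
    for seed in (1, 2, 3, 4, 5):
        study, truth = _confounded_study(seed)
        sub = Submission("t", study.study_id, frozenset(truth.control_ids),
                         frozenset(truth.treatment_ids), "drug", truth.entity)
        sig = correct_and_extract(study, sub, sva_seed=0)
        assert sig.method == "cd+sva"
        uncorrected = characteristic_direction(
            study.expression[truth.control_ids], study.expression[truth.treatment_ids]
        )
        planted = set(truth.planted_up) | set(truth.planted_down)
        corrected_aucs.append(_planted_auc(sig.coefficients, planted))
        uncorrected_aucs.append(_planted_auc(uncorrected, planted))
    assert np.mean(corrected_aucs) > np.mean(uncorrected_aucs)


def test_correction_is_near_identity_without_batch_structure():
    cfg = SimConfig(n_studies=1, samples_per_group=(5, 5), n_genes=400,
                    batch_effect_size=0.0, seed=9)
    study, truth = simulate_study(cfg, "drug", np.random.default_rng(9))
    sub = Submission("t", study.study_id, frozenset(truth.control_ids),
                     frozenset(truth.treatment_ids), "drug", truth.entity)
    sig = correct_and_extract(study, sub, sva_seed=0)
    plain = characteristic_direction(
        study.expression[truth.control_ids], study.expression[truth.treatment_ids]
    )
    a = np.array([sig.coefficients[g] for g in plain])
    b = np.array(list(plain.values()))
    cosine = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    assert cosine > 0.95


def test_degenerate_contrast_propagates():
    cfg = SimConfig(n_studies=1, n_genes=20, samples_per_group=(3, 3), seed=2)
    study, truth = simulate_study(cfg, "drug", np.random.default_rng(2))
    expr = study.expression.copy()
    expr[truth.treatment_ids] = expr[truth.control_ids[: len(truth.treatment_ids)]].to_numpy()
    study2 = Study(study_id=study.study_id, samples=study.samples,
                   organism=study.organism, expression=expr)
    sub = Submission("t", study.study_id, frozenset(truth.control_ids),
                     frozenset(truth.treatment_ids), "drug", truth.entity)
    with pytest.raises(DegenerateContrastError):
        correct_and_extract(study2, sub, sva_seed=0)


def test_correction_removes_the_batch_structure():
    # after one pass the planted batch direction is gone: any surrogate a
    # second pass reports is uncorrelated with the true batch vector
    study, truth = _confounded_study(5)
    ids = truth.control_ids + truth.treatment_ids
    cond = ["c"] * len(truth.control_ids) + ["t"] * len(truth.treatment_ids)
    bind = np.array([truth.batches[s] == truth.batches[ids[-1]] for s in ids], float)
    x = study.expression[ids].to_numpy()
    svs = estimate_surrogate_variables(x, cond, seed=0)
    assert svs.shape[1] >= 1
    assert max(abs(np.corrcoef(svs[:, j], bind)[0, 1]) for j in range(svs.shape[1])) > 0.9
    corrected = remove_surrogate_components(x, cond, svs)
    # energy of the residual along the batch direction collapses
    b = bind - bind.mean()
    b /= np.linalg.norm(b)
    before = float(np.sum(((x - x.mean(axis=1, keepdims=True)) @ b) ** 2))
    after = float(np.sum(((corrected - corrected.mean(axis=1, keepdims=True)) @ b) ** 2))
    assert after < 0.2 * before
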