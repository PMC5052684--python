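"""Tokenization, TF-IDF, SVD reduction, naive Bayes, calibration and
the study/sample classifier harnesses."""

import itertools

import numpy as np
import pytest

from geosig._porter import porter_stem
from geosig.errors import GeosigError
from geosig.synthdata import SimConfig, simulate_corpus
from geosig.textclf import (
    CVMetrics,
    bag_and_calibrate,
    bernoulli_nb,
    fit_tfidf,
    isotonic_fit,
    metrics_from_predictions,
    nb_predict,
    reduce_svd,
    tokenize_stem,
    train_study_classifier,
    transform,
)


@pytest.mark.parametrize(
    "word,stem",
    [
        ("gene", "gene"), ("expression", "express"), ("profiling", "profil"),
        ("caresses", "caress"), ("ponies", "poni"), ("happy", "happi"),
        ("relational", "relat"), ("hopping", "hop"), ("agreed", "agre"),
        ("adjustable", "adjust"), ("activate", "activ"), ("knockdown", "knockdown"),
    ],
)
def test_porter_stems_known_words(word, stem):
    assert porter_stem(word) == stem


def test_tokenize_lowercases_filters_and_stems():
    assert tokenize_stem("Gene expression profiling") == ["gene", "express", "profil"]
    assert tokenize_stem("") == []
    assert tokenize_stem("a I x") == []  # stop words / single characters
    # alphanumeric tokens (doses) survive verbatim
    assert "10um" in tokenize_stem("imatinib 10uM dose")


def test_tokenize_idempotent_on_stems():
    stems = tokenize_stem("treated samples with overexpression constructs")
    assert tokenize_stem(" ".join(stems)) == stems


def test_tfidf_document_frequency_ordering():
    model = fit_tfidf(["aspirin boost", "aspirin cure"], ngram_range=(1, 1))
    vocab = model.vocabulary
    idf = model.idf
    assert idf[vocab["aspirin"]] < idf[vocab["boost"]]
    single = fit_tfidf(["one document only"], ngram_range=(1, 1))
    assert len(set(np.round(single.idf, 12))) == 1
    with pytest.raises(GeosigError):
        fit_tfidf([])


def test_tfidf_matches_hand_computed_matrix():
    # 3 docs over stems; idf = ln((1+N)/(1+df)) + 1, rows L2-normalized
    docs = ["drug drug dose", "drug tumor", "dose tumor tumor"]
    model = fit_tfidf(docs, ngram_range=(1, 1))
    mat = transform(model, docs).toarray()
    vocab = model.vocabulary
    df = {"drug": 2, "dose": 2, "tumor": 2}
    n = 3
    idf = {t: np.log((1 + n) / (1 + d)) + 1 for t, d in df.items()}
    def grams(doc):
        toks = tokenize_stem(doc)
        return toks + [" ".join(g) for g in zip(toks, toks[1:])]

    for i in range(n):
        row = np.zeros(len(vocab))
        for term, idx in vocab.items():
            tf = grams(docs[i]).count(term)
            docfreq = sum(1 for j in range(n) if term in grams(docs[j]))
            row[idx] = tf * (np.log((1 + n) / (1 + docfreq)) + 1)
        row = row / np.linalg.norm(row)
        np.testing.assert_allclose(mat[i], row, atol=1e-9)
    assert df  # unigram document frequencies used above via grams
    assert idf["drug"] == pytest.approx(np.log(4 / 3) + 1)


def test_reduce_svd_component_selection(rng):
    x = rng.normal(size=(20, 15))
    full = reduce_svd(x, variance_target=1.0)
    assert full.shape[1] == np.linalg.matrix_rank(x)
    rank1 = np.outer(rng.normal(size=12), rng.normal(size=6))
    assert reduce_svd(rank1, variance_target=0.10).shape[1] == 1
    # k matches an exhaustive scan over cumulative variance
    for target in (0.1, 0.3, 0.7, 0.95):
        k = reduce_svd(x, variance_target=target).shape[1]
        s = np.linalg.svd(x, compute_uv=False)
        var = s**2 / np.sum(s**2)
        brute = next(i + 1 for i in range(len(s)) if var[: i + 1].sum() >= target - 1e-12)
        assert k == brute


def test_bernoulli_nb_hand_bayes_with_laplace():
    # one token; class A shows it 3/4 times, class B 1/4; alpha=1:
    # P(present|A) = 4/6, P(present|B) = 2/6, equal priors
    # => P(A|present) = (4/6) / (4/6 + 2/6) = 2/3
    x = np.array([[1], [1], [1], [0], [1], [0], [0], [0]])
    y = np.array(["A"] * 4 + ["B"] * 4)
    model = bernoulli_nb(x, y, alpha=1.0)
    probs = nb_predict(model, [1])
    assert probs["A"] == pytest.approx(2 / 3, abs=1e-12)
    assert sum(probs.values()) == pytest.approx(1.0)


def test_bernoulli_nb_uninformative_token_gives_half_and_duplicate_invariance():
    x = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    y = np.array(["A", "A", "B", "B"])  # token 2 is uninformative
    model = bernoulli_nb(x[:, [1]], y)
    assert nb_predict(model, [1])["A"] == pytest.approx(0.5)
    # duplicating an uninformative token does not move the posterior
    base = bernoulli_nb(x, y)
    dup = bernoulli_nb(np.hstack([x, x[:, [1]]]), y)
    assert nb_predict(base, [1, 0])["A"] == pytest.approx(
        nb_predict(dup, [1, 0, 0])["A"]
    )


def test_isotonic_hand_pava_and_monotone_identity():
    iso = isotonic_fit([0.0, 1.0, 2.0], [1.0, 3.0, 2.0])
    np.testing.assert_allclose(iso.predict([0.0, 1.0, 2.0]), [1.0, 2.5, 2.5])
    mono = isotonic_fit([0.0, 1.0, 2.0], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(mono.predict([0.0, 1.0, 2.0]), [0.0, 0.5, 1.0])


def _bruteforce_isotonic(y):
    # exact: enumerate contiguous-block partitions, keep monotone-feasible
    # block-mean fits, return the squared-error minimizer
    n = len(y)
    best, best_err = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [np.mean(y[a:b]) for a, b in zip(bounds, bounds[1:])]
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        fit = np.concatenate(
            [np.full(b - a, m) for (a, b), m in zip(zip(bounds, bounds[1:]), means)]
        )
        err = float(np.sum((fit - y) ** 2))
        if err < best_err - 1e-15:
            best, best_err = fit, err
    return best


@pytest.mark.parametrize("seed", range(8))
def test_isotonic_matches_bruteforce_partition_optimum(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=8)
    x = np.arange(8.0)
    iso = isotonic_fit(x, y)
    np.testing.assert_allclose(iso.predict(x), _bruteforce_isotonic(y), atol=1e-8)


def test_metrics_match_hand_computed_confusion_values():
    # fixed 10-item prediction set, threshold 0.5:
    # predictions: [1,1,1,0,0,1,0,0,1,0]; truth: [1,1,0,0,1,1,0,0,0,0]
    # TP=3 FP=2 FN=1 TN=4
    y = [1, 1, 0, 0, 1, 1, 0, 0, 0, 0]
    p = [0.9, 0.8, 0.7, 0.4, 0.3, 0.6, 0.2, 0.1, 0.55, 0.45]
    m = metrics_from_predictions(y, p)
    tp, fp, fn, tn = 3, 2, 1, 4
    f1 = 2 * tp / (2 * tp + fp + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    assert m.f1 == pytest.approx(f1)
    assert m.mcc == pytest.approx(mcc)
    # AUROC by brute-force pair counting
    pairs = [(pi, pj) for pi, yi in zip(p, y) if yi for pj, yj in zip(p, y) if not yj]
    auroc = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
    assert m.auroc == pytest.approx(auroc)


def test_cvmetrics_range_validation():
    with pytest.raises(ValueError):
        CVMetrics(auroc=1.2, auprc=0.5, mcc=0.0, f1=0.5, folds=3)
    with pytest.raises(ValueError):
        CVMetrics(auroc=0.9, auprc=0.5, mcc=-1.5, f1=0.5, folds=3)


def test_calibrated_outputs_monotone_in_raw_scores(training_corpus):
    studies, truth = training_corpus
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, (120, 30)).astype(np.uint8)
    y = (x[:, :5].sum(axis=1) + rng.normal(0, 0.8, 120) > 2.5).astype(int)
    model = bag_and_calibrate(x, y, seed=0)
    raw = model.raw_predict_proba(x)
    cal = model.predict_proba(x)
    order = np.argsort(raw)
    assert np.all(np.diff(cal[order]) >= -1e-12)


def test_single_estimator_without_resampling_equals_plain_nb(rng):
    x = rng.integers(0, 2, (60, 12)).astype(np.uint8)
    y = (x[:, 0] | x[:, 1]).astype(int)
    model = bag_and_calibrate(x, y, n_estimators=1, bootstrap=False, seed=0)
    nb = bernoulli_nb(x, y)
    raw = model.raw_predict_proba(x)
    ref = nb.predict_proba(x)[:, list(nb.classes_).index(1)]
    np.testing.assert_allclose(raw, ref, atol=1e-12)


def test_sample_titles_separate_control_from_treatment(sample_model):
    m = sample_model.metrics
    assert m.auroc > 0.9
    assert m.folds == 10


def _study_features(studies, seed=0):
    from geosig.textclf import fit_tfidf, reduce_svd, transform

    feats = {}
    for field in ("title", "summary", "keywords"):
        docs = [getattr(s, field) for s in studies]
        feats[field] = reduce_svd(transform(fit_tfidf(docs), docs), 0.5)
    return feats


def test_study_classifier_separable_vs_shuffled(training_corpus):
    studies, truth = training_corpus
    labels = np.array(
        [int(truth[s.study_id].category == "gene") for s in studies]
    )
    feats = _study_features(studies)
    _, metrics = train_study_classifier(feats, labels, model="rf", seed=0)
    assert metrics.auroc > 0.9
    shuffled = np.random.default_rng(0).permutation(labels)
    _, null_metrics = train_study_classifier(feats, shuffled, model="rf", seed=0)
    assert 0.4 < null_metrics.auroc < 0.6


def test_study_classifier_rejects_single_class(training_corpus):
    studies, _ = training_corpus
    feats = _study_features(studies)
    with pytest.raises(GeosigError):
        train_study_classifier(feats, np.zeros(len(studies), int), model="rf")
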