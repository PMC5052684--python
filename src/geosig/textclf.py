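"""Text featurization and classifiers over study and sample metadata.

Two classification problems are handled:

* **Study categorization** — does a series describe a gene, disease or
  drug perturbation? Free text (title, summary, keywords) is tokenized,
  Porter-stemmed, converted to unigram+bigram TF-IDF per field, reduced
  by truncated SVD to capture at least 10% of the variance, concatenated
  and fed to a standard classifier (gradient boosting by default),
  evaluated with 3-fold cross-validation.

* **Control-vs-treatment sample labeling** — binary presence/absence
  token vectors from the sample's title, description, characteristics
  and source name, classified by a bagging of 20 Bernoulli naive Bayes
  models whose averaged probabilities are calibrated with isotonic
  regression fitted on out-of-fold predictions (10-fold CV).

Both report AUROC, AUPRC, Matthews correlation and F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC

from ._porter import porter_stem
from .errors import GeosigError
from .geo_io import Sample, Study

# A fixed small English stop list; tokens of length 1 are always dropped.
STOPWORDS = frozenset(
    """a an and are as at be been but by for from had has have if in into is
    it its no not of on or such that the their then there these they this to
    was we were what when which while who will with during each between after
    before""".split()
)

_TOKEN_SPLIT = None  # compiled lazily


def tokenize_stem(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop single characters and
    stop words, Porter-stem the rest. Purely alphabetic tokens are
    stemmed; alphanumeric tokens (doses, ids) are kept verbatim."""
    import re

    global _TOKEN_SPLIT
    if _TOKEN_SPLIT is None:
        _TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")
    out = []
    for tok in _TOKEN_SPLIT.split(text.lower()):
        if len(tok) <= 1 or tok in STOPWORDS:
            continue
        out.append(porter_stem(tok) if tok.isalpha() else tok)
    return out


@dataclass
class TfidfModel:
    """Fitted unigram+bigram TF-IDF over stems.

    idf = ln((1+N)/(1+df)) + 1 with document-wise L2 normalization;
    vocabulary is deterministic for a fixed corpus and tokenizer.
    """

    vectorizer: TfidfVectorizer
    n_documents: int

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_


def fit_tfidf(corpus: Sequence[str], ngram_range: tuple[int, int] = (1, 2)) -> TfidfModel:
    if not corpus:
        raise GeosigError("cannot fit TF-IDF on an empty corpus")
    vec = TfidfVectorizer(
        tokenizer=tokenize_stem,
        token_pattern=None,
        lowercase=False,
        ngram_range=ngram_range,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    vec.fit(corpus)
    return TfidfModel(vectorizer=vec, n_documents=len(corpus))


def transform(model: TfidfModel, docs: Sequence[str]) -> sparse.csr_matrix:
    return model.vectorizer.transform(docs)


def reduce_svd(matrix, variance_target: float = 0.10) -> np.ndarray:
    """Truncated SVD keeping the smallest k components whose cumulative
    squared singular values reach ``variance_target`` of the total.
    Returns the document embedding U_k * s_k."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix, float)
    u, s, _ = np.linalg.svd(dense, full_matrices=False)
    nonzero = s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0)
    u, s = u[:, nonzero], s[nonzero]
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return u[:, :k] * s[:k]


@dataclass
class CVMetrics:
    """Cross-validated binary classification metrics."""

    auroc: float
    auprc: float
    mcc: float
    f1: float
    folds: int

    def __post_init__(self) -> None:
        for name in ("auroc", "auprc", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.mcc <= 1.0:
            raise ValueError(f"mcc={self.mcc} outside [-1, 1]")


def metrics_from_predictions(
    y_true, y_prob, folds: int = 1, threshold: float = 0.5
) -> CVMetrics:
    """AUROC/AUPRC from probabilities; MCC/F1 at the given threshold."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    y_hat = (y_prob >= threshold).astype(int)
    return CVMetrics(
        auroc=float(roc_auc_score(y_true, y_prob)),
        auprc=float(average_precision_score(y_true, y_prob)),
        mcc=float(matthews_corrcoef(y_true, y_hat)),
        f1=float(f1_score(y_true, y_hat)),
        folds=folds,
    )


_MODEL_GRIDS: dict[str, tuple] = {
    "gbm": (
        GradientBoostingClassifier,
        {"n_estimators": [50, 100], "max_depth": [2, 3]},
    ),
    "rf": (
        RandomForestClassifier,
        {"n_estimators": [100, 200], "max_features": ["sqrt", None]},
    ),
    "extra_trees": (
        ExtraTreesClassifier,
        {"n_estimators": [100, 200], "max_features": ["sqrt", None]},
    ),
    "svc": (
        SVC,
        {"C": [0.1, 1.0, 10.0]},
    ),
}


def train_study_classifier(
    field_features: Mapping[str, np.ndarray],
    labels: Sequence[int],
    model: str = "gbm",
    seed: int = 0,
    grid: Mapping | None = None,
):
    """Fit a study-level binary classifier on concatenated per-field
    feature matrices (title / summary / keywords embeddings).

    A small grid search (3-fold stratified) picks hyperparameters by
    AUROC; out-of-fold predictions with the selected configuration give
    the reported CVMetrics. Returns (fitted classifier, CVMetrics).
    """
    if model not in _MODEL_GRIDS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODEL_GRIDS)}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise GeosigError("labels contain a single class")
    x = np.hstack([np.asarray(field_features[k], float) for k in sorted(field_features)])
    cls, default_grid = _MODEL_GRIDS[model]
    kwargs = {"random_state": seed}
    if model == "svc":
        kwargs["probability"] = True
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(
        cls(**kwargs), dict(grid or default_grid), scoring="roc_auc", cv=cv,
    )
    search.fit(x, y)
    best = search.best_estimator_
    oof = cross_val_predict(best, x, y, cv=cv, method="predict_proba")[:, 1]
    metrics = metrics_from_predictions(y, oof, folds=3)
    best.fit(x, y)
    return best, metrics


# ---------------------------------------------------------------------------
# Sample-level: binary token vectors + bagged Bernoulli NB + isotonic


class TokenVectorizer:
    """Binary presence/absence vectors over a stemmed token vocabulary."""

    def __init__(self) -> None:
        self._vec = CountVectorizer(
            tokenizer=tokenize_stem, token_pattern=None, lowercase=False,
            binary=True,
        )

    def fit(self, texts: Sequence[str]) -> "TokenVectorizer":
        self._vec.fit(texts)
        return self

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        return self._vec.transform(texts).toarray().astype(np.uint8)

    def fit_transform(self, texts: Sequence[str]) -> np.ndarray:
        return self.fit(texts).transform(texts)

    @property
    def vocabulary(self) -> dict[str, int]:
        return self._vec.vocabulary_


def sample_text(sample: Sample, fields: Sequence[str] | None = None) -> str:
    """Concatenate a sample's metadata text fields for featurization."""
    texts = sample.text_fields()
    keys = fields or ("title", "description", "characteristics", "source_name")
    return " ".join(texts[k] for k in keys if texts.get(k))


def bernoulli_nb(train_vectors, labels, alpha: float = 1.0) -> BernoulliNB:
    """Bernoulli naive Bayes with Laplace smoothing ``alpha``; class
    priors from class frequencies; the posterior uses both token-presence
    and token-absence likelihood terms."""
    model = BernoulliNB(alpha=alpha)
    model.fit(np.asarray(train_vectors), np.asarray(labels))
    return model


def nb_predict(model: BernoulliNB, vector) -> dict:
    """Posterior class probabilities for one binary token vector."""
    probs = model.predict_proba(np.asarray(vector).reshape(1, -1))[0]
    return dict(zip(model.classes_.tolist(), probs.tolist()))


def isotonic_fit(scores, labels) -> IsotonicRegression:
    """Pool-adjacent-violators monotone least-squares fit of labels on
    scores (the calibration map). out_of_bounds clips to the fitted range."""
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(np.asarray(scores, float), np.asarray(labels, float))
    return iso


class CalibratedBaggedNB:
    """Bagging of Bernoulli NB classifiers with isotonic calibration.

    ``n_estimators`` bootstrap-resampled NB models vote by averaging
    probabilities; the isotonic map is fitted on out-of-fold averaged
    probabilities from ``n_folds`` stratified CV, so calibrated outputs
    are a monotone function of the raw bagged scores.
    """

    def __init__(
        self,
        n_estimators: int = 20,
        alpha: float = 1.0,
        n_folds: int = 10,
        bootstrap: bool = True,
        seed: int = 0,
    ) -> None:
        self.n_estimators = n_estimators
        self.alpha = alpha
        self.n_folds = n_folds
        self.bootstrap = bootstrap
        self.seed = seed
        self.bag: BaggingClassifier | None = None
        self.isotonic: IsotonicRegression | None = None
        self.metrics: CVMetrics | None = None

    def _make_bag(self) -> BaggingClassifier:
        return BaggingClassifier(
            estimator=BernoulliNB(alpha=self.alpha),
            n_estimators=self.n_estimators,
            bootstrap=self.bootstrap,
            random_state=self.seed,
        )

    def fit(self, vectors, labels) -> "CalibratedBaggedNB":
        x = np.asarray(vectors)
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise GeosigError("labels contain a single class")
        n_folds = min(self.n_folds, int(np.bincount(y).min()))
        if n_folds < 2:
            raise GeosigError("too few samples per class for cross-validation")
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
        oof = cross_val_predict(self._make_bag(), x, y, cv=cv, method="predict_proba")[:, 1]
        self.isotonic = isotonic_fit(oof, y)
        self.metrics = metrics_from_predictions(y, self.isotonic.predict(oof), folds=n_folds)
        self.bag = self._make_bag().fit(x, y)
        return self

    def raw_predict_proba(self, vectors) -> np.ndarray:
        """Averaged (uncalibrated) bagged NB probability of the positive class."""
        if self.bag is None:
            raise GeosigError("model not fitted")
        return self.bag.predict_proba(np.asarray(vectors))[:, 1]

    def predict_proba(self, vectors) -> np.ndarray:
        """Isotonic-calibrated probability of the positive class."""
        raw = self.raw_predict_proba(vectors)
        return self.isotonic.predict(raw)


def bag_and_calibrate(
    train, labels, n_estimators: int = 20, n_folds: int = 10,
    bootstrap: bool = True, seed: int = 0,
) -> CalibratedBaggedNB:
    """Convenience wrapper: fit a :class:`CalibratedBaggedNB`."""
    return CalibratedBaggedNB(
        n_estimators=n_estimators, n_folds=n_folds, bootstrap=bootstrap, seed=seed
    ).fit(train, labels)


# ---------------------------------------------------------------------------
# End-to-end models over Studies and Samples


class StudyCategoryModel:
    """Multi-category study classifier over title/summary/keywords text.

    Per-field TF-IDF + truncated SVD embeddings are concatenated and fed
    to one multiclass classifier with probability outputs; categories are
    whatever labels were supplied at fit time (for example gene, disease,
    drug, other).
    """

    FIELDS = ("title", "summary", "keywords")

    def __init__(self, model: str = "gbm", variance_target: float = 0.10,
                 seed: int = 0) -> None:
        self.model_name = model
        self.variance_target = variance_target
        self.seed = seed
        self.tfidf: dict[str, TfidfModel] = {}
        self.components: dict[str, np.ndarray] = {}
        self.classifier = None
        self.categories: list[str] = []

    def _field_text(self, study: Study, field: str) -> str:
        return getattr(study, field) or ""

    def _embed(self, studies: Sequence[Study], fit: bool) -> np.ndarray:
        blocks = []
        for field in self.FIELDS:
            docs = [self._field_text(s, field) for s in studies]
            if fit:
                self.tfidf[field] = fit_tfidf(docs)
                mat = transform(self.tfidf[field], docs)
                dense = mat.toarray()
                u, s, vt = np.linalg.svd(dense, full_matrices=False)
                nonzero = s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0)
                u, s, vt = u[:, nonzero], s[nonzero], vt[nonzero]
                var = s**2
                cum = np.cumsum(var) / var.sum()
                k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
                self.components[field] = vt[:k]
                blocks.append(u[:, :k] * s[:k])
            else:
                mat = transform(self.tfidf[field], docs).toarray()
                blocks.append(mat @ self.components[field].T)
        return np.hstack(blocks)

    def fit(self, studies: Sequence[Study], categories: Sequence[str]) -> "StudyCategoryModel":
        y = np.asarray(categories)
        self.categories = sorted(set(y.tolist()))
        x = self._embed(studies, fit=True)
        cls, grid = _MODEL_GRIDS[self.model_name]
        kwargs = {"random_state": self.seed}
        if self.model_name == "svc":
            kwargs["probability"] = True
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=self.seed)
        search = GridSearchCV(cls(**kwargs), dict(grid), cv=cv)
        search.fit(x, y)
        self.classifier = search.best_estimator_.fit(x, y)
        return self

    def predict_categories(self, studies: Sequence[Study]) -> list[dict[str, float]]:
        """Per-study category -> probability maps."""
        x = self._embed(studies, fit=False)
        probs = self.classifier.predict_proba(x)
        classes = self.classifier.classes_.tolist()
        return [dict(zip(classes, row.tolist())) for row in probs]


class SampleControlModel:
    """Control-probability model over sample metadata text.

    Binary token vectors feed a calibrated bagged Bernoulli NB; the
    positive class is "control", so ``prob_control`` near 1 marks likely
    control samples and near 0 likely treatment samples.
    """

    def __init__(self, fields: Sequence[str] = ("title",), seed: int = 0,
                 n_estimators: int = 20, n_folds: int = 10) -> None:
        self.fields = tuple(fields)
        self.seed = seed
        self.n_estimators = n_estimators
        self.n_folds = n_folds
        self.vectorizer = TokenVectorizer()
        self.model: CalibratedBaggedNB | None = None

    def fit(self, samples: Sequence[Sample], is_control: Sequence[int]) -> "SampleControlModel":
        texts = [sample_text(s, self.fields) for s in samples]
        x = self.vectorizer.fit_transform(texts)
        self.model = bag_and_calibrate(
            x, np.asarray(is_control, int),
            n_estimators=self.n_estimators, n_folds=self.n_folds, seed=self.seed,
        )
        return self

    @property
    def metrics(self) -> CVMetrics | None:
        return self.model.metrics if self.model is not None else None

    def prob_control(self, samples: Sequence[Sample]) -> np.ndarray:
        texts = [sample_text(s, self.fields) for s in samples]
        return self.model.predict_proba(self.vectorizer.transform(texts))

    def token_vectors(self, samples: Sequence[Sample],
                      fields: Sequence[str] | None = None) -> np.ndarray:
        texts = [sample_text(s, fields or self.fields) for s in samples]
        return self.vectorizer.transform(texts)
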