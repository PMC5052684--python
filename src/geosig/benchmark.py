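"""Benchmarking signatures against prior-knowledge gene sets.

Prior knowledge supplies, per perturbed entity, the genes expected to be
differentially expressed (direct protein interactors for a gene
perturbation, disease-associated genes for a disease, known targets for
a drug). Quality is scored by where those genes land in the signature's
coefficient ranking: scaled ranks, pooled ROC curves with
Mann-Whitney-consistent AUC, DeLong's test between methods, and a
Kolmogorov-Smirnov distance of scaled ranks from uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, GeosigError, UndefinedROCError
from .geo_io import Signature, read_gmt


@dataclass
class PriorKnowledge:
    """entity -> expected differentially-expressed gene set."""

    kind: str  # ppi | disease_genes | drug_targets
    expected: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for entity, genes in self.expected.items():
            if not genes:
                raise GeosigError(f"empty expected set for {entity!r}")
            self.expected[entity] = frozenset(genes)

    @classmethod
    def from_gmt(cls, path, kind: str = "ppi") -> "PriorKnowledge":
        sets = read_gmt(path)
        return cls(kind=kind, expected={name: frozenset(genes)
                                        for name, (_, genes) in sets.items()})


@dataclass
class ROCResult:
    """ROC points, trapezoid AUC (== Mann-Whitney with ties at 1/2), and
    the underlying scores/labels (kept for DeLong comparisons)."""

    points: list[tuple[float, float]]
    auc: float
    n_pos: int
    n_neg: int
    items: list = field(default_factory=list, repr=False)
    scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def scaled_ranks(
    coefficients: Mapping[str, float], expected_genes
) -> tuple[list[float], int]:
    """Scaled ranks (rank/total, in (0, 1]) of the expected genes when all
    genes are ordered by |coefficient| descending (ties broken by symbol).

    Expected genes absent from the coefficient map are dropped; their
    count is returned alongside the ranks.
    """
    genes = sorted(coefficients, key=lambda g: (-abs(coefficients[g]), g))
    total = len(genes)
    rank_of = {g: i + 1 for i, g in enumerate(genes)}
    expected = set(expected_genes)
    dropped = sum(1 for g in expected if g not in rank_of)
    ranks = sorted(rank_of[g] / total for g in expected if g in rank_of)
    return ranks, dropped


def roc(scores: Mapping, labels: Mapping) -> ROCResult:
    """ROC curve and AUC for item->score against item->{0,1} labels.

    The AUC equals the Mann-Whitney probability P(score_pos > score_neg)
    with ties counted 1/2; it is computed from midranks, and the plotted
    staircase (tie-grouped thresholds) integrates to the same value.
    """
    items = sorted(scores)
    if set(items) != set(labels):
        raise ValueError("scores and labels must cover the same items")
    y = np.array([int(labels[i]) for i in items])
    s = np.array([float(scores[i]) for i in items])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(f"need both classes: n_pos={n_pos}, n_neg={n_neg}")
    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # staircase: sweep thresholds over distinct scores, descending
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(
        points=points, auc=float(auc), n_pos=n_pos, n_neg=n_neg,
        items=items, scores=s, labels=y,
    )


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values: V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # one per positive item
    v01 = cmp.mean(axis=0)  # one per negative item
    return v10, v01, float(cmp.mean())


def delong_test(
    roc_a: ROCResult, roc_b: ROCResult, paired: bool = True
) -> tuple[float, float]:
    """DeLong's test comparing two AUCs; returns (z, two-sided p).

    paired=True requires the two ROCs to be computed over the identical
    item set (the usual two-methods-one-benchmark comparison); the
    covariance of placement values is then used. paired=False treats the
    samples as independent and sums the variances.
    """
    v10a, v01a, auc_a = _placements(roc_a.scores, roc_a.labels)
    v10b, v01b, auc_b = _placements(roc_b.scores, roc_b.labels)
    if paired:
        if roc_a.items != roc_b.items or not np.array_equal(roc_a.labels, roc_b.labels):
            raise ValueError("paired DeLong requires identical item sets and labels")
        m, n = len(v10a), len(v01a)
        s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2 over positives
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = v10a.var(ddof=1) / len(v10a) + v01a.var(ddof=1) / len(v01a) \
            + v10b.var(ddof=1) / len(v10b) + v01b.var(ddof=1) / len(v01b)
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "zero variance estimate with differing AUCs (constant placements)"
        )
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def delong_variance(roc_a: ROCResult, roc_b: ROCResult, paired: bool = True) -> float:
    """Variance of the AUC difference as estimated inside delong_test."""
    v10a, v01a, _ = _placements(roc_a.scores, roc_a.labels)
    v10b, v01b, _ = _placements(roc_b.scores, roc_b.labels)
    if paired:
        m, n = len(v10a), len(v01a)
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        return float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                     + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    return float(v10a.var(ddof=1) / len(v10a) + v01a.var(ddof=1) / len(v01a)
                 + v10b.var(ddof=1) / len(v10b) + v01b.var(ddof=1) / len(v01b))


def uniformity_cdf_distance(ranks: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov distance of scaled ranks from
    Uniform(0, 1), with the asymptotic two-sided p-value. Small ranks
    concentrated near 0 (expected genes highly ranked) give a large D."""
    res = stats.kstest(np.asarray(ranks, dtype=float), "uniform")
    return float(res.statistic), float(res.pvalue)


def benchmark_collection(
    signatures: Sequence[Signature],
    prior: PriorKnowledge,
    methods: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float]]]:
    """Pooled per-gene ROC per DEG method against prior knowledge.

    For every signature whose entity has an expected set, each gene
    contributes (|coefficient|, gene-in-expected-set) to its method's
    pool; one ROC/AUC per method, plus pairwise DeLong comparisons
    (unpaired: different methods may cover different signature pools).
    Returns (AUC table, {(method_a, method_b): (z, p)}).
    """
    if not prior.expected:
        raise GeosigError("prior knowledge is empty")
    pools: dict[str, tuple[dict, dict]] = {}
    for sig in signatures:
        if methods is not None and sig.method not in methods:
            continue
        expected = prior.expected.get(sig.entity_label)
        if expected is None:
            continue
        scores, labels = pools.setdefault(sig.method, ({}, {}))
        for gene, coef in sig.coefficients.items():
            item = (sig.signature_id, gene)
            scores[item] = abs(coef)
            labels[item] = int(gene in expected)
    if not pools:
        raise GeosigError("no signature matched the prior knowledge entities")
    rows, rocs = [], {}
    for method, (scores, labels) in sorted(pools.items()):
        r = roc(scores, labels)
        rocs[method] = r
        rows.append({"method": method, "auc": r.auc,
                     "n_pos": r.n_pos, "n_neg": r.n_neg})
    comparisons: dict[tuple[str, str], tuple[float, float]] = {}
    names = sorted(rocs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            paired = rocs[a].items == rocs[b].items
            comparisons[(a, b)] = delong_test(rocs[a], rocs[b], paired=paired)
    return pd.DataFrame(rows), comparisons
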