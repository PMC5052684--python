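"""Differential expression statistics: Characteristic Direction and baselines.

The Characteristic Direction treats differential expression as a
multivariate two-class problem: the per-gene coefficients are the
components of the unit normal of a regularized linear-discriminant
hyperplane separating control from treatment samples. Genes that carry
the joint expression change get large |coefficients| even when their
univariate statistics are modest.

Inputs are expected to be log-scale, normalized intensities (genes in
rows, samples in columns). Normalization itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateContrastError, InsufficientReplicatesError

import logging

logger = logging.getLogger(__name__)


@dataclass
class CDParams:
    """Tunables of the Characteristic Direction.

    gamma
        Shrinkage weight in [0, 1] blending the empirical within-class
        scatter with a scaled identity; 0 gives pure identity (the
        coefficients then reduce to the mean-difference direction),
        1 gives the raw (possibly ill-conditioned) scatter.
    subspace_frac
        Cumulative-variance fraction of the pooled-sample SVD retained
        before solving; caps the component count at n1+n2-1.
    top_n
        Genes kept per direction when cutting discrete up/down sets.
    """

    gamma: float = 0.5
    subspace_frac: float = 0.95
    top_n: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 < self.subspace_frac <= 1.0:
            raise ValueError("subspace_frac must lie in (0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be a positive integer")


def _as_matrix(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(g) for g in m.index]
    arr = np.asarray(m, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


def _check_pair(ctrl, trt) -> tuple[np.ndarray, np.ndarray, list[str]]:
    c, genes_c = _as_matrix(ctrl)
    t, genes_t = _as_matrix(trt)
    if c.shape[0] != t.shape[0]:
        raise ValueError("ctrl and trt must have the same gene rows")
    if isinstance(ctrl, pd.DataFrame) and isinstance(trt, pd.DataFrame):
        if list(ctrl.index) != list(trt.index):
            raise ValueError("ctrl and trt gene rows differ")
    return c, t, genes_c


def characteristic_direction(
    ctrl, trt, params: CDParams | None = None
) -> dict[str, float]:
    """Unit-norm characteristic-direction coefficients per gene.

    Positive coefficients mean higher expression in treatment. The
    computation runs in the span of the pooled, centered samples:

    1. delta = rowmean(trt) - rowmean(ctrl);
    2. SVD of the centered pooled matrix; keep the first k components
       reaching ``subspace_frac`` cumulative variance (k <= n1+n2-1);
    3. within-class (pooled) scatter in component space, shrunk as
       Sigma_gamma = gamma*Sigma + (1-gamma)*(tr Sigma / k)*I;
    4. solve Sigma_gamma v = projected delta;
    5. map back to gene space and L2-normalize.
    """
    params = params or CDParams()
    c, t, genes = _check_pair(ctrl, trt)
    n1, n2 = c.shape[1], t.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 samples per class, got n1={n1}, n2={n2}"
        )
    delta = t.mean(axis=1) - c.mean(axis=1)
    if np.allclose(delta, 0.0):
        raise DegenerateContrastError("class means are identical; no direction")

    pooled = np.concatenate([c, t], axis=1)  # genes x (n1+n2)
    centered = pooled - pooled.mean(axis=1, keepdims=True)
    # economy SVD: columns of U span the centered sample space
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    u, s = u[:, keep], s[keep]
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, params.subspace_frac - 1e-12) + 1)
    k = min(k, n1 + n2 - 1, len(s))
    basis = u[:, :k]  # genes x k

    # project samples and delta into component space
    pc = basis.T @ (c - c.mean(axis=1, keepdims=True))
    pt = basis.T @ (t - t.mean(axis=1, keepdims=True))
    scatter = (pc @ pc.T + pt @ pt.T) / (n1 + n2 - 2)
    target = np.trace(scatter) / k
    sigma = params.gamma * scatter + (1.0 - params.gamma) * target * np.eye(k)
    proj_delta = basis.T @ delta
    v = np.linalg.solve(sigma, proj_delta)
    b = basis @ v
    norm = np.linalg.norm(b)
    if norm == 0.0:
        raise DegenerateContrastError("direction vanished after projection")
    b /= norm
    # orient so that the direction agrees with the mean difference
    if float(b @ delta) < 0:
        b = -b
    return dict(zip(genes, b.tolist()))


def characteristic_direction_dense(ctrl, trt, gamma: float = 0.5) -> dict[str, float]:
    """Full gene-space solve of the shrunk-scatter system (no SVD subspace).

    Independent of :func:`characteristic_direction`'s projection shortcut;
    intended for small gene counts where the p x p system is tractable.
    """
    c, t, genes = _check_pair(ctrl, trt)
    n1, n2 = c.shape[1], t.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("need >= 2 samples per class")
    delta = t.mean(axis=1) - c.mean(axis=1)
    if np.allclose(delta, 0.0):
        raise DegenerateContrastError("class means are identical")
    cc = c - c.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    scatter = (cc @ cc.T + tc @ tc.T) / (n1 + n2 - 2)
    p = c.shape[0]
    target = np.trace(scatter) / p
    sigma = gamma * scatter + (1.0 - gamma) * target * np.eye(p)
    b = np.linalg.solve(sigma, delta)
    b /= np.linalg.norm(b)
    if float(b @ delta) < 0:
        b = -b
    return dict(zip(genes, b.tolist()))


def log_fold_change(ctrl, trt) -> dict[str, float]:
    """Per-gene mean(trt) - mean(ctrl); inputs must already be log-scale."""
    c, t, genes = _check_pair(ctrl, trt)
    return dict(zip(genes, (t.mean(axis=1) - c.mean(axis=1)).tolist()))


def welch_t(ctrl, trt) -> dict[str, float]:
    """Per-gene Welch t statistic, oriented so positive = higher in treatment.

    Genes with zero variance in both classes get statistic 0 (warned).
    """
    c, t, genes = _check_pair(ctrl, trt)
    n1, n2 = c.shape[1], t.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("need >= 2 samples per class")
    v1 = c.var(axis=1, ddof=1)
    v2 = t.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    diff = t.mean(axis=1) - c.mean(axis=1)
    zero = se == 0.0
    if zero.any():
        logger.warning("%d genes with zero variance in both classes; t set to 0",
                       int(zero.sum()))
    stat = np.zeros_like(diff)
    np.divide(diff, se, out=stat, where=~zero)
    return dict(zip(genes, stat.tolist()))


def cut_signature(
    coefficients: dict[str, float], top_n: int
) -> tuple[list[str], list[str]]:
    """Cut a coefficient vector into discrete (up, down) gene lists.

    up: the top_n largest strictly positive coefficients in descending
    order; down: the top_n most negative in ascending-value order.
    Ties break lexicographically on the gene symbol.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pos = sorted(
        ((g, v) for g, v in coefficients.items() if v > 0),
        key=lambda gv: (-gv[1], gv[0]),
    )
    neg = sorted(
        ((g, v) for g, v in coefficients.items() if v < 0),
        key=lambda gv: (gv[1], gv[0]),
    )
    return [g for g, _ in pos[:top_n]], [g for g, _ in neg[:top_n]]


DEG_METHODS = {
    "cd": lambda ctrl, trt, params: characteristic_direction(ctrl, trt, params),
    "fc": lambda ctrl, trt, params: log_fold_change(ctrl, trt),
    "t": lambda ctrl, trt, params: welch_t(ctrl, trt),
}


def compute_coefficients(ctrl, trt, method: str = "cd",
                         params: CDParams | None = None) -> dict[str, float]:
    """Dispatch over the registered DEG methods ('cd', 'fc', 't')."""
    if method not in DEG_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(DEG_METHODS)}")
    return DEG_METHODS[method](ctrl, trt, params)
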