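"""Batch-effect handling: date-derived batches, variance attribution and
surrogate-variable correction.

Microarray samples scanned on the same date are assumed to belong to the
same processing batch. Before calling differential expression the
expression matrix can be adjusted by estimating surrogate variables
(latent factors of the condition-residualized data) and regressing them
out, preserving the condition contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import CDParams, characteristic_direction, cut_signature
from .errors import DegenerateContrastError, UndefinedAttributionError
from .geo_io import Signature, Study, Submission

import logging

logger = logging.getLogger(__name__)


@dataclass
class BatchAssignment:
    """sample_id -> batch label, derived from scan dates."""

    labels: dict[str, str]
    coverage: float

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, lab in self.labels.items():
            out.setdefault(lab, []).append(sid)
        return out


@dataclass
class VarianceShares:
    """Fractions of expression variance attributed to batch, condition
    and residual; they sum to one."""

    share_batch: float
    share_condition: float
    share_residual: float

    def __post_init__(self) -> None:
        total = self.share_batch + self.share_condition + self.share_residual
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {total}, expected 1")


def batches_from_dates(study: Study) -> BatchAssignment:
    """One batch label per distinct scan date; samples without a date all
    fall into a single ``unknown`` batch (warned)."""
    labels: dict[str, str] = {}
    known = 0
    for s in study.samples:
        if s.scan_date is None:
            labels[s.sample_id] = "unknown"
        else:
            labels[s.sample_id] = s.scan_date.isoformat()
            known += 1
    n = len(study.samples)
    if known < n:
        logger.warning(
            "study %s: %d/%d samples lack scan dates; grouped as 'unknown'",
            study.study_id, n - known, n,
        )
    return BatchAssignment(labels=labels, coverage=known / n if n else 0.0)


def _one_way_r2(y: np.ndarray, groups: np.ndarray) -> float:
    """R^2 of a one-way group-mean fit of y."""
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0.0:
        return 0.0
    ssb = 0.0
    for g in np.unique(groups):
        mask = groups == g
        ssb += mask.sum() * (y[mask].mean() - grand) ** 2
    return float(ssb / sst)


def pvca_lite(
    expression,
    batch,
    condition,
    n_pcs: int | None = None,
    variance_target: float = 0.60,
) -> VarianceShares:
    """Attribute expression variance to batch vs condition via principal
    components.

    Takes the top principal components (by default those reaching 60%
    cumulative variance); for each PC score vector computes the R^2 of
    one-way fits on batch and on condition; the explained part
    max(R2_b, R2_c) is split between the two factors proportionally to
    their R^2 (shared variance split proportionally), the rest is
    residual. Per-PC attributions are averaged weighted by eigenvalue
    fraction and renormalized to sum to one.
    """
    x = np.asarray(
        expression.to_numpy() if isinstance(expression, pd.DataFrame) else expression,
        dtype=float,
    )
    batch = np.asarray(list(batch))
    condition = np.asarray(list(condition))
    if len(np.unique(batch)) < 2 and len(np.unique(condition)) < 2:
        raise UndefinedAttributionError(
            "need >= 2 batches or >= 2 conditions to attribute variance"
        )
    centered = x - x.mean(axis=1, keepdims=True)
    # PC scores over samples: right singular vectors of the centered matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0)
    s, vt = s[keep], vt[keep]
    var = s**2
    frac = var / var.sum()
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(frac), variance_target - 1e-12) + 1)
    n_pcs = min(n_pcs, len(s))
    w = frac[:n_pcs] / frac[:n_pcs].sum()
    shares = np.zeros(3)  # batch, condition, residual
    for i in range(n_pcs):
        y = vt[i]
        rb = _one_way_r2(y, batch)
        rc = _one_way_r2(y, condition)
        explained = max(rb, rc)
        if rb + rc > 0:
            sb = explained * rb / (rb + rc)
            sc = explained * rc / (rb + rc)
        else:
            sb = sc = 0.0
        shares += w[i] * np.array([sb, sc, 1.0 - explained])
    shares = shares / shares.sum()
    return VarianceShares(*shares.tolist())


def _condition_design(condition) -> np.ndarray:
    condition = np.asarray(list(condition))
    levels = np.unique(condition)
    cols = [np.ones(len(condition))]
    for lev in levels[1:]:
        cols.append((condition == lev).astype(float))
    return np.column_stack(cols)


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Remove the column space of design from every gene row of x."""
    q, _ = np.linalg.qr(design)
    return x - (x @ q) @ q.T


def estimate_surrogate_variables(
    expression,
    condition,
    n_sv: int | None = None,
    n_permutations: int = 20,
    percentile: float = 95.0,
    n_reweight: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Estimate orthonormal surrogate-variable columns (samples x n_sv).

    Procedure: (1) residualize each gene on the condition design;
    (2) when ``n_sv`` is not given, estimate it by comparing singular-value
    variance shares against a within-row permutation null (components kept
    while their observed share exceeds the permutation ``percentile``);
    (3) refine by iterative reweighting: per-gene association strength
    (squared correlation) with each surrogate scales the residual rows
    before the SVD is recomputed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(
        expression.to_numpy() if isinstance(expression, pd.DataFrame) else expression,
        dtype=float,
    )
    n_samples = x.shape[1]
    if n_samples < 4:
        raise ValueError("need >= 4 samples to estimate surrogate variables")
    design = _condition_design(condition)
    resid = _residualize(x, design)
    max_rank = min(resid.shape) - 1
    s = np.linalg.svd(resid, compute_uv=False)
    total = np.sum(s**2)
    shares = s**2 / total if total > 0 else s * 0

    if n_sv is None:
        # null: permute entries within each gene row of the residual
        # (breaking cross-sample structure while preserving per-gene
        # variance), re-residualize, and keep leading components whose
        # variance share beats the permutation percentile for that index
        null_shares = np.empty((n_permutations, len(s)))
        for b in range(n_permutations):
            perm = np.empty_like(resid)
            for i in range(resid.shape[0]):
                perm[i] = rng.permutation(resid[i])
            perm = _residualize(perm, design)
            sp = np.linalg.svd(perm, compute_uv=False)
            tot = np.sum(sp**2)
            null_shares[b] = sp**2 / tot if tot > 0 else 0.0
        cutoffs = np.percentile(null_shares, percentile, axis=0)
        n_sv = 0
        for i in range(len(s)):
            if shares[i] > cutoffs[i]:
                n_sv += 1
            else:
                break
    if n_sv > max_rank:
        logger.warning("n_sv=%d exceeds residual rank; reduced to %d", n_sv, max_rank)
        n_sv = max_rank
    if n_sv == 0:
        return np.empty((n_samples, 0))

    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:n_sv].T  # samples x n_sv
    centered = x - x.mean(axis=1, keepdims=True)
    for _ in range(n_reweight):
        # per-gene weight: strongest squared correlation of the gene's
        # condition residual with any current surrogate
        rc = resid - resid.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(rc, axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        sc = svs - svs.mean(axis=0, keepdims=True)
        sn = np.linalg.norm(sc, axis=0, keepdims=True)
        sn[sn == 0] = 1.0
        corr = (rc / denom) @ (sc / sn)  # genes x n_sv
        weights = (corr**2).max(axis=1)
        # surrogates are rebuilt from the weighted ORIGINAL matrix so they
        # can carry the condition-aligned part of a partially confounded
        # batch; the joint regression in the removal step then attributes
        # that shared variance to the surrogate, not the condition
        _, _, vt = np.linalg.svd(centered * weights[:, None], full_matrices=False)
        svs = vt[:n_sv].T
    return svs


def remove_surrogate_components(x: np.ndarray, condition, svs: np.ndarray) -> np.ndarray:
    """Regress expression on [condition design, SVs] and subtract the SV part,
    leaving the condition contrast intact."""
    if svs.size == 0:
        return x
    design = np.column_stack([_condition_design(condition), svs])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    sv_part = svs @ coef[-svs.shape[1]:]
    return x - sv_part.T


def correct_and_extract(
    study: Study,
    submission: Submission,
    params: CDParams | None = None,
    sva_seed: int = 0,
    signature_id: str | None = None,
    provenance: str = "manual",
    confidence: float | None = None,
) -> Signature:
    """Surrogate-variable correction followed by Characteristic Direction.

    Surrogates are estimated on the submission's samples only, regressed
    out of the expression matrix, and the CD coefficients are computed on
    the corrected control/treatment matrices.
    """
    params = params or CDParams()
    if study.expression is None:
        raise ValueError(f"study {study.study_id} has no expression matrix")
    ctrl_ids = sorted(submission.control_ids)
    trt_ids = sorted(submission.perturbation_ids)
    expr = study.expression[ctrl_ids + trt_ids]
    condition = ["control"] * len(ctrl_ids) + ["treatment"] * len(trt_ids)
    x = expr.to_numpy(dtype=float)
    n1 = len(ctrl_ids)
    if np.allclose(x[:, n1:].mean(axis=1), x[:, :n1].mean(axis=1)):
        raise DegenerateContrastError(
            f"study {study.study_id}: class means identical before correction"
        )
    if x.shape[1] >= 4:
        svs = estimate_surrogate_variables(x, condition, seed=sva_seed)
        x = remove_surrogate_components(x, condition, svs)
    corrected = pd.DataFrame(x, index=expr.index, columns=expr.columns)
    coeffs = characteristic_direction(
        corrected[ctrl_ids], corrected[trt_ids], params
    )
    up, down = cut_signature(coeffs, params.top_n)
    return Signature(
        signature_id=signature_id
        or f"{study.study_id}:{submission.entity_label}:cd+sva",
        study_id=study.study_id,
        control_ids=submission.control_ids,
        perturbation_ids=submission.perturbation_ids,
        signature_type=submission.signature_type,
        entity_label=submission.entity_label,
        coefficients=coeffs,
        up_genes=up,
        down_genes=down,
        method="cd+sva",
        provenance=provenance,
        confidence=confidence,
    )
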