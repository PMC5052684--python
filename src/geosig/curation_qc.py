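"""Sanitization of crowdsourced submissions.

Filters, applied in order: sample/study integrity, gene-symbol validity
(gene perturbations only), control/treatment swap detection and
correction, then removal of every submission from curators whose invalid
fraction exceeds 10% (strictly). The first failing filter decides a
submission's removal reason. Swapped submissions are corrected (groups
exchanged), not dropped, but count against their curator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geo_io import Study, Submission, Vocabulary

VALID = "valid"
CURATOR_INVALID_FRACTION = 0.10


@dataclass
class Verdict:
    status: str  # "valid" or "invalid:<reason>"
    swap: str = "ok"  # "ok" | "swapped" | "undecidable"

    @property
    def is_valid(self) -> bool:
        return self.status == VALID

    @property
    def counts_against_curator(self) -> bool:
        # invalid verdicts and swapped-as-submitted both count (pre-correction)
        return (not self.is_valid) or self.swap == "swapped"


@dataclass
class QCReport:
    """Per-submission verdicts (aligned to the input order), per-curator
    invalid fractions, removed curators, and before/after counts."""

    verdicts: list[Verdict]
    curator_invalid_fraction: dict[str, float]
    removed_curators: list[str]
    n_input: int
    n_surviving: int
    n_duplicates_collapsed: int = 0
    review_queue: list[int] = field(default_factory=list)  # indices with undecidable swaps

    def to_frame(self, submissions: Sequence[Submission]) -> pd.DataFrame:
        rows = []
        for i, (sub, v) in enumerate(zip(submissions, self.verdicts)):
            rows.append(
                {
                    "index": i,
                    "curator_id": sub.curator_id,
                    "study_id": sub.study_id,
                    "status": v.status,
                    "swap": v.swap,
                    "curator_removed": sub.curator_id in self.removed_curators,
                }
            )
        return pd.DataFrame(rows)


def check_integrity(
    submission: Submission, study_index: Mapping[str, set[str] | frozenset[str]]
) -> str:
    """Validate sample membership and group disjointness.

    Invalid when the study is unknown, any referenced sample is not in the
    study, the same sample sits in both groups, or either group is empty.
    """
    if submission.study_id not in study_index:
        return "invalid:unknown-study"
    if not submission.control_ids or not submission.perturbation_ids:
        return "invalid:empty-group"
    if submission.control_ids & submission.perturbation_ids:
        return "invalid:overlap"
    members = set(study_index[submission.study_id])
    if (submission.control_ids | submission.perturbation_ids) - members:
        return "invalid:membership"
    return VALID


def check_gene_symbol(submission: Submission, vocabulary: Vocabulary) -> str:
    """Gene-perturbation submissions must carry a valid (canonicalizable)
    gene symbol; other signature types always pass."""
    if submission.signature_type != "gene":
        return VALID
    if vocabulary.canonicalize(submission.entity_label) is None:
        return "invalid:gene-symbol"
    return VALID


def detect_swapped_groups(
    submission: Submission, study: Study, tau: float = 1.0
) -> str:
    """Decide whether control and perturbation groups were switched.

    Uses the perturbed gene's own expression: a knockdown/knockout whose
    target is up by more than ``tau`` log2 units in the nominal
    perturbation group (or an overexpression whose target is down) is
    flagged ``swapped``; a difference inside (-tau, tau) is
    ``undecidable`` (kept, queued for manual review).
    """
    if submission.signature_type != "gene":
        return "ok"
    direction = submission.perturbation_direction
    if direction not in ("knockdown", "knockout", "overexpression"):
        return "undecidable"
    if study.expression is None:
        return "undecidable"
    gene = None
    for g in study.expression.index:
        if str(g).lower() == submission.entity_label.lower():
            gene = g
            break
    if gene is None:
        return "undecidable"
    row = study.expression.loc[gene]
    ctrl = [s for s in submission.control_ids if s in row.index]
    trt = [s for s in submission.perturbation_ids if s in row.index]
    if not ctrl or not trt:
        return "undecidable"
    diff = float(row[trt].mean() - row[ctrl].mean())
    if abs(diff) < tau:
        return "undecidable"
    if direction in ("knockdown", "knockout"):
        return "swapped" if diff > 0 else "ok"
    return "swapped" if diff < 0 else "ok"


def apply_curator_filter(
    verdict_by_curator: Mapping[str, Sequence[bool]],
    threshold: float = CURATOR_INVALID_FRACTION,
) -> list[str]:
    """Curators with strictly more than ``threshold`` invalid submissions
    are removed entirely. Input: curator -> list of per-submission
    "counts as invalid" flags."""
    removed = []
    for curator, flags in verdict_by_curator.items():
        if not flags:
            continue
        frac = sum(bool(f) for f in flags) / len(flags)
        if frac > threshold:
            removed.append(curator)
    return sorted(removed)


def deduplicate(submissions: Sequence[Submission]) -> tuple[list[Submission], int]:
    """Collapse submissions with identical study + groups, keeping the
    earliest (input order is submission order)."""
    seen: set[tuple] = set()
    out = []
    for sub in submissions:
        key = sub.group_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(sub)
    return out, len(submissions) - len(out)


def sanitize(
    submissions: Sequence[Submission],
    study_index: Mapping[str, set[str] | frozenset[str]],
    vocabularies: Mapping[str, Vocabulary],
    studies: Mapping[str, Study] | None = None,
    tau: float = 1.0,
    curator_threshold: float = CURATOR_INVALID_FRACTION,
) -> tuple[list[Submission], QCReport]:
    """Run the full sanitization pipeline.

    ``study_index`` maps study_id -> sample-id set; ``studies`` (optional)
    provides expression matrices for swap detection. Returns the surviving
    submissions (swapped ones corrected) and a QCReport.
    """
    submissions, n_dups = deduplicate(submissions)
    gene_vocab = vocabularies.get("gene")
    verdicts: list[Verdict] = []
    for sub in submissions:
        status = check_integrity(sub, study_index)
        if status == VALID and gene_vocab is not None:
            status = check_gene_symbol(sub, gene_vocab)
        swap = "ok"
        if status == VALID and studies is not None and sub.study_id in studies:
            swap = detect_swapped_groups(sub, studies[sub.study_id], tau=tau)
        verdicts.append(Verdict(status=status, swap=swap))

    by_curator: dict[str, list[bool]] = {}
    for sub, v in zip(submissions, verdicts):
        by_curator.setdefault(sub.curator_id, []).append(v.counts_against_curator)
    removed_curators = apply_curator_filter(by_curator, threshold=curator_threshold)
    fractions = {
        c: sum(flags) / len(flags) for c, flags in by_curator.items() if flags
    }

    surviving: list[Submission] = []
    review_queue: list[int] = []
    for i, (sub, v) in enumerate(zip(submissions, verdicts)):
        if v.swap == "undecidable":
            review_queue.append(i)
        if not v.is_valid or sub.curator_id in removed_curators:
            continue
        surviving.append(sub.swapped() if v.swap == "swapped" else sub)

    report = QCReport(
        verdicts=verdicts,
        curator_invalid_fraction=fractions,
        removed_curators=removed_curators,
        n_input=len(submissions),
        n_surviving=len(surviving),
        n_duplicates_collapsed=n_dups,
        review_queue=review_queue,
    )
    return surviving, report
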