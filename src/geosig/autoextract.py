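"""Automatic signature extraction from a corpus of studies.

Pipeline: (1) keep studies whose predicted perturbation category has
probability strictly above 0.9; (2) score every sample's probability of
being a control from its metadata text; (3) cluster samples by Manhattan
distance on binary token vectors with DBSCAN (min_samples=2, so clusters
are connected components of the eps-neighborhood graph and isolated
samples are noise); (4) drop clusters whose member probabilities have
standard deviation above 0.2, call mean > 0.7 control groups and
mean < 0.3 treatment groups; (5) enumerate all control x treatment group
pairs within a study as candidate submissions; (6) label each candidate
by dictionary-tagging the study and sample text against the controlled
vocabulary of the predicted category; (7) batch-correct with surrogate
variables and compute Characteristic Direction coefficients. Each
resulting signature carries a confidence score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .batchfx import correct_and_extract
from .diffexp import CDParams
from .errors import DegenerateContrastError, GeosigError, InsufficientReplicatesError
from .geo_io import Sample, Study, Submission, Vocabulary

import logging

logger = logging.getLogger(__name__)


@dataclass
class AutoExtractConfig:
    """Thresholds of the automatic extraction pipeline.

    study_prob_threshold
        Minimum (strict) predicted category probability for a study to
        enter the pipeline.
    control_mean_threshold / treatment_mean_threshold
        A cluster whose mean control-probability is strictly above /
        below these becomes a control / treatment group.
    cluster_std_threshold
        Clusters with a larger (population) standard deviation of member
        probabilities are discarded as likely control/treatment mixtures.
    dbscan_eps
        Neighborhood radius in token-difference units (Manhattan distance
        between binary vectors counts differing tokens).
    dbscan_min_samples
        DBSCAN core-point threshold; at 2, clustering reduces to
        connected components over non-isolated points.
    """

    study_prob_threshold: float = 0.9
    control_mean_threshold: float = 0.7
    treatment_mean_threshold: float = 0.3
    cluster_std_threshold: float = 0.2
    dbscan_eps: float = 3.0
    dbscan_min_samples: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.treatment_mean_threshold < self.control_mean_threshold <= 1.0:
            raise ValueError(
                "need 0 <= treatment_mean_threshold < control_mean_threshold <= 1"
            )


def filter_studies(
    corpus: Sequence[Study],
    study_classifier,
    config: AutoExtractConfig | None = None,
    categories: Sequence[str] = ("gene", "disease", "drug"),
) -> list[tuple[Study, str, float]]:
    """Keep studies whose maximum perturbation-category probability is
    strictly above the threshold; returns (study, category, probability)."""
    config = config or AutoExtractConfig()
    out = []
    for study, probs in zip(corpus, study_classifier.predict_categories(corpus)):
        considered = {c: p for c, p in probs.items() if c in categories}
        if not considered:
            continue
        category = max(sorted(considered), key=lambda c: considered[c])
        p = considered[category]
        if p > config.study_prob_threshold:
            out.append((study, category, p))
    return out


def sample_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan (L1) distance between binary token vectors;
    equals the count of differing tokens."""
    v = np.asarray(vectors, dtype=float)
    return cdist(v, v, metric="cityblock")


def cluster_samples(
    distance_matrix: np.ndarray, eps: float, min_samples: int = 2
) -> np.ndarray:
    """DBSCAN on a precomputed distance matrix; noise points get -1."""
    model = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed")
    return model.fit_predict(np.asarray(distance_matrix, dtype=float))


def label_clusters(
    cluster_labels: np.ndarray,
    sample_probabilities: np.ndarray,
    config: AutoExtractConfig | None = None,
) -> tuple[list[list[int]], list[list[int]], list[list[int]]]:
    """Partition clusters into control groups, treatment groups, and
    discarded clusters (mixed or ambiguous), by the mean and population
    standard deviation of member control-probabilities. Noise samples
    (label -1) never form a group."""
    config = config or AutoExtractConfig()
    labels = np.asarray(cluster_labels)
    probs = np.asarray(sample_probabilities, dtype=float)
    controls, treatments, discarded = [], [], []
    for lab in sorted(set(labels.tolist()) - {-1}):
        idx = np.flatnonzero(labels == lab).tolist()
        p = probs[idx]
        if p.std() > config.cluster_std_threshold:
            discarded.append(idx)
        elif p.mean() > config.control_mean_threshold:
            controls.append(idx)
        elif p.mean() < config.treatment_mean_threshold:
            treatments.append(idx)
        else:
            discarded.append(idx)
    return controls, treatments, discarded


def enumerate_pairs(
    study: Study,
    control_groups: Sequence[Sequence[int]],
    treatment_groups: Sequence[Sequence[int]],
    signature_type: str,
    entity_label: str,
) -> list[Submission]:
    """Every control x treatment group pair within the study becomes a
    candidate auto submission."""
    ids = study.sample_ids
    out = []
    for cg in control_groups:
        for tg in treatment_groups:
            out.append(
                Submission(
                    curator_id="auto",
                    study_id=study.study_id,
                    control_ids=frozenset(ids[i] for i in cg),
                    perturbation_ids=frozenset(ids[i] for i in tg),
                    signature_type=signature_type,
                    entity_label=entity_label,
                )
            )
    return out


def tag_entities(
    text: str,
    vocabularies: Mapping[str, Vocabulary],
    category: str,
) -> tuple[dict[str, int], str, bool]:
    """Dictionary entity tagger: longest-match scan of the category's
    vocabulary (terms and synonyms) over the text.

    Returns (canonical term -> count, chosen label, flagged). The label
    is the most frequent matched term; ties break by earliest mention.
    With no match the label is ``unknown:<category>`` and flagged=True.
    """
    vocab = vocabularies.get(category)
    if vocab is None:
        return {}, f"unknown:{category}", True
    names = sorted(
        list(vocab.terms) + list(vocab.synonyms),
        key=len, reverse=True,  # longest match wins
    )
    if not names:
        return {}, f"unknown:{category}", True
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(n) for n in names) + r")\b", re.IGNORECASE
    )
    counts: dict[str, int] = {}
    first_pos: dict[str, int] = {}
    for m in pattern.finditer(text):
        canonical = vocab.canonicalize(m.group(0))
        if canonical is None:
            continue
        counts[canonical] = counts.get(canonical, 0) + 1
        first_pos.setdefault(canonical, m.start())
    if not counts:
        return {}, f"unknown:{category}", True
    label = min(counts, key=lambda t: (-counts[t], first_pos[t]))
    return counts, label, False


@dataclass
class AutoExtractAudit:
    """Per-study trace of the pipeline's decisions."""

    study_id: str
    category: str = ""
    study_probability: float = 0.0
    kept: bool = False
    n_clusters: int = 0
    n_control_groups: int = 0
    n_treatment_groups: int = 0
    n_candidates: int = 0
    n_signatures: int = 0
    label: str = ""
    notes: list[str] = field(default_factory=list)


def auto_extract(
    corpus: Sequence[Study],
    study_classifier,
    sample_classifier,
    vocabularies: Mapping[str, Vocabulary],
    config: AutoExtractConfig | None = None,
    cd_params: CDParams | None = None,
    seed: int = 0,
) -> tuple[list, list[AutoExtractAudit]]:
    """Run the full pipeline over a corpus; returns (signatures, audit).

    Confidence of a signature = study category probability x mean control
    probability of its control group x (1 - mean control probability of
    its treatment group), clipped to [0, 1].
    """
    config = config or AutoExtractConfig()
    kept = filter_studies(corpus, study_classifier, config)
    kept_ids = {s.study_id for s, _, _ in kept}
    audits = [
        AutoExtractAudit(study_id=s.study_id, kept=s.study_id in kept_ids)
        for s in corpus
    ]
    audit_by_id = {a.study_id: a for a in audits}
    signatures = []
    for study, category, study_prob in kept:
        audit = audit_by_id[study.study_id]
        audit.category = category
        audit.study_probability = study_prob
        samples = study.samples
        if len(samples) < 4:
            audit.notes.append("too few samples")
            continue
        probs = sample_classifier.prob_control(samples)
        vectors = sample_classifier.token_vectors(
            samples, fields=("title", "description", "characteristics", "source_name")
        )
        dist = sample_distance_matrix(vectors)
        labels = cluster_samples(dist, config.dbscan_eps, config.dbscan_min_samples)
        audit.n_clusters = len(set(labels.tolist()) - {-1})
        controls, treatments, _ = label_clusters(labels, probs, config)
        audit.n_control_groups = len(controls)
        audit.n_treatment_groups = len(treatments)
        text = " ".join(
            [study.text()] + [
                " ".join(s.text_fields().values()) for s in samples
            ]
        )
        _, entity, flagged = tag_entities(text, vocabularies, category)
        audit.label = entity
        if flagged:
            audit.notes.append("no vocabulary match")
        candidates = enumerate_pairs(study, controls, treatments, category, entity)
        audit.n_candidates = len(candidates)
        for k, sub in enumerate(candidates):
            ctrl_idx = [study.sample_ids.index(s) for s in sorted(sub.control_ids)]
            trt_idx = [study.sample_ids.index(s) for s in sorted(sub.perturbation_ids)]
            conf = study_prob * float(probs[ctrl_idx].mean()) * float(
                1.0 - probs[trt_idx].mean()
            )
            conf = float(np.clip(conf, 0.0, 1.0))
            try:
                sig = correct_and_extract(
                    study, sub, cd_params, sva_seed=seed,
                    signature_id=f"{study.study_id}:auto{k}",
                    provenance="auto", confidence=conf,
                )
            except (DegenerateContrastError, InsufficientReplicatesError) as exc:
                audit.notes.append(f"candidate {k}: {exc}")
                continue
            signatures.append(sig)
        audit.n_signatures = sum(
            1 for s in signatures if s.study_id == study.study_id
        )
    return signatures, audits
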