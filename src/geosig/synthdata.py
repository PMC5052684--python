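"""Synthetic GEO-like corpora with known ground truth.

Every downstream module is testable without network access: the
generator plants differentially expressed genes (log2-scale shifts on a
Gaussian noise background), scan-date batch structure (a rank-one
per-batch shift, optionally confounded with the condition), sample
titles drawn from small control/treatment grammars whose token
vocabularies statistically separate the two classes, and study text that
embeds category keywords and entity mentions. Truth records store the
planted DEGs, group memberships and batches.

All randomness flows from a single seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import PriorKnowledge
from .geo_io import (
    Sample,
    Study,
    Submission,
    Vocabulary,
    write_gmt,
    write_study,
)

# Small controlled vocabularies used by generated corpora and examples.
GENE_SYMBOLS = [
    "TP53", "STAT3", "MYC", "KRAS", "NRAS", "EGFR", "BRCA1", "BRCA2",
    "PTEN", "AKT1", "NOTCH1", "SOX2", "FOXP3", "GATA3", "CDKN2A",
    "ERBB2", "YY1", "PPARG", "IGF1", "MIR34A",
]
GENE_SYNONYMS = {"HER2": "ERBB2", "P53": "TP53"}

DISEASE_NAMES = [
    "breast cancer", "hepatocellular carcinoma", "hypercholesterolemia",
    "myelodysplastic syndrome", "endometrial cancer", "muscular dystrophy",
    "chronic myelogenous leukemia", "melanoma", "asthma", "type 2 diabetes",
]
DISEASE_SYNONYMS = {"cml": "chronic myelogenous leukemia"}

DRUG_NAMES = [
    "imatinib", "dexamethasone", "estradiol", "tamoxifen", "doxorubicin",
    "lapatinib", "azacitidine", "tretinoin", "sorafenib", "vemurafenib",
    "curcumin", "methylprednisolone",
]
DRUG_SYNONYMS = {"gleevec": "imatinib", "sti571": "imatinib"}

TISSUES = ["liver", "kidney", "lung", "breast", "muscle", "brain", "blood", "skin"]

CONTROL_WORDS = ["control", "untreated", "vehicle", "mock"]

CATEGORY_KEYWORDS = {
    "gene": ["knockdown", "shRNA", "overexpression", "perturbation", "transfection"],
    "disease": ["patients", "tumor", "diagnosis", "biopsy", "pathology"],
    "drug": ["compound", "treatment", "dose", "pharmacology", "inhibitor"],
    "other": ["atlas", "development", "timecourse", "baseline", "survey"],
}


def build_default_vocabularies() -> dict[str, Vocabulary]:
    return {
        "gene": Vocabulary("gene", frozenset(GENE_SYMBOLS), dict(GENE_SYNONYMS)),
        "disease": Vocabulary("disease", frozenset(DISEASE_NAMES), dict(DISEASE_SYNONYMS)),
        "drug": Vocabulary("drug", frozenset(DRUG_NAMES), dict(DRUG_SYNONYMS)),
    }


@dataclass
class SimConfig:
    """Study-generation conditions.

    Defaults emulate small mammalian microarray studies on the log2
    scale: ~1,000 genes, 3-6 replicates per group, planted two-fold
    shifts (effect_size 1.0) on a noise floor of sd 0.5 (so planted
    effects are two within-class standard deviations), and a rank-one
    scan-date batch shift of comparable size to the condition effect.
    batch_confound in [0, 1]: 0 gives a crossed (balanced) design, 1
    aligns batches fully with condition.
    """

    n_studies: int = 30
    samples_per_group: tuple[int, int] = (3, 6)
    n_genes: int = 1000
    n_planted_degs: int = 50
    effect_size: float = 1.0
    batch_effect_size: float = 0.5
    batch_confound: float = 0.0
    noise_sd: float = 0.5
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.4, "disease": 0.2, "drug": 0.2, "other": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_genes < 1 or self.n_planted_degs < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.batch_confound <= 1.0:
            raise ValueError("batch_confound must lie in [0, 1]")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")


@dataclass
class StudyTruth:
    """Ground truth for one generated study."""

    study_id: str
    category: str
    entity: str
    direction: str | None
    control_ids: list[str]
    treatment_ids: list[str]
    planted_up: list[str]
    planted_down: list[str]
    batches: dict[str, str]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _titles(category: str, entity: str, direction: str | None,
            ctrl_word: str, tissue: str, n_ctrl: int, n_trt: int
            ) -> tuple[list[str], list[str]]:
    if category == "disease":
        ctrl = [f"healthy {ctrl_word} {tissue} rep {i+1}" for i in range(n_ctrl)]
        trt = [f"{entity} patient biopsy {tissue} rep {i+1}" for i in range(n_trt)]
    elif category == "drug":
        ctrl = [f"{ctrl_word} dmso {tissue} rep {i+1}" for i in range(n_ctrl)]
        trt = [f"{entity} treated 10uM {tissue} rep {i+1}" for i in range(n_trt)]
    elif category == "gene":
        word = "knockdown" if direction in ("knockdown", "knockout") else "overexpression"
        ctrl = [f"{ctrl_word} scrambled {tissue} rep {i+1}" for i in range(n_ctrl)]
        trt = [
            f"sh{entity} {word} perturbation transfected {tissue} rep {i+1}"
            for i in range(n_trt)
        ]
    else:  # no perturbation: all samples look alike
        ctrl = [f"{tissue} specimen timepoint rep {i+1}" for i in range(n_ctrl)]
        trt = [f"{tissue} specimen timepoint rep {i+1+n_ctrl}" for i in range(n_trt)]
    return ctrl, trt


def _study_text(category: str, entity: str, rng: np.random.Generator
                ) -> tuple[str, str, str]:
    kw = CATEGORY_KEYWORDS[category]
    decoy = {
        "gene": rng.choice(GENE_SYMBOLS), "disease": rng.choice(DISEASE_NAMES),
        "drug": rng.choice(DRUG_NAMES), "other": "reference",
    }[category]
    if category == "other":
        title = f"Expression {kw[0]} of {rng.choice(TISSUES)} {kw[1]}"
        summary = (
            f"A {kw[2]} {kw[3]} profiling {kw[4]} of normal tissue without "
            f"any experimental intervention."
        )
    else:
        title = f"Expression profiling of {entity} {kw[0]} in {rng.choice(TISSUES)}"
        summary = (
            f"We examined the {kw[1]} response to {entity} using genome wide "
            f"expression profiling. Samples exposed to {entity} were compared "
            f"with matched controls to characterize the {kw[2]} effect; "
            f"{decoy} was profiled previously."
        )
    keywords = ", ".join(kw)
    return title, summary, keywords


def simulate_study(
    config: SimConfig,
    category: str,
    rng: np.random.Generator | None = None,
    study_index: int = 1,
) -> tuple[Study, StudyTruth]:
    """Generate one study of the given category with its truth record.

    Expression = per-gene baseline + planted DEG shifts on treatment
    samples + per-batch rank-one shifts + Gaussian noise, all on the log2
    scale. Sample titles follow category-specific grammars; study text
    embeds category keywords and (twice) the perturbed entity.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.samples_per_group
    n_ctrl = int(rng.integers(lo, hi + 1))
    n_trt = int(rng.integers(lo, hi + 1))
    n = n_ctrl + n_trt
    genes = _gene_names(config.n_genes)

    direction: str | None = None
    if category == "gene":
        entity = str(rng.choice(GENE_SYMBOLS))
        direction = str(rng.choice(["knockdown", "knockout", "overexpression"]))
        # the perturbed gene is measured: rename one row to the entity symbol
        genes[int(rng.integers(0, config.n_genes))] = entity
    elif category == "disease":
        entity = str(rng.choice(DISEASE_NAMES))
    elif category == "drug":
        entity = str(rng.choice(DRUG_NAMES))
    else:
        entity = ""

    baseline = rng.uniform(4.0, 12.0, size=config.n_genes)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))

    planted_up: list[str] = []
    planted_down: list[str] = []
    n_degs = min(config.n_planted_degs, config.n_genes)
    if category != "other" and n_degs > 0:
        idx = rng.choice(config.n_genes, size=n_degs, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_degs)
        if category == "gene":
            ei = genes.index(entity)
            if ei not in idx:
                idx[0] = ei
            pos = int(np.flatnonzero(idx == ei)[0])
            # target gene moves consistently with the stated direction,
            # clearly past the swap-detection threshold
            signs[pos] = -1.0 if direction in ("knockdown", "knockout") else 1.0
            shift = signs * config.effect_size
            shift[pos] *= 2.0
        else:
            shift = signs * config.effect_size
        x[idx, n_ctrl:] += shift[:, None]
        planted_up = sorted(genes[i] for i, s in zip(idx, signs) if s > 0)
        planted_down = sorted(genes[i] for i, s in zip(idx, signs) if s < 0)

    # scan-date batches: two dates, optionally confounded with condition
    dates = [_dt.date(2014, 3, 10), _dt.date(2014, 5, 22)]
    batch = np.zeros(n, dtype=int)
    for cls, (start, stop) in (("ctrl", (0, n_ctrl)), ("trt", (n_ctrl, n))):
        size = stop - start
        aligned = 1 if cls == "trt" else 0
        k = int(round(size * (1.0 + config.batch_confound) / 2.0))
        members = start + rng.permutation(size)
        batch[members[:k]] = aligned
        batch[members[k:]] = 1 - aligned
    if config.batch_effect_size > 0:
        batch_shift = rng.normal(0.0, config.batch_effect_size, size=config.n_genes)
        x[:, batch == 1] += batch_shift[:, None]

    study_id = f"SYN{study_index:04d}"
    sample_ids = [f"SMP{study_index:04d}{j:02d}" for j in range(1, n + 1)]
    tissue = str(rng.choice(TISSUES))
    ctrl_word = str(rng.choice(CONTROL_WORDS))
    ctrl_titles, trt_titles = _titles(
        category, entity, direction, ctrl_word, tissue, n_ctrl, n_trt
    )
    samples = []
    for j, sid in enumerate(sample_ids):
        samples.append(
            Sample(
                sample_id=sid,
                title=(ctrl_titles + trt_titles)[j],
                description=f"total RNA from {tissue}",
                characteristics=f"tissue: {tissue}",
                source_name=tissue,
                scan_date=dates[batch[j]],
            )
        )
    title, summary, keywords = _study_text(category, entity, rng)
    study = Study(
        study_id=study_id,
        title=title,
        summary=summary,
        keywords=keywords,
        organism=str(rng.choice(["human", "mouse", "rat"])),
        samples=samples,
        expression=pd.DataFrame(x, index=genes, columns=sample_ids),
    )
    truth = StudyTruth(
        study_id=study_id,
        category=category,
        entity=entity,
        direction=direction,
        control_ids=sample_ids[:n_ctrl],
        treatment_ids=sample_ids[n_ctrl:],
        planted_up=planted_up,
        planted_down=planted_down,
        batches={sid: dates[b].isoformat() for sid, b in zip(sample_ids, batch)},
    )
    return study, truth


def simulate_corpus(config: SimConfig) -> tuple[list[Study], dict[str, StudyTruth]]:
    """Generate ``config.n_studies`` studies with categories drawn from
    the configured mix; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    cats = sorted(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    studies, truths = [], {}
    for i in range(config.n_studies):
        category = str(rng.choice(cats, p=probs))
        study, truth = simulate_study(config, category, rng, study_index=i + 1)
        studies.append(study)
        truths[study.study_id] = truth
    return studies, truths


VIOLATION_TYPES = ("membership", "overlap", "bad_gene", "swapped")


def simulate_submissions(
    corpus: Sequence[Study],
    truths: Mapping[str, StudyTruth],
    rng: np.random.Generator | int = 0,
    n_good_curators: int = 8,
    violations: Sequence[tuple[str, str]] | None = None,
) -> tuple[list[Submission], list[tuple[int, str]]]:
    """One correct submission per perturbation study, distributed over
    good curators, plus planted violations.

    ``violations`` is a list of (curator_id, violation_type) pairs; each
    plants one corrupted submission for that curator against a randomly
    chosen compatible study. Returns (submissions, planted) where planted
    lists (submission index, violation type).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perturbation = [s for s in corpus if truths[s.study_id].category != "other"]
    curators = [f"curator{u:02d}" for u in range(1, n_good_curators + 1)]
    submissions: list[Submission] = []
    for i, study in enumerate(perturbation):
        t = truths[study.study_id]
        submissions.append(
            Submission(
                curator_id=curators[i % len(curators)],
                study_id=study.study_id,
                control_ids=frozenset(t.control_ids),
                perturbation_ids=frozenset(t.treatment_ids),
                signature_type=t.category,
                entity_label=t.entity,
                perturbation_direction=t.direction,
            )
        )
    planted: list[tuple[int, str]] = []
    for curator, vtype in violations or []:
        if vtype not in VIOLATION_TYPES:
            raise ValueError(f"unknown violation type {vtype!r}")
        pool = perturbation
        if vtype in ("bad_gene", "swapped"):
            pool = [s for s in perturbation if truths[s.study_id].category == "gene"]
        if not pool:
            raise ValueError(f"no compatible study for violation {vtype!r}")
        study = pool[int(rng.integers(0, len(pool)))]
        t = truths[study.study_id]
        ctrl = frozenset(t.control_ids)
        trt = frozenset(t.treatment_ids)
        entity = t.entity
        if vtype == "membership":
            trt = trt | {"SMPBOGUS01"}
        elif vtype == "overlap":
            trt = trt | {sorted(ctrl)[0]}
        elif vtype == "bad_gene":
            entity = "NOTAGENE"
            # also drop one replicate so the record is not a duplicate of
            # the correct submission for the same study
            if len(trt) > 2:
                trt = frozenset(sorted(trt)[:-1])
        elif vtype == "swapped":
            ctrl, trt = trt, ctrl
        submissions.append(
            Submission(
                curator_id=curator,
                study_id=study.study_id,
                control_ids=ctrl,
                perturbation_ids=trt,
                signature_type=t.category,
                entity_label=entity,
                perturbation_direction=t.direction,
            )
        )
        planted.append((len(submissions) - 1, vtype))
    return submissions, planted


def simulate_prior_knowledge(
    truths: Mapping[str, StudyTruth],
    dilution: float = 0.0,
    rng: np.random.Generator | int = 0,
    n_genes: int = 1000,
) -> PriorKnowledge:
    """Expected DEG sets per entity: the planted DEGs, with a ``dilution``
    fraction replaced by random decoy genes (1.0 = fully random sets)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if not 0.0 <= dilution <= 1.0:
        raise ValueError("dilution must lie in [0, 1]")
    universe = _gene_names(n_genes)
    expected: dict[str, frozenset[str]] = {}
    for t in truths.values():
        if t.category == "other" or not t.entity:
            continue
        genes = sorted(set(t.planted_up) | set(t.planted_down))
        if not genes:
            continue
        n_swap = int(round(dilution * len(genes)))
        if n_swap:
            keep = list(rng.choice(genes, size=len(genes) - n_swap, replace=False))
            decoys = [g for g in universe if g not in genes]
            add = list(rng.choice(decoys, size=n_swap, replace=False))
            genes = sorted(keep + add)
        existing = expected.get(t.entity, frozenset())
        expected[t.entity] = existing | frozenset(genes)
    return PriorKnowledge(kind="planted", expected=expected)


def write_corpus(
    studies: Sequence[Study],
    truths: Mapping[str, StudyTruth],
    out_dir: str | Path,
    dialect: str = "series_matrix",
) -> None:
    """Write per-study files plus a truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"series_matrix": ".txt", "soft_simplified": ".soft", "tsv_bundle": ""}[dialect]
    for study in studies:
        write_study(study, out / f"{study.study_id}{suffix}", dialect)
    payload = {
        sid: {
            "category": t.category,
            "entity": t.entity,
            "direction": t.direction,
            "control_ids": t.control_ids,
            "treatment_ids": t.treatment_ids,
            "planted_up": t.planted_up,
            "planted_down": t.planted_down,
            "batches": t.batches,
        }
        for sid, t in truths.items()
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
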