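# geosig

A toolkit for extracting, quality-controlling and comparing **gene
expression signatures** from GEO-style perturbation studies — the kind of
curated contrast a biologist defines by picking control and perturbation
samples (GSMs) inside a series (GSE) and asking which genes move.

It is aimed at computational biologists who curate or mine public
expression repositories and need, in one place:

* **Differential expression by the Characteristic Direction (CD)**: the
  per-gene coefficients are the components of the unit normal **b** of a
  regularized linear-discriminant hyperplane separating the two sample
  classes. With class mean difference δ and within-class scatter Σ̂
  (estimated in the span of the pooled samples), the toolkit solves

  Σ<sub>γ</sub> **b** ∝ δ,  Σ<sub>γ</sub> = γ Σ̂ + (1−γ)(tr Σ̂ / k) I,  ‖**b**‖₂ = 1

  so genes that carry the *joint* expression change get large
  coefficients even when their univariate statistics are modest. Log
  fold change and Welch's t are included as univariate baselines.
* **Batch effects**: scan dates define processing batches; a PVCA-style
  decomposition attributes expression variance to batch vs condition,
  and an SVA-style procedure estimates surrogate variables from the
  condition-residualized matrix and regresses them out before CD
  (method tag `cd+sva`).
* **Sanitization of crowdsourced submissions**: sample/series integrity,
  HGNC-style gene symbol validation, detection and correction of swapped
  control/treatment groups, and removal of all submissions from curators
  whose invalid fraction exceeds 10% (strictly).
* **Signed Jaccard similarity** between signatures abstracted to up/down
  gene sets:

  sj(S<sub>i</sub>, S<sub>j</sub>) = ½ [ J(up<sub>i</sub>, up<sub>j</sub>) + J(dn<sub>i</sub>, dn<sub>j</sub>) − J(up<sub>i</sub>, dn<sub>j</sub>) − J(dn<sub>i</sub>, up<sub>j</sub>) ]

  with range [−1, 1]: 1 for identical signatures, −1 for signatures of
  reverse effect, 0 for unrelated ones. All-pairs adjacency, ranked
  queries, hierarchical cluster ordering, and Tanimoto pairing of drug
  fingerprints (>0.9) for chemical-similarity benchmarks.
* **Benchmarking against prior knowledge** (GMT gene sets): scaled
  ranks, ROC curves whose AUC equals the Mann–Whitney probability,
  DeLong's test between ROC curves, and a Kolmogorov–Smirnov distance of
  scaled ranks from uniformity.
* **Metadata text classifiers**: study categorization (gene / disease /
  drug perturbation) from TF-IDF of Porter-stemmed unigrams+bigrams with
  truncated SVD, and control-vs-treatment sample labeling with a bagging
  of 20 Bernoulli naive Bayes models calibrated by isotonic regression.
* **Automatic signature extraction**: classify studies (keep category
  probability > 0.9), score samples, cluster them by Manhattan distance
  on binary token vectors with DBSCAN (min_samples=2), call clusters
  with mean control-probability > 0.7 controls and < 0.3 treatments
  (discarding mixtures with std > 0.2), enumerate control×treatment
  pairs, tag the perturbed entity from the text, and extract `cd+sva`
  signatures, each with a confidence score.
* **A synthetic-data generator** (`geosig.synthdata`) that emulates all
  of the above with known ground truth — planted DEGs, scan-date batch
  structure, and token grammars separating control from treatment
  titles — so every component is testable offline.

## Worked example

```bash
python examples/01_extract_signature.py
```

```
study SYN0001: methylprednisolone perturbation, 5 control vs 5 treated samples
top up-regulated:   G00047, G00368, G00800, G00039, G00555
top down-regulated: G00147, G00190, G00572, G00596, G00408
mean scaled rank of the 50 planted DEGs: 0.037
```

The study has 50 genes planted with two-fold shifts on a noise floor of
half that size; a mean scaled rank of 0.037 means CD places the true
DEGs, on average, inside the top 4% of the 1,000-gene ranking (0.5 would
be chance). `examples/03_batch_correction.py` shows the batch machinery
on a study whose batches are partially confounded with the condition:

```
variance shares: batch 64.1%, condition 29.8%, residual 6.0%
planted-DEG AUC without correction: 0.915
planted-DEG AUC with SVA correction: 0.943
```

and `examples/06_auto_extract.py` runs the full automatic pipeline on a
30-study corpus, recovering the planted control/treatment designs with
precision 1.00 and recall 0.84. The other examples cover similarity
queries, submission sanitization and the text classifiers.

A thin CLI mirrors the library:
`geosig simulate | extract | sanitize | similarity | benchmark | train |
autoextract` (see `geosig --help`); thresholds come from `--config`
(YAML/JSON) and all randomness from `--seed`.

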