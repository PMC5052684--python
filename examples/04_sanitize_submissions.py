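"""Sanitize a pool of crowdsourced submissions.

Plants integrity violations, an invalid gene symbol, and a swapped
control/treatment pair across two unreliable curators, then runs the
filter pipeline: invalid submissions are removed, swapped ones are
corrected, and curators above the strict 10% invalid threshold lose all
their submissions.
"""

from geosig.curation_qc import sanitize
from geosig.synthdata import (
    SimConfig,
    build_default_vocabularies,
    simulate_corpus,
    simulate_submissions,
)

cfg = SimConfig(n_studies=40, n_genes=30, n_planted_degs=10,
                category_mix={"gene": 0.6, "disease": 0.2, "drug": 0.2,
                              "other": 0.0}, seed=17)
studies, truths = simulate_corpus(cfg)
violations = [("badA", "membership"), ("badA", "overlap"),
              ("badB", "bad_gene"), ("badB", "swapped")]
submissions, planted = simulate_submissions(studies, truths, rng=7,
                                            violations=violations)
print(f"{len(submissions)} submissions, {len(planted)} planted violations")

index = {s.study_id: set(s.sample_ids) for s in studies}
surviving, report = sanitize(submissions, index, build_default_vocabularies(),
                             {s.study_id: s for s in studies})
print(f"surviving: {report.n_surviving}/{report.n_input}")
print("removed curators:", report.removed_curators)
for curator, frac in sorted(report.curator_invalid_fraction.items()):
    if frac > 0:
        print(f"  {curator}: {frac:.0%} invalid")
print("verdicts for the planted entries:")
for idx, vtype in planted:
    v = report.verdicts[idx]
    print(f"  planted {vtype:10s} -> status={v.status}, swap={v.swap}")
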