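"""Extract a differential expression signature from one study.

Simulates a small drug-perturbation study (planted two-fold shifts on a
log2 noise floor), computes Characteristic Direction coefficients, and
cuts them into discrete up/down gene sets.
"""

import numpy as np

from geosig.benchmark import scaled_ranks
from geosig.diffexp import characteristic_direction, cut_signature
from geosig.synthdata import SimConfig, simulate_study

cfg = SimConfig(n_studies=1, samples_per_group=(5, 5), n_genes=1000,
                n_planted_degs=50, batch_effect_size=0.0, seed=7)
study, truth = simulate_study(cfg, "drug", np.random.default_rng(7))
print(f"study {study.study_id}: {truth.entity} perturbation, "
      f"{len(truth.control_ids)} control vs {len(truth.treatment_ids)} treated samples")

coeffs = characteristic_direction(
    study.expression[truth.control_ids], study.expression[truth.treatment_ids]
)
up, down = cut_signature(coeffs, top_n=10)
print("top up-regulated:  ", ", ".join(up[:5]))
print("top down-regulated:", ", ".join(down[:5]))

planted = set(truth.planted_up) | set(truth.planted_down)
ranks, _ = scaled_ranks(coeffs, planted)
print(f"mean scaled rank of the {len(planted)} planted DEGs: {np.mean(ranks):.3f}")
print("(values near 0 mean the method ranks the true DEGs at the top; "
      "0.5 would be chance)")
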