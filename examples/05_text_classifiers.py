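"""Train the two metadata classifiers on a synthetic corpus.

Study level: TF-IDF (unigram+bigram stems) of title/summary/keywords,
truncated SVD, gradient boosting -> perturbation category.
Sample level: binary token vectors of sample titles, bagging of 20
Bernoulli naive Bayes models, isotonic calibration -> probability that a
sample is a control.
"""

from geosig.synthdata import SimConfig, simulate_corpus
from geosig.textclf import SampleControlModel, StudyCategoryModel

studies, truth = simulate_corpus(SimConfig(n_studies=80, n_genes=50, seed=11))
labels = [truth[s.study_id].category for s in studies]
study_clf = StudyCategoryModel(model="gbm", seed=0).fit(studies, labels)
probs = study_clf.predict_categories(studies[:3])
for s, p in zip(studies[:3], probs):
    best = max(p, key=p.get)
    print(f"{s.study_id}: predicted {best} (p={p[best]:.2f}), "
          f"truth {truth[s.study_id].category}")

samples, is_ctrl = [], []
for s in studies:
    t = truth[s.study_id]
    if t.category == "other":
        continue
    for smp in s.samples:
        samples.append(smp)
        is_ctrl.append(int(smp.sample_id in t.control_ids))
sample_clf = SampleControlModel(seed=0).fit(samples, is_ctrl)
m = sample_clf.metrics
print(f"\nsample classifier 10-fold CV: AUROC={m.auroc:.3f} AUPRC={m.auprc:.3f} "
      f"MCC={m.mcc:.3f} F1={m.f1:.3f}")
for smp, p in zip(samples[:4], sample_clf.prob_control(samples[:4])):
    print(f"  '{smp.title}' -> P(control) = {p:.2f}")
print("probabilities near 1 mark control samples, near 0 treated samples")
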