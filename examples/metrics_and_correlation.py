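"""Evaluation utilities: metrics from a confusion table, AUC comparison,
and the correlation structure of probabilistic features.

The metric block reproduces a hand-checkable confusion table; the correlation
block shows that probabilistic features built from related encodings cluster
together.
"""

import numpy as np

from mc4pred import compare_auc_ttest, compute_metrics, correlation_analysis
import pandas as pd

# metrics on a hand-computable confusion table: TP=8, FN=4, TN=6, FP=2
labels = [1] * 12 + [0] * 8
preds = [1] * 8 + [0] * 4 + [0] * 6 + [1] * 2
rep = compute_metrics(labels, preds)
print(f"SN={rep.SN:.4f}  SP={rep.SP:.4f}  ACC={rep.ACC:.4f}  MCC={rep.MCC:.4f}")
print("(expected: SN=0.6667, SP=0.7500, ACC=0.7000, MCC=0.4082)\n")

# two-tailed t-test on per-split AUCs of two hypothetical methods
rng = np.random.default_rng(0)
auc_strong = 0.87 + rng.normal(0, 0.005, size=10)
auc_weak = 0.82 + rng.normal(0, 0.005, size=10)
p = compare_auc_ttest(auc_strong, auc_weak)
print(f"AUC {auc_strong.mean():.3f} vs {auc_weak.mean():.3f} over 10 splits: p = {p:.2e}")
print("(p < 0.05 means the difference in split-level AUCs is significant)\n")

# correlation clustering of synthetic probabilistic-feature columns
shared_a, shared_b = rng.random(500), rng.random(500)
frame = pd.DataFrame({
    "Kmer:RF": shared_a, "Kmer:SVM": shared_a + rng.normal(0, 0.1, 500),
    "BPF:RF": shared_b, "BPF:SVM": shared_b + rng.normal(0, 0.1, 500),
})
result = correlation_analysis(frame)
print("Pearson correlations:")
print(result.matrix.round(2).to_string())
print(f"two-cluster cut memberships: {dict(zip(frame.columns, result.cluster_labels))}")
print("(columns sharing an information source fall in the same cluster)")
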