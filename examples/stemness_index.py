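"""Train a one-class stemness model and score a cohort with mRNAsi.

Synthetic stem-cell profiles are displaced (relative to a reference
origin) along a set of stemness genes; the one-class logistic regression
learns positive weights on those genes, and mRNAsi ranks query samples
by their Spearman agreement with the learned weights.
"""

import numpy as np
import pandas as pd

from margin_profiler import signatures
from margin_profiler.io_core import ExpressionMatrix

rng = np.random.default_rng(0)
genes = [f"g{i}" for i in range(100)]
stem_genes = genes[:15]

# stem training profiles: +1 displacement on stemness genes, noise elsewhere
train = pd.DataFrame(rng.normal(0, 0.2, size=(100, 10)), index=genes)
train.loc[stem_genes] += 1.0
model = signatures.train_oclr(train, lam=1.0)
print(f"OCLR converged after {model.iterations} iterations: {model.converged}")
top = model.weights.nlargest(5).index.tolist()
print(f"top-weight genes (expect stemness genes): {top}")

# query cohort: samples with graded stemness-gene expression
boosts = np.linspace(0, 3, 12)
query = pd.DataFrame(rng.uniform(0, 4, size=(100, 12)), index=genes,
                     columns=[f"p{j}" for j in range(12)])
for j, boost in enumerate(boosts):
    query.loc[stem_genes, f"p{j}"] += boost
scores = signatures.mrnasi(model, ExpressionMatrix(query, "log2_tpm_plus1"))
print("\nmRNAsi per sample (stemness planted in increasing order p0 ... p11):")
print(scores["mrnasi"].round(3).to_string())
from scipy.stats import spearmanr

rho = spearmanr(boosts, scores["mrnasi"]).statistic
print(f"\nSpearman(planted stemness, mRNAsi) = {rho:.2f}")
print("The index spans [0, 1] over the cohort and tracks the planted gradient;")
print("residual noise in the non-stemness genes adds sample-level jitter.")
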