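"""End-to-end GA-MLR pipeline on synthetic descriptor data.

Generates an 18-compound descriptor matrix with near-duplicate columns
and a planted two-descriptor linear response at 10% noise, prunes the
matrix, selects a descriptor subset by genetic algorithm, and validates
the model with the full metric suite plus applicability-domain
assessment.
"""

import numpy as np

import bioqsrr as b

SEED = 1

# 18 compounds x 30 descriptors, 3 near-duplicate columns for the pruner
X = b.generate_descriptors(18, 30, n_redundant=3, seed=SEED)
clean = b.generate_response(X, support_size=2, noise_sd=0.0, seed=SEED)
noise = 0.1 * float(np.std(clean.signal, ddof=1))
data = b.generate_response(X, support_size=2, noise_sd=noise, seed=SEED)
print(f"planted support: {data.true_support}, "
      f"coefficients {dict((k, round(v, 3)) for k, v in data.true_coefficients.items())}")

pruned, report = b.prune_descriptors(X)
print(f"pruning: {X.shape[1]} -> {pruned.shape[1]} descriptors "
      f"({len(report.removed_correlated)} correlated pairs dropped)")

config = b.GAConfig(seed=SEED)  # population 10, 20% mutation, 500 generations
chromosome, model, trace = b.ga_select(pruned, data.y, config)
picked = [pruned.descriptor_names[i] for i in chromosome.selected_indices]
print(f"GA-selected subset: {picked}  (best Q2_LOO fitness {trace[-1]:.4f})")

train, ext = b.split_train_validation(data.y, n_tr=12, method="ranked")
Xs = pruned.frame[picked]
report, fitted = b.validate_split(
    Xs.iloc[train], data.y[train], Xs.iloc[ext], data.y[ext]
)
print("\nvalidation metrics (training n=12, external n=6):")
for k, v in report.metrics.items():
    print(f"  {k:9s} = {v:7.4f}")
print(f"acceptable (R2 > 0.6 and R2_EXT > 0.5): {report.acceptable['overall']}")

domain = b.williams_assessment(
    fitted, Xs.iloc[train], data.y[train], Xs.iloc[ext], data.y[ext]
)
n_in = int(domain.in_domain.sum())
print(f"\napplicability domain: h* = {domain.h_star:.3f}, "
      f"{n_in}/{len(domain.in_domain)} compounds in-domain")
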