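# bioqsrr

QSRR retention modelling for biomimetic chromatography.

Biomimetic HPLC phases — C18 reversed phase, immobilised artificial
membrane (IAM) and immobilised human serum albumin (HSA) — turn a fast
gradient run into physicochemical profiling: lipophilicity (CHI_C18),
phospholipid affinity (CHI_IAM) and plasma-protein binding
(LogK_HSA / %HSA). This package implements the analysis layer that sits
on top of such measurements, developed around an 18-compound
organophosphate pesticide dataset that ships with the package:

- **Index transforms** — least-squares calibration of gradient retention
  time against reference standards, and the logistic link between the
  two albumin-binding scales, `LogK_HSA = log10(%HSA / (101 − %HSA))`.
- **Descriptor pruning** — removal of constant, nearly constant and
  highly correlated (|r| ≥ 0.95) descriptor columns, with full
  accounting, plus auto-scaling.
- **GA-MLR subset selection** — a genetic algorithm over binary
  descriptor-inclusion chromosomes (population 10, 20% per-gene
  mutation, 500 generations, elitism) scoring candidate ordinary
  least-squares models by leave-one-out Q².
- **OECD-style validation** — R², RMSE_TR, Q²_LOO, RMSE_LOO, R²_EXT,
  RMSE_P and Lin's concordance CCC_EXT on a systematic 12/6
  train/validation split; Tropsha acceptability flags
  (R² > 0.6, R²_EXT > 0.5); Williams-plot applicability domain with
  critical leverage h\* = 3p/(n − 1) and the ±3σ residual rule.
- **Exploration** — endpoint correlation matrices, Ward clustering on
  auto-scaled indices with low/medium/high bioaccumulation group
  naming, heat-map export.
- **Synthetic data** — seeded generators for descriptor matrices with
  correlated blocks and near-duplicate columns, planted linear
  responses, and realistic endpoint tables, so the whole pipeline is
  testable without commercial descriptor software.

## Worked example

`examples/ga_qsrr_pipeline.py` generates an 18-compound descriptor
matrix with a planted two-descriptor signal at 10% noise and runs the
full pipeline:

```
planted support: ['D13', 'D14'], coefficients {'D13': 1.179, 'D14': -0.925}
pruning: 30 -> 27 descriptors (3 correlated pairs dropped)
GA-selected subset: ['D13', 'D14']  (best Q2_LOO fitness 0.9964)

validation metrics (training n=12, external n=6):
  r2_tr     =  0.9979
  rmse_tr   =  0.0660
  q2_loo    =  0.9956
  rmse_loo  =  0.0949
  r2_ext    =  0.9958
  rmse_p    =  0.1021
  ccc_ext   =  0.9980
acceptable (R2 > 0.6 and R2_EXT > 0.5): True

applicability domain: h* = 0.545, 17/18 compounds in-domain
```

The GA recovers exactly the two planted descriptors; the model fits the
training set (R² ≈ 1), survives leave-one-out cross-validation
(Q²_LOO close to R², so no overfit), predicts the held-out six
compounds (R²_EXT, CCC_EXT) and nearly all compounds fall inside the
leverage/residual applicability domain. `examples/index_transforms.py`
and `examples/explore_measured_table.py` demonstrate calibration plus
the %HSA ↔ LogK_HSA transforms, and the correlation/clustering view of
the packaged measured table (which separates weakly accumulating
compounds such as dichlorvos and naled from the lipophilic, strongly
protein-bound majority).

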