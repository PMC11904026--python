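# lofcast

Dual pathogenicity–severity classification of missense variants in the
thyroid-hormone transporter **MCT8** (encoded by the X-linked *SLC16A2*
gene). Loss-of-function MCT8 variants cause a rare, treatable
neurodevelopmental and metabolic disorder in males; predicting not only
*whether* a variant is pathogenic but *how severe* its loss of function
is directly informs prognosis and trial stratification.

`lofcast` implements the full modelling stack as a tested library with a
thin CLI:

* **Evolutionary index** — a variational autoencoder (numpy-only,
  fully seeded) trained on the phylogeny-reweighted protein family
  alignment. The index of a variant is the ensemble-mean difference in
  approximate sequence log-probability (ELBO) between wild type and
  mutant: positive = evolution disfavours the substitution.
* **Feature engineering** — AAindex2 substitution-matrix scores,
  per-column conservation scores, membrane-topology one-hots
  (TMD/ICL/ECL), and structural features on wild-type models with a
  docked T4 substrate: Shrake–Rupley solvent-accessible surface area,
  ligand/membrane interface areas, substrate distances, and ad-hoc
  geometry measurements. External predictions (FoldX/MAESTRO ddG, MD
  flexibility, server conservation grades) are *ingested*, never
  recomputed.
* **Functional labels** — residual T3/T4 transport (% of wild type)
  from cell-based assays. Pathogenic ⇔ activity < 50%;
  moderate/severe ⇔ activity < 10%; plus the clinical LoF classes with
  assay-specific thresholds (COS-1, JEG-3, patient fibroblasts).
* **The cascade** — stage 1 (benign vs pathogenic): ridge logistic
  regression, C = 1, on 9 canonical features; stage 2 (mild vs
  moderate/severe, applied to predicted-pathogenic variants):
  elastic-net logistic regression, C = 10, l1_ratio = 0.4, on 22
  canonical features. Standardization and recursive feature elimination
  are refit inside every cross-validation fold.
* **Mutational landscape** — enumerate all 19 substitutions per
  position over a region, predict each with the cascade, and export a
  long-format CSV or heat map with per-position tolerability.
* **Synthetic data** — generators for alignments with planted
  conservation, feature tables with a known activity-generating model,
  and toy structures with analytic geometry, so every stage is testable
  without downloads.

## Worked example

Train and cross-validate the cascade on the default synthetic scenario
(480 variants × 134 features, of which 9 drive pathogenicity and 22
drive severity):

```python
from lofcast.synthetic import TableScenario, generate_feature_table
from lofcast import CascadeClassifier

table, functional, truth = generate_feature_table(TableScenario())
activity = functional.set_index("variant")["relative_activity"]

model = CascadeClassifier(table, activity)
results = model.fit(seed=0)

print(model.crossvalidate_stage1(k=10, seed=0).summary())
```

```
pathogenicity 10-fold CV (stratified, seed 0)
------------------------------------------------------
  accuracy: 0.908 +/- 0.043
        f1: 0.911 +/- 0.041
       auc: 0.975 +/- 0.022
     auprc: 0.979 +/- 0.016
```

Accuracy/AUC here measure recovery of the generator's planted labels;
the ±-values are standard deviations across the ten folds. Prediction
is a pure function of the archived model and a feature row:

```python
pred = results.predict(table)
print(pred.head(3))
```

```
              label severity  probability
variant
Q237R    pathogenic     mild     1.000000
I393F        benign              0.934253
K164C    pathogenic     mild     0.999848
```

Each variant is either benign (no severity) or pathogenic with a
severity call; `probability` is the predicted-class probability of the
deciding stage. Over this batch the cascade partitions the 480 variants
into 234 benign, 119 mild and 127 moderate/severe.

The same run from the shell:

```bash
lofcast train --synthetic --seed 0 --out run/
lofcast predict --model run/model.json --features features.csv --out pred.csv
lofcast landscape --model run/model.json --features features.csv \
    --sequence ref.fasta --region 161:192 --out landscape.csv
```

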