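# nrcascade

Two-level support-vector-machine prediction of **nuclear receptors (NRs)**
and their subfamilies from protein sequence alone.

Nuclear receptors are ligand-inducible transcription factors organised
into eight subfamilies (NR1–NR8 in the NucleaRDB scheme).  Annotating a
new protein therefore asks two questions in sequence: *is it a nuclear
receptor at all?* and, if so, *which subfamily does it belong to?*
`nrcascade` answers both with a cascade of RBF-kernel SVMs over simple
frequency encodings of the primary sequence — no alignments, domain
models or structure required.

## Method

**Encoders.**  A sequence `P = R₁R₂…R_L` is mapped to a fixed-length
frequency vector by any of three encoders, used alone or concatenated:

* **AAC** (20-d) — amino-acid composition, `fᵢ = nᵢ/L` for each residue
  type.
* **CTF** (343-d) — conjoint triad feature.  The 20 amino acids are
  reduced to seven classes by side-chain dipole and volume
  ({AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C}); a width-3 window
  slides over the reduced sequence and each of the 7³ = 343 ordered
  triad types is counted, `fᵢ = nᵢ/(L−2)`.
* **CGR** (24-d) — chaos game representation.  Residues are grouped
  into twelve classes, one per vertex of a regular 12-gon with
  `V_k = (cos((k−1)π/6), sin((k−1)π/6))`; starting from the centre, each
  residue moves the current point to the midpoint between it and its
  class vertex, and the fraction of trajectory points `D_k = L_k/N`
  falling in each of 24 equal angular sectors is the feature.

The seven feature sets are `aac` (20), `cgr` (24), `ctf` (343),
`aac+cgr` (44), `aac+ctf` (363), `ctf+cgr` (367) and `aac+cgr+ctf` (387).

**Cascade.**  Level 1 is a binary RBF-SVM (NR vs non-NR); only sequences
predicted NR reach level 2, an eight-class one-vs-one RBF-SVM assigning
NR1..NR8.  Tuned `(γ, C)` defaults per feature set ship with the package
and an exhaustive cross-validated grid search is built in.

**Evaluation.**  Stratified 10-fold cross-validation and the jackknife
(leave-one-out) test; sensitivity, specificity, accuracy and Matthews
correlation from the confusion table, per-class one-vs-rest counts and
overall metrics for the subfamily level, ROC curves and AUC.

**Feature significance.**  Per-feature two-sided Wilcoxon rank-sum tests
between NR and non-NR feature distributions rank the 343 triad features;
top-k subsets and their complements (ablation) feed back into training
to measure the weight of the most discriminative triads.

A seeded synthetic generator plants class-specific triad motifs into
background sequences, emulating the benchmark's shape (474 NRs over
eight subfamilies with sizes 162, 140, 82, 23, 29, 7, 21, 10, plus 500
non-NRs), so the whole pipeline is testable without any dataset
download.

## Worked example

```python
import numpy as np
from nrcascade import (default_benchmark, TwoLevelNRClassifier, kfold_cv,
                       rank_features, SequenceEncoder)

coll = default_benchmark(seed=7)          # 474 synthetic NRs + 500 non-NRs
records, labels = list(coll.records), list(coll.labels)

model = TwoLevelNRClassifier(feature_set="aac+ctf",
                             gamma1=8.0, C1=8.0, gamma2=32.0, C2=8.0, seed=7)
model.fit(records[::2], labels[::2])      # train on half
pred = model.predict(records[1::2])       # cascade labels for the rest
print("held-out cascade agreement:",
      round(float((pred == np.asarray(labels[1::2])).mean()), 4))

binary = ["0" if lab == "non-NR" else "1" for lab in labels]
cv = kfold_cv(records, binary, feature_set="aac+ctf", k=10, seed=7,
              config=model.config1_)
print(cv.mean)

X = SequenceEncoder("ctf").fit_transform(records)
lab = np.asarray(labels)
ranking = rank_features(X[lab != "non-NR"], X[lab == "non-NR"])
for rf in ranking[:3]:
    print(f"{rf.label:<18} p = {rf.p_value:.2E}")
```

prints

```
held-out cascade agreement: 0.9897
MetricsReport(sens=0.9979, spec=1.0000, acc=0.9990, mcc=0.9980, auc=1.0000)
AGV-C-RK           p = 5.93E-162
DE-AGV-C           p = 5.47E-161
C-RK-AGV           p = 2.23E-160
```

— 98.97 % of held-out sequences get the correct cascade label
(non-NR or the right subfamily); level-1 10-fold CV is essentially
perfect on this separable synthetic benchmark; and the rank-sum test
retrieves exactly the triads that the generator planted as NR signal
(sequences rich in cysteine–basic–small triads, echoing zinc-finger-like
composition).

The same pipeline is available from the shell:

```bash
nrcascade simulate --seed 7 --out data/
nrcascade cv --fasta data/seqs.fa --labels data/labels.tsv \
             --features aac+ctf --k 10 --seed 1 --out cv.json
nrcascade rank --fasta data/seqs.fa --labels data/labels.tsv \
             --features ctf --out ranking.tsv
```

To run the full two-level protocol on a real labeled FASTA (e.g. a
curated NR benchmark), see `nrcascade.cascade.run_benchmark_protocol`,
which emits the complete per-feature-set, per-level report.

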