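# phistruct

A toolkit for phage–host interaction prediction from receptor-binding
proteins (RBPs), built around structure-aware protein representations and an
abstaining multilayer-perceptron host-genus classifier.

Phages adsorb to their bacterial hosts through receptor-binding proteins —
tail fibers, tailspikes and related adhesins at the distal end of the
virion. Given an RBP, the task is to predict the host genus from among the
seven ESKAPEE genera (*Enterococcus*, *Staphylococcus*, *Klebsiella*,
*Acinetobacter*, *Pseudomonas*, *Enterobacter*, *Escherichia*), the priority
pathogens for phage-therapy candidate shortlisting. The toolkit covers the
full experimental loop a study of this kind needs, with every stage exposed
both as a library function and a CLI subcommand:

1. **catalog** — identify RBPs among annotated proteins by regex rules
   (inclusion / exclusion / hypothetical routing), drop length outliers by
   Tukey fences on the length distribution, remove exact duplicates.
2. **tokenize** — pair each residue r_i with its structure letter f_i (a
   20-letter 3Di-style alphabet) into tokens ⟨(r_1,f_1),…,(r_n,f_n)⟩, read
   per-residue pLDDT out of predicted-structure PDB files, and apply
   masking strategies (mask residues, mask structure, mask structure only
   where pLDDT < 70).
3. **embed** — mean-pool per-residue hidden states into one fixed-length
   vector per protein (L = 1280 by default). The protein language model
   itself is behind a narrow contract; a deterministic synthetic embedder
   with genus-conditional centers stands behind it for testing and
   simulation.
4. **split** — CD-HIT-style greedy identity clustering at threshold *s*;
   representatives split 70/30 stratified by genus; members inherit their
   representative's side, so no test protein has identity ≥ s with any
   training protein (audited by brute force). An outgroup sample of
   non-ESKAPEE RBPs is appended to the test set, sized to the smallest
   in-scope test class.
5. **balance** — SMOTE oversampling to the majority count followed by
   Tomek-link cleaning, training set only.
6. **train / predict** — the classifier below.
7. **evaluate** — confidence-parameterized macro/weighted metrics,
   precision–recall-vs-k curves, confusion matrices.

## The classifier

A two-hidden-layer perceptron over RBP embeddings x ∈ R^L:

```
h1 = ReLU(W1 x + b1)        |h1| = ⌊L/8⌋   (160 at L = 1280), dropout 0.2
h2 = ReLU(W2 h1 + b2)       |h2| = ⌊L/16⌋  (80 at L = 1280)
p  = softmax(W3 h2 + b3)    |p| = |C| = 7
```

trained 200 epochs with Adam (lr 10⁻³, β₁ = 0.9, β₂ = 0.999, batch 128) on
cross-entropy with L2 penalty 10⁻⁴, implemented in numpy with analytic
backpropagation (gradient-checked against finite differences). Exposed as a
scikit-learn-style estimator `StructEmbeddingMLP` (fit / predict /
predict_proba / get_params).

Predictions abstain below a confidence threshold *k*: with p₁, p₂ the two
largest class probabilities, the genus is emitted only if p₁ − p₂ ≥ k.
Metrics are parameterized by (k, s):

- Macro-Precision_{k,s} = (1/|C|) Σ_c TP_c / (TP_c + FP_c), and likewise
  macro-recall and macro-F1;
- Weighted variants weight each class by n_c / N.

Abstention on an in-scope sample counts as a false negative for its true
class; an outgroup sample contributes only false positives when a genus is
(wrongly) emitted. Low k therefore favors recall and high k favors
precision.

Alongside the classifier, `phistruct pairtest` runs the paired-distance
analysis: for each genus, 500 (configurable) RBP pairs below 40% sequence
identity, within-genus versus cross-genus, compared by a Mann–Whitney U
test on cosine distances between their embeddings (or externally supplied
structural distances such as RMSDs).

## Worked example

Everything runs end to end on synthetic data (no downloads, no GPU). The
generator produces sequence families with realistic identity structure,
pLDDT profiles near the 77–83 range typical of predicted RBP structures,
toy PDB files, and genus-clustered embeddings:

```
$ cat demo.yaml
seed: 7
s: 0.4
generator:
  n_per_genus: 12
  n_outgroup: 12
  embed_dim: 256
  length_median: 300
  length_spread: 40

$ phistruct run --config demo.yaml --out out
{
  "config_hash": "3b8a426ed605",
  "final_train_loss": 0.08353477215110143,
  "macro_f1_at_k0": 0.8797036297036297,
  "n_outgroup": 6,
  "n_rbps": 96,
  "n_records": 96,
  "n_test": 48,
  "n_train": 42,
  "n_train_balanced": 42,
  "s": 0.4,
  "seed": 7,
  "weighted_f1_at_k0": 0.8797036297036297
}
```

96 generated proteins all pass the catalog stage; clustering at s = 0.4 and
the representative split leave 42 training and 48 test proteins (6 of them
outgroup). The trained classifier reaches macro-F1 0.88 on the held-out
side at k = 0. `out/metrics.tsv` holds the full report, one row per
confidence threshold k = 0.0 … 0.9:

```
k    s    coverage  macro_precision  macro_recall  macro_f1  ...
0    0.4  1         0.8589569161     0.9285714286  0.8797036297
```

`out/` also contains the protein tables, the catalog audit log, the cluster
and split files, the balanced training set, the model container
(`model.json`) and confusion matrices. Re-running with the same config is
byte-identical.

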