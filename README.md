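# idrbrnn

Per-residue prediction of **short intrinsically-disordered protein regions**
(runs of 3–30 consecutive disordered residues in chains longer than 50) with
**two-stage bidirectional recurrent neural networks**.

Disordered regions lack a stable 3D structure but carry much of a proteome's
regulatory function. Because disorder is rare (~6% of residues in
X-ray-derived corpora), the practical challenge is recognising it with very
few false positives. This package is for structural-bioinformatics
practitioners who want a transparent, dependency-light, trainable
implementation of the full pipeline: corpus curation, input encoding,
the recurrent architecture, the training/ensembling protocol, and the
evaluation battery — plus a synthetic-corpus generator so everything is
testable end-to-end on a laptop.

## The model

Each stage is a bidirectional RNN over the chain:

    o_j  = N_O(i_j, hF_j, hB_j)
    hF_j = N_F(i_j, hF_{j−1}, …, hF_{j−S})
    hB_j = N_B(i_j, hB_{j+1}, …, hB_{j+S})

with zero boundary states and two-layer tanh subnets N_O, N_F, N_B (softmax
output, m = 2 classes). A second, identical-architecture stage filters the
first using semi-global evidence: its input at position j is the
first-stage output c_j plus 2p+1 window averages of first-stage outputs,
windows of width 2w+1 anchored at k_f = j + f(2w+1), f = −p..p (defaults
w = 7, p = 10).

The input vector i_j concatenates up to four components (E, S, A, T):
a 21-dim MSA frequency profile (20 amino acids + gap), 3-dim one-hot
secondary structure, 4-dim one-hot solvent accessibility, and a 3-dim
template transfer

    T_j = [ Σ_p V_{p,j} I_p³ / Σ_p I_p³ ,  Σ_p I_p⁴ / Σ_p I_p³ ]

that weights each template's order/disorder annotation by the cube of its
sequence identity I_p. The four variants — MSA (21), MSA-SS-SA (28),
MSA-Templ (24), MSA-SS-SA-Templ (31 inputs) — share one code path; missing
template coverage is encoded as zeros, so a single predictor handles
queries with and without homology information.

Training minimises cross-entropy by plain gradient descent with
backpropagation through structure (500 weight updates per epoch over a
shuffled, block-partitioned chain list; learning-rate halving on validation
plateaus; no momentum or weight decay). The nine best checkpoints per fold
are ensemble-averaged; five-fold cross-validation yields a 45-member final
predictor. See `docs/methods.md` for the complete account.

## Worked example

```python
import numpy as np
from idrbrnn import (DisorderBRNN, FilterGeometry, SyntheticConfig,
                     TrainConfig, generate_corpus)

corpus = generate_corpus(SyntheticConfig(n_chains=50, seed=7))
model = DisorderBRNN(
    corpus, variant="MSA-Templ",
    hidden_chain=8, subnet_hidden=8,
    train_config=TrainConfig(epochs=30, batches_per_epoch=50,
                             lr_halving_patience=10,
                             n_best_checkpoints=3, seed=1),
)
res = model.fit(k=5)
print(res.summary())
```

prints:

```
Disorder prediction: two-stage BRNN, out-of-fold results
==========================================================
variant:              MSA-Templ
chains / residues:    50 / 9029
disorder prevalence:  0.0603
folds / members:      5 / 15
threshold (FPR<=5%): 0.0031
----------------------------------------------------------
sensitivity (SE):     0.998
specificity (SP):     0.950
precision (Prec):     0.562
balanced acc (Acc):   0.974
MCC:                  0.730
AUC-ROC:              1.000
AUC-PR:               0.993
```

Read it as: on held-out chains the template-augmented variant separates
disordered from ordered residues almost perfectly (AUC-ROC 1.000 at this
printed precision — high-identity, low-noise templates nearly give the
labels away), and the threshold chosen to spend the full 5% false-positive
budget recovers 99.8% of disordered residues; at 6% prevalence that budget
caps precision near 0.56. `res.predict(record)` returns the
per-residue disorder probabilities for a new chain;
`res.report(n_trim=10)` re-scores with 10 residues trimmed from each
terminus (internal disorder only).

The same pipeline is scriptable from a shell:

```bash
idrbrnn simulate --out corpus/ --n-chains 200 --seed 1
idrbrnn train    --corpus corpus/ --out run/ --variant MSA-Templ \
                 --epochs 100 --batches-per-epoch 50
idrbrnn predict  --model run/ensemble_merged.npz --corpus corpus/ \
                 --variant MSA-Templ --out pred.tsv
idrbrnn evaluate --predictions pred.tsv --corpus corpus/ --out report.json
```

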