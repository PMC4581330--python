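# Methods

## Problem

Intrinsically-disordered regions (DRs) are protein segments without a stable
three-dimensional structure. This package targets *short* disorder: runs of
3–30 consecutive disordered residues inside chains longer than 50 residues,
the flavour of disorder that dominates X-ray-derived annotation databases.
The task is per-residue binary sequence labelling (ordered/disordered) with
strong class imbalance (~6% of residues disordered), where the practical
requirement is high sensitivity at a very low false-positive rate.

## Model

### Bidirectional recurrent architecture

Each stage is a bidirectional recurrent neural network. For inputs
i_1..i_N (N the chain length):

    o_j  = N_O(i_j, hF_j, hB_j)
    hF_j = N_F(i_j, hF_{j-1}, …, hF_{j-S})
    hB_j = N_B(i_j, hB_{j+1}, …, hB_{j+S})

with zero boundary states hF_0 = hB_{N+1} = 0. N_O, N_F and N_B are
two-layer feed-forward subnets (tanh hidden layer; the chains' states are
tanh vectors; the output is a 2-class softmax). The shortcut span S feeds
each transition the previous/next S states, shortening gradient paths. This
lets the predictor integrate evidence over variable-range context instead of
a fixed window.

### Two-stage filtering

A second BRNN of the same architecture refines the first stage using
semi-global evidence. Its input at position j is the first-stage output
c_j plus 2p+1 window averages of first-stage outputs; the f-th window is
centred at k_f = j + f(2w+1) and spans k_f − w .. k_f + w, f = −p..p.
Window positions outside 1..N are excluded from both the sum and the
divisor (divisor floored at 1), so terminal inputs stay on the same scale
as interior ones. Defaults are w = 7 and p = 10, giving a second-stage
input width of m(2p+2) = 44 per position. Averages (not raw sums) are
used; the two differ only by constants absorbable into second-stage
weights.

### Input encodings

Four variants, always in component order E, S, A, T:

| variant          | E  | S | A | T | total |
|------------------|----|---|---|---|-------|
| MSA              | 21 | 0 | 0 | 0 | 21    |
| MSA-SS-SA        | 21 | 3 | 4 | 0 | 28    |
| MSA-Templ        | 21 | 0 | 0 | 3 | 24    |
| MSA-SS-SA-Templ  | 21 | 3 | 4 | 3 | 31    |

* **E** — frequency profile: per query position, the frequencies of the 20
  amino acids plus the gap frequency over the MSA column. The query row is
  counted (so singleton MSAs give one-hot profiles); columns where the query
  is gapped are dropped; nonstandard letters are spread uniformly over the
  20 amino-acid channels.
* **S**, **A** — one-hot predicted secondary structure (helix/strand/coil)
  and 4-class solvent accessibility (completely buried, partly buried,
  partly exposed, exposed). These arrive as strings from any upstream
  predictor.
* **T** — template transfer. For hits p covering position j, with identity
  I_p and per-residue state V_{p,j} (O=(1,0), D=(0,1)):

      T_j = [ Σ_p V_{p,j} I_p³ / Σ_p I_p³ ,  Σ_p I_p⁴ / Σ_p I_p³ ]

  Identity-cubed weighting makes a 90%-identity template worth two orders
  of magnitude more than a 20% one; the third component (the
  cubed-identity-weighted mean identity) tells the network how much to
  trust the transfer. Hits above 95% identity are removed before encoding
  (a 50% cap reproduces a low-homology regime). Positions covered by no hit
  are all-zero ("blank"), so one predictor serves queries with and without
  templates. The sums are taken per position over the hits covering that
  position, so fragment templates are handled consistently; consequently
  the score component can vary along the chain.

A windowed feed-forward baseline (window 21, 20 hidden units, softmax) is
included for comparison.

## Training

Loss is the summed cross-entropy of both stages against the labels; the
second-stage gradient also flows back through the (linear) filter-input map
into stage 1. Supervising stage 1 directly keeps its outputs calibrated
class probabilities, which the filter contract assumes. Gradients are
computed by backpropagation through structure: each hidden state's adjoint
accumulates contributions from the output net and from the S downstream
transition evaluations that consumed it.

Full-scale schedule: 2000 epochs; each epoch shuffles the chain list and
cuts it into 500 contiguous blocks; gradients are summed over all residues
of a block and one plain gradient-descent step is taken per block (no
momentum, no weight decay), scaled by lr / residues-in-block. The learning
rate halves whenever validation cross-entropy has not decreased for the
patience window (500 epochs at full scale). The nine best end-of-epoch
checkpoints by validation error are retained and ensemble-averaged
(unweighted mean of probabilities); across five cross-validation folds this
yields the 45-member final predictor. Validation (the held-out fold during
cross-validation) is used for both checkpoint ranking and the halving
schedule.

Numerical choices: float64 throughout; weight init uniform in ±1/√fan-in
under the run seed, biases zero; softmax probabilities floored at 1e-12
inside logs; hidden-chain width 11, subnet hidden width 11 and span S = 2 by
default (small, CPU-friendly, all configurable). The initial learning rate
defaults to 0.3 with per-residue gradient scaling, chosen from a small
stability sweep on synthetic corpora (0.05 converges needlessly slowly,
1.0 begins to oscillate). The recurrence kernels are JIT-compiled with
numba; everything position-parallel is vectorised numpy.

A note on the filter geometry: the canonical description is the formula
with configurable (w, p) and defaults (7, 10). Alternative prose figures
sometimes quoted for this architecture (18 windows of 18 residues, 19m
inputs) are mutually inconsistent with that formula and are treated as an
erratum; this implementation follows the formula.

## Evaluation

Confusion counts use the ≥-threshold rule (a residue is called disordered
when its probability is at least the threshold). SE, SP, Prec, balanced
accuracy (SE+SP)/2 and MCC are reported; any zero denominator in MCC gives
0 by convention. ROC curves sweep all distinct scores; the trapezoidal
AUC equals the Mann–Whitney pair-counting statistic with ties counted ½
(verified exactly in tests). PR curves are swept the same way and
integrated by trapezoid over recall, anchored at recall 0 with the first
point's precision — an approximation, since no interpolation convention is
canonical for PR areas. The operating threshold is the smallest threshold
whose FPR on the selection data is ≤ the target (default 5%); realized FPR
on other data may differ by score granularity. Termini trimming excludes
n residues at each chain end (chains with N ≤ 2n drop out), isolating
internal-disorder performance. Identity-binned AUC groups chains by
best-template identity into half-open 10% bins (top bin closed) and pools
residues per bin.

## Dataset curation

Chains enter the corpus only if length > 50, resolution < 2.0 Å when
recorded, and every disordered run lies in 3–30 with at least one present.
The run rule is read strictly: a chain containing any run longer than 30 is
rejected even if it also has a valid short run, because over-long runs make
the chain a long-disorder example, outside this predictor's target. For
redundancy reduction the worse member of any pair above 30% identity is
removed greedily (worst conflicted record first); "quality" is
crystallographic resolution when available, else chain length (longer
preferred), ties broken lexicographically by id. Pairwise identities are
supplied externally; a fallback global-alignment identity
(match=1/mismatch=0, gaps ignored, normalised by the shorter length) is
provided. Folds are balanced to ±1 chain, assigned uniformly at random
under the seed; residue balance follows from scale.

## Synthetic corpus

The generator plants a learnable signal with the statistical shape the
predictor assumes:

* **Labels** — each chain receives a disordered-residue budget of
  round(length × target fraction) (floored at one minimal run), partitioned
  into runs of 3–30 separated by at least one ordered residue. Every chain
  therefore carries at least one valid run and pooled prevalence tracks the
  6% target.
* **Composition** — disordered positions draw from a distribution enriched
  2.5× in P/E/S/K/Q/G and depleted 3× in W/C/F/I/Y/V (the classic
  disorder-/order-promoting split); ordered positions draw from the
  complementary bias.
* **MSAs** — row 0 is the query; other rows mutate each position at 0.1
  (ordered) or 0.4 (disordered) per residue, substituting from the label's
  composition, so disordered columns are visibly less conserved. A mutation
  event emits a gap with probability 0.1 (exercising the 21st profile
  channel); zero mutation rates therefore give rows identical to the query.
* **SS/SA** — disordered residues emit coil/exposed classes with
  probability 0.85, ordered residues the complementary bias, mirroring the
  qualitative structure–disorder coupling.
* **Templates** — one hit per configured identity; annotations are the true
  labels flipped independently at the noise rate; 30% of hits cover only a
  contiguous fragment (50–90% of the chain).

What the generator does **not** emulate: real amino-acid background
frequencies, correlated substitution patterns, alignment insertions,
length/prevalence statistics of any real database, or structural context.
Passing the learning tests therefore shows that the architecture, encodings,
gradients and protocol work end-to-end and that template information is
exploited when informative — not that real-data accuracies are reproduced,
which would require database-scale profiles and template searches.

## Problem sizes used in the test and acceptance runs

The learning experiment uses a 200-chain corpus (lengths 80–300, 6%
disorder, depth-30 MSAs, templates at 0.95/0.875/0.8 identity with 5%
noise), five-fold cross-validation, and a scaled-down schedule of 100
epochs × 50 blocks with widths 8 and span 2 — sizes chosen so the full
experiment runs in minutes on one CPU while leaving a wide margin over the
pass criteria. The full-scale defaults (2000 × 500, widths 11) remain the
documented production settings.

## Known limitations

* Training is plain gradient descent by design; no adaptive optimisers.
* PR-AUC is interpolation-sensitive at tiny sample sizes.
* The per-position template score deviates from a whole-protein reading of
  the score definition (which subscripts it by protein); the per-position
  form was chosen so fragment templates contribute only where they align.
* The greedy redundancy reduction is order-deterministic but not guaranteed
  to retain the maximum possible number of chains (neither is any greedy
  rule); tests verify the no-conflict postcondition and the 3-clique case
  exhaustively.
* The NN baseline is exposed as a forward model for comparison; the
  training loop is implemented for the two-stage BRNN.
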