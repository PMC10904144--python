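# Methods

## Problem and model

Dipeptidyl peptidase IV (DPP-IV) is a serine protease that cleaves
N-terminal dipeptides after a proline or alanine; peptides that inhibit it
(DPP-IV-IPs) are candidate antidiabetic agents. `dppiv` classifies a
peptide sequence as inhibitory or not from two complementary views that
are fused multiplicatively.

### Structural view

Each residue is rendered independently as the *free amino-acid molecule*
(peptide bonds between residues are not modelled — the per-residue encoding
is context-free, which is what makes a fixed 15-atom residue matrix
possible). RDKit parses a pinned canonical SMILES per residue, computes
Gasteiger partial charges, and each heavy atom receives a 21-slot vector:

| slots | content |
|---|---|
| 0–3 | one-hot element (C, N, O, S) |
| 4–6 | one-hot heavy-atom degree 1–3 |
| 7–10 | one-hot total hydrogen count 0–3 |
| 11–14 | one-hot implicit hydrogen count 0–3 |
| 15 | aromaticity flag |
| 16–17 | one-hot ring membership |
| 18 | hybridization as an integer (S=1, SP=2, SP2=3, SP3=4, SP3D=5, SP3D2=6, other=7) |
| 19 | Gasteiger charge (becomes the neighbour sum, below) |
| 20 | Gasteiger charge of the atom itself |

Slots 0–19 are then replaced by the adjacency-matrix product — each atom
carries the *sum of its bonded neighbours'* raw features, with no
self-loop — while slot 20 bypasses aggregation and keeps the atom's own
charge. Degrees or H-counts outside the one-hot ranges map to an all-zero
block rather than an error, keeping the encoding total.

Residue matrices are padded to 15 atom rows (tryptophan's heavy-atom
count, the maximum over the 20 standard residues) and sequences to a
configurable residue cap (default 90, the longest peptide in the public
benchmark this family of models is trained on). Padded cells are exact
zeros and carry validity masks; sequences over the cap are rejected, never
truncated.

The structural encoder treats the tensor as a 2-D image (residues × atoms)
with 21 channels:

    T_conv = Conv(T_S)
    T_res1 = T_conv + Conv(relu(Norm(Conv(relu(Norm(T_conv))))))
    M      = Conv_s2(T_res1) + Conv(relu(Norm(Conv(relu(Norm(MP(T_res1)))))))
    v_S    = Linear(flatten(M))

`Norm` is batch normalization, `MP` is 2×2 max pooling (ceil mode), and the
shortcut convolution `Conv_s2` is strided 2×2 so both addends of the second
residual block share a shape. The final map `M` is *flattened* and
projected to the fusion dimension rather than globally pooled: global
pooling would make the branch translation-invariant and provably unable to
use residue *position*, which both the biology (the P/A signal sits at the
second residue) and the positional importance analyses require.

### Sequence view

A TextCNN: trainable residue embeddings (non-static), 1-D convolutions of
several filter widths (default 2, 3, 4), max-over-time pooling per filter
restricted to real (non-padding) positions, and a per-branch linear
projection:

    v_emb = Embed(a),  v_conved = Convs(v_emb),  v_T = Linear(MP(v_conved))

### Fusion and head

    v_final = v_S ⊙ v_T
    ŷ = sigmoid(Linear(ReLU(Dropout(Linear(v_final)))))

Element-wise multiplication introduces a nonlinear interaction between the
branch features. Single-branch ablations (`branch=structural_only` /
`text_only`) feed that branch's vector directly to the head.

## Training

Focal loss, `mean(−α_t (1−p_t)^γ log p_t)` with γ=2 and α=0.5 by default
(α is neutral because the generated classes are balanced), minimized with
Adam. The benchmark-scale protocol defaults are batch size 32, learning
rate 5·10⁻⁶ and at most 150 epochs. All peptides are encoded once before
the first epoch; with a `cache_dir` the encodings are persisted under a
content hash of the sequences so repeated runs skip the chemistry.

Everything that consumes randomness — parameter initialization, epoch
shuffling, dropout — draws from generators derived from the single config
seed, so a fixed seed reproduces the loss history and the predictions
bit-for-bit (the stack is float64, single-threaded numpy).

## Interpretability

* **Grad-CAM.** The differentiation target is the positive-class logit
  (pre-sigmoid — the sigmoid saturates and shrinks gradients). The target
  layer is the output of the second residual block, the last convolutional
  feature map of the structural branch and the only map with atom-level
  spatial structure. Gradients weight activations *per spatial cell*
  (gradient ⊙ activation summed over channels, then rectified) rather than
  through globally averaged channel weights: global averaging is the right
  formulation when a pooling head makes activation magnitude carry the
  class evidence, but with a flatten+linear readout the spatial attention
  lives in the readout weights, and globally averaged weights demonstrably
  smear importance away from the decisive positions. The rectified map is
  mapped back to (residue, atom) cells (each stride-2 cell covers a 2×2
  block, so neighbouring residue/atom pairs share a coarse score). A residue's position score is
  the sum over its atoms; padding scores are exactly zero. Dataset-level
  position aggregation averages only over sequences long enough to reach a
  position (no zero-imputation), and amino-acid-type aggregation sums CAM
  scores grouped by residue identity.
* **Perturbation scanning.** Every position is substituted by each of the
  20 residues and the change in predicted probability recorded; identity
  substitutions are exactly zero. Absolute mean deltas measure importance,
  signed means measure direction; identity (X→X) entries are excluded from
  the averages. Averaging signed deltas per (original → substituted) pair
  over a dataset gives the conversion matrix, whose diagonal is exactly
  zero and whose rows for residues absent from the dataset are flagged
  missing rather than zeroed.
* **AAC fold.** Residue frequency in the positive set divided by that in
  the negative set; folds above 1 mark enrichment in inhibitory peptides.
  Residues absent from the negatives give a flagged infinity.

## Synthetic data

The generator emulates a labelled inhibitory-peptide benchmark without any
download: uniform residue background, lengths uniform on 5–30 (inside the
2–90 envelope real collections span), and a planted motif in the positive
class — by default proline or alanine at the second residue (probability
0.5 each), echoing the enzyme's cleavage signature. Negatives are pure
background; about 10% of them carry P/A at position 2 by chance, which
caps the achievable held-out AUC near 0.95.

What it deliberately does *not* emulate: realistic amino-acid composition,
length–class correlations, homology between records, label noise, or the
multi-position determinants of real DPP-IV inhibition. Passing the
synthetic learnability and localization tests therefore shows the
pipeline is sound and the explanations track planted signal — not that
benchmark-level accuracy transfers to real data.

## Study conditions and problem sizes

The synthetic study used by the tests and the acceptance script:
400 peptides (200 per class), stratified 80/20 split, and
`ModelConfig.for_synthetic_study` — channels (8, 16), embedding 16,
8 filters per width, fusion 32, head 16, dropout 0.3, learning rate 10⁻³,
batch 32, up to 150 epochs, tensor cap 30 residues. The width/depth
choices scale the benchmark-sized defaults down to a 320-sample task;
dropout is reduced because half-dropping a 16-unit head is far noisier
than on the wide default head.

## Numerical choices

* float64 throughout; convolutions via im2col + BLAS matmul.
* Batch-norm momentum 0.1, ε=10⁻⁵; running statistics frozen at inference.
* Max pooling pads with −∞ (ceil mode); gradient goes to the first argmax
  on ties.
* Focal-loss probabilities clamped to [10⁻¹², 1−10⁻¹²].
* 'Same' convolution padding puts the extra cell on the right/bottom.
* Classifier threshold 0.5 for confusion-matrix metrics (balanced classes).
* Metrics with zero denominators are reported as tagged *undefined* values
  with reasons, never silently 0 or NaN.

## Known limitations

* The real benchmark (665+665 peptides) is not bundled; users supply it as
  CSV/FASTA and train with the wide defaults. No claim is made about
  reproducing published benchmark accuracies.
* The network is implemented on a compact numpy autodiff engine written
  for this package; it is CPU-oriented and single-threaded — appropriate
  for peptide-scale inputs, not for large-scale pretraining.
* Grad-CAM's stride-2 coarse map cannot separate adjacent residue pairs
  (or adjacent atom pairs) that share a cell; rankings at that resolution
  are reported as-is.
* Only the 20 standard L-amino acids are supported; no post-translational
  modifications, D-stereoisomers, or whole-peptide SMILES.
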