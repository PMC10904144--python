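# dppiv

Structure- and sequence-aware prediction of dipeptidyl peptidase IV (DPP-IV)
inhibitory peptides, with atom-level interpretability.

DPP-IV degrades the incretin hormones that stimulate insulin secretion;
peptides that inhibit it are a promising class of antidiabetic agents, and
screening candidate peptides in the wet lab is slow and expensive. `dppiv`
is an in-silico screening toolkit for peptide chemists and ML-for-biology
practitioners: it scores peptide sequences (2–90 residues, one-letter code)
for inhibitory potential and explains *which positions, residues and atoms*
drive each score.

## The model

Each residue `a_i` of a peptide `S = (a_1, …, a_n)` is rendered as the free
amino-acid molecule from a pinned canonical SMILES; every heavy atom gets a
21-feature vector (element / degree / H-count one-hots, aromaticity, ring
membership, hybridization, Gasteiger charges), and slots 0–19 are replaced
by the sum over bonded neighbours via the adjacency matrix `A` (slot 20
keeps the atom's own charge):

    V' = A·V[:, 0:20]  ⊕  V[:, 20]

Padding to 15 atoms (tryptophan's heavy-atom count) and `n_max` residues
yields the structural tensor `T_S ∈ R^(n_max × 15 × 21)`. Two encoders then
produce branch vectors:

    T_conv = Conv(T_S)
    T_res1 = T_conv + Conv(relu(Norm(Conv(relu(Norm(T_conv))))))
    v_S    = Linear(flatten(Conv(T_res1) + Conv(relu(Norm(Conv(relu(Norm(MP(T_res1)))))))))

    v_T    = Linear(MaxOverTime(Convs(Embed(S))))        # TextCNN branch

and the joint representation is their element-wise product, classified by a
small head with focal-loss training:

    v_final = v_S ⊙ v_T
    ŷ       = sigmoid(Linear(ReLU(Dropout(Linear(v_final)))))
    L       = mean(−α_t (1−p_t)^γ log p_t)               # focal loss, γ=2

Evaluation reports ACC, sensitivity, specificity, MCC and rank-based AUC.
The interpretability suite provides Grad-CAM maps at atom / position /
residue-type granularity, exhaustive single-residue perturbation scanning
(absolute and signed), amino-acid-composition fold changes, and the
residue-conversion matrix. Everything runs on CPU in float64 and is
bit-reproducible for a fixed seed; see `docs/methods.md` for assumptions,
defaults and limitations.

No benchmark data is bundled. A synthetic generator plants a configurable
class-separating motif — by default proline/alanine at the second residue,
the DPP-IV cleavage signature — so the full pipeline is testable offline;
user-supplied datasets load from CSV (`sequence,label`) or FASTA
(label as an `|1` / `|0` id suffix).

## Worked example

```python
import numpy as np
from dppiv import (
    MotifSpec, generate_synthetic, split_benchmark,
    ModelConfig, train, predict, evaluate_scores,
    cam_scores, aggregate_cam, perturb_scan, perturbation_importance, aac_fold,
)

records = generate_synthetic(200, 200, MotifSpec(seed=7))
train_set, test_set = split_benchmark(records, train_fraction=0.8, seed=7)

model = train(train_set, ModelConfig.for_synthetic_study(seed=7))

labels = np.array([r.label for r in test_set])
scores = predict([r.sequence for r in test_set], model)
m = evaluate_scores(labels, scores)
print(f"held-out ACC={m['ACC']:.3f}  Sn={m['Sn']:.3f}  Sp={m['Sp']:.3f}  "
      f"MCC={m['MCC']:.3f}  AUC={m['AUC']:.3f}")

positives = [r.sequence for r in test_set if r.label == 1]
cam = aggregate_cam([cam_scores(model, s)[0] for s in positives], by="position")
print("top-3 CAM positions (0-based):",
      sorted(cam.scores, key=cam.scores.get, reverse=True)[:3])

scans = [(s, perturb_scan(model, s)) for s in positives[:10]]
pert = perturbation_importance(scans, mode="absolute", by="position")
print("top-3 perturbation positions:",
      sorted(pert.scores, key=pert.scores.get, reverse=True)[:3])

folds = aac_fold(positives, [r.sequence for r in test_set if r.label == 0])
print("AAC-fold enriched residues:",
      {r: round(f, 2) for r, f in folds.items() if f > 1.3})
```

Output (about four minutes on one CPU core):

```
held-out ACC=0.887  Sn=0.875  Sp=0.900  MCC=0.775  AUC=0.924
top-3 CAM positions (0-based): [2, 3, 0]
top-3 perturbation positions: [1, 16, 23]
AAC-fold enriched residues: {'A': 1.61, 'T': 1.39, 'Y': 1.3}
```

The classifier separates the classes well (AUC 0.92 against a Bayes
ceiling near 0.95 — about 10% of negatives carry P/A at position 2 by
chance). Both explanation methods concentrate on the head of the peptide,
where the generator plants P/A at 0-based position 1: perturbation
scanning ranks that exact position first, while Grad-CAM — whose stride-2
map scores adjacent positions jointly and whose convolutions smear
evidence into neighbouring cells — puts the surrounding head positions
(0–3) on top. The composition statistic independently flags alanine
enrichment in the positives.

The same workflow is available from the shell:

```sh
dppiv synth --n-pos 200 --n-neg 200 --seed 7 --out synth.csv
dppiv init-config && dppiv train --config dppiv-config.yaml --data synth.csv --out model.ckpt
dppiv predict --model model.ckpt --in synth.csv --out scores.csv
dppiv evaluate --model model.ckpt --data synth.csv --out metrics.json
dppiv explain --model model.ckpt --in synth.csv --method cam --out cam.csv
```

Every command writes a `*.manifest.json` (config, seeds, input hashes)
next to its outputs.

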