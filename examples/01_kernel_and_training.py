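"""Train a gapped k-mer SVM on a toy planted-motif problem.

Builds 30 positive sequences carrying the word GATTACA on random background
and 30 plain background sequences, trains a gkm-SVM (l=5, k=3), and prints
the training accuracy, five-fold cross-validated AUROC and the scores of one
motif-bearing versus one background sequence.  AUROC near 1.0 means the
kernel separates motif-bearing from background sequence almost perfectly.
"""

import random

from crevip import GkmParams, cross_validate, predict_score, train_model

rng = random.Random(0)
rand = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

positives = [rand(10) + "GATTACA" + rand(10) for _ in range(30)]
negatives = [rand(27) for _ in range(30)]

params = GkmParams(word_length=5, k=3)
model = train_model(positives, negatives, params, seed=0, class_label="toy")
cv = cross_validate(positives, negatives, params, folds=5, seed=0)

print(f"training accuracy : {model.training_accuracy:.3f}")
print(f"pooled 5-fold AUROC: {cv.pooled_auroc:.3f}")
print(f"score(motif-bearing) = {predict_score(model, positives[0]):+.3f}")
print(f"score(background)    = {predict_score(model, negatives[0]):+.3f}")
print("Positive decision values mean 'accessible-like' for this model.")
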