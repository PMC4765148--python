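"""Train an mLASSO localization model on planted data and predict a protein.

Builds a synthetic dataset with known sparse structure, runs the two-stage
pipeline (one-vs-rest selection -> essential GO terms -> refit), and scores
one protein.  The printed scores are s_m = intercept_m + beta~_m . x^s; the
predicted set is every location with a positive score, or the argmax when
all scores are negative.
"""

import numpy as np

import sparseloc as sl
from sparseloc.go_features import GoTerm, GoVocabulary
from sparseloc.solver import PenaltyParams

dataset, truth = sl.make_planted_dataset(N=150, T=60, M=3, k=5, seed=42)
terms = tuple(GoTerm(f"GO:{1000000 + j:07d}", ("CC", "MF", "BP")[j % 3])
              for j in range(60))
vocab = GoVocabulary(terms, {t.id: j for j, t in enumerate(terms)})

model = sl.train(dataset.X, dataset.label_sets, 3, vocab,
                 mode="mlasso", penalties=PenaltyParams(lam=8.0), seed=0)
print(f"vocabulary size T = {len(vocab)}, essential terms S = {model.S}")

result = sl.predict(model, dataset.X[0])
print("scores:", np.round(result.scores, 3))
print("predicted locations:", sorted(result.labels),
      "| true locations:", sorted(dataset.label_sets[0]))
print("(positive scores -> predicted; all-negative -> single best location)")
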