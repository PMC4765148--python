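"""Interpret a prediction term by term and compare mLASSO vs mEN selections.

Each essential GO term contributes weight x term-frequency to a location's
score, so the prediction decomposes into a ranked feature-score table.  The
overlap report shows how the elastic net's (greedier) essential set relates
to the LASSO's (more parsimonious) one.
"""

import numpy as np

import sparseloc as sl
from sparseloc.go_features import GoTerm, GoVocabulary
from sparseloc.interpret import classify_weights, feature_breakdown, overlap_report
from sparseloc.multilabel import project_features
from sparseloc.solver import PenaltyParams

dataset, _ = sl.make_planted_dataset(N=150, T=60, M=3, k=5, seed=42)
terms = tuple(GoTerm(f"GO:{1000000 + j:07d}", ("CC", "MF", "BP")[j % 3])
              for j in range(60))
vocab = GoVocabulary(terms, {t.id: j for j, t in enumerate(terms)})

mlasso = sl.train(dataset.X, dataset.label_sets, 3, vocab,
                  mode="mlasso", penalties=PenaltyParams(lam=8.0), seed=0)
men = sl.train(dataset.X, dataset.label_sets, 3, vocab,
               mode="men", penalties=PenaltyParams(lam=8.0, gamma=0.5), seed=0)

xs = project_features(dataset.X[0], mlasso.essential)
print("top contributions to the location-1 score (weight x term-freq):")
for c in feature_breakdown(mlasso, xs, 1)[:5]:
    print(f"  {c.term.id} ({c.term.category})  weight={c.weight:+.3f}  "
          f"freq={c.term_freq:g}  feature_score={c.feature_score:+.3f}")

catalog = classify_weights(mlasso, threshold=0.1)
print("\nweight intervals (count of nonzero weights per interval):")
for interval, count in catalog.interval_counts().items():
    print(f"  {interval:<12} {count}")
print("significantly essential terms (|weight| > 0.1):",
      len(catalog.significant_terms()))

report = overlap_report(mlasso, men)
g = report["global"]
print(f"\nessential-term overlap: common={g['n_common']}, "
      f"mLASSO-only={g['n_only_a']}, mEN-only={g['n_only_b']}")
print("(the elastic net tends to select a superset: correlated terms enter together)")
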