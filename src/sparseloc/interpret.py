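"""Interpretability reports for trained localization models.

A sparse linear scorer is interpretable term by term: the contribution of
essential GO term s to the score of location m is the product of its
refit weight and the query's term frequency.  This module turns that into
per-protein feature-score tables, weight-significance catalogs, bipartite
term-location edge lists, and overlap reports between two models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .go_features import GoTerm
from .multilabel import LocalizationModel, score

#: interval boundary separating "significant" weights; the only numeric
#: boundary the weight-interval scheme defines
DEFAULT_SIGNIFICANCE_THRESHOLD = 0.1

INTERVALS = ("beta<=-0.1", "-0.1<beta<0", "0<beta<=0.1", "beta>0.1")


@dataclass(frozen=True)
class FeatureContribution:
    """One (term, location) contribution: weight x term frequency."""

    term: GoTerm
    location: int
    weight: float
    term_freq: float
    feature_score: float


def feature_breakdown(
    model: LocalizationModel, xs: np.ndarray, location: int
) -> list[FeatureContribution]:
    """Per-term contributions to one location's score, largest first.

    Only terms with nonzero weight *and* nonzero frequency are listed;
    ties in feature score keep vocabulary order.  The contributions plus
    the intercept reconstruct the location score exactly.
    """
    if not 1 <= location <= model.M:
        raise ValueError(f"location must be in 1..{model.M}")
    xs = np.asarray(xs, dtype=np.float64)
    if xs.shape != (model.S,):
        raise ValueError(f"expected a length-{model.S} essential-space vector")
    w = model.weights[location - 1]
    rows = [
        FeatureContribution(
            term=model.essential.terms[s],
            location=location,
            weight=float(w[s]),
            term_freq=float(xs[s]),
            feature_score=float(w[s] * xs[s]),
        )
        for s in range(model.S)
        if w[s] != 0.0 and xs[s] != 0.0
    ]
    order = sorted(range(len(rows)), key=lambda i: (-rows[i].feature_score, i))
    return [rows[i] for i in order]


def _interval(beta: float) -> str:
    if beta <= -0.1:
        return INTERVALS[0]
    if beta < 0:
        return INTERVALS[1]
    if beta <= 0.1:
        return INTERVALS[2]
    return INTERVALS[3]


@dataclass(frozen=True)
class WeightEntry:
    term: GoTerm
    location: int
    weight: float
    interval: str
    significant: str  # "positive", "negative" or ""


@dataclass
class SignificanceCatalog:
    """Every nonzero (term, location) weight with interval and significance."""

    entries: list[WeightEntry]
    threshold: float

    def significant_terms(self) -> set[str]:
        return {e.term.id for e in self.entries if e.significant}

    def interval_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in INTERVALS}
        for e in self.entries:
            counts[e.interval] += 1
        return counts


def classify_weights(
    model: LocalizationModel, threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
) -> SignificanceCatalog:
    """Assign each nonzero weight to its interval and flag significance.

    Positive-significant: beta > threshold (strong indicator of residence);
    negative-significant: beta < -threshold (strong indicator of absence).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    entries: list[WeightEntry] = []
    for m in range(model.M):
        for s in range(model.S):
            beta = float(model.weights[m, s])
            if beta == 0.0:
                continue
            if beta > threshold:
                flag = "positive"
            elif beta < -threshold:
                flag = "negative"
            else:
                flag = ""
            entries.append(
                WeightEntry(model.essential.terms[s], m + 1, beta, _interval(beta), flag)
            )
    return SignificanceCatalog(entries, threshold)


def weight_summary(model: LocalizationModel) -> dict[int, dict]:
    """Per-location counts of nonzero/positive/negative weights + histogram."""
    summary: dict[int, dict] = {}
    for m in range(model.M):
        w = model.weights[m]
        nz = w[w != 0.0]
        hist = {name: 0 for name in INTERVALS}
        for beta in nz:
            hist[_interval(float(beta))] += 1
        summary[m + 1] = {
            "nonzero": int(nz.size),
            "positive": int((nz > 0).sum()),
            "negative": int((nz < 0).sum()),
            "intervals": hist,
        }
    return summary


def network_edges(model: LocalizationModel) -> list[tuple[str, int, str, float]]:
    """Bipartite term-location edges: one per nonzero weight.

    Each edge is (term id, location, sign, weight); a term whose edges
    span all M locations is a global indicator of presence/absence.
    """
    edges = []
    for s in range(model.S):
        for m in range(model.M):
            beta = float(model.weights[m, s])
            if beta != 0.0:
                edges.append(
                    (model.essential.terms[s].id, m + 1, "+" if beta > 0 else "-", beta)
                )
    return edges


def overlap_report(
    model_a: LocalizationModel, model_b: LocalizationModel
) -> dict:
    """Essential-term overlap between two models sharing a vocabulary.

    Reports global and per-location intersections and differences with the
    term ids listed, mirroring the mLASSO-vs-mEN comparison in which the
    parsimonious model's selection nests inside the greedier one's.
    """
    if model_a.vocabulary.terms != model_b.vocabulary.terms:
        raise ValueError("models do not share a vocabulary")
    if model_a.M != model_b.M:
        raise ValueError("models have different numbers of locations")

    def _sets(model: LocalizationModel) -> tuple[set[str], list[set[str]]]:
        glob = {t.id for t in model.essential.terms}
        per = []
        for m in range(model.M):
            per.append(
                {model.essential.terms[s].id for s in range(model.S)
                 if model.weights[m, s] != 0.0}
            )
        return glob, per

    a_glob, a_per = _sets(model_a)
    b_glob, b_per = _sets(model_b)

    def _entry(a: set[str], b: set[str]) -> dict:
        return {
            "common": sorted(a & b),
            "only_a": sorted(a - b),
            "only_b": sorted(b - a),
            "n_common": len(a & b),
            "n_only_a": len(a - b),
            "n_only_b": len(b - a),
        }

    report = {"global": _entry(a_glob, b_glob), "per_location": {}}
    for m in range(model_a.M):
        report["per_location"][m + 1] = _entry(a_per[m], b_per[m])
    return report


def breakdown_consistency_error(
    model: LocalizationModel, xs: np.ndarray, location: int
) -> float:
    """|intercept + sum(feature scores) - s_m|; should be ~1e-12."""
    contributions = feature_breakdown(model, xs, location)
    total = model.intercepts[location - 1] + sum(c.feature_score for c in contributions)
    return abs(float(total - score(model, xs)[location - 1]))
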