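"""GO term-frequency feature vectors via homolog transfer.

A protein that lacks direct GO annotation inherits the annotation of its
closest annotated BLAST homolog.  The transferred GO multiset is converted
into a term-frequency vector over the vocabulary of distinct GO terms seen
in the training set: entry *j* counts how often the *j*-th vocabulary term
occurs among the protein's (transferred) annotations.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")
CATEGORIES = ("CC", "MF", "BP")

#: GAF "aspect" column letter -> taxonomy code.
_GAF_ASPECT = {"C": "CC", "F": "MF", "P": "BP"}


class ParseError(ValueError):
    """Malformed input line; message names the offending line number."""


class NullGoTerms(LookupError):
    """No homolog within reach carried any GO annotation."""


@dataclass(frozen=True, order=True)
class GoTerm:
    """A Gene Ontology identifier with its taxonomy (CC, MF or BP)."""

    id: str
    category: str

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise ValueError(f"malformed GO id {self.id!r} (expected GO: + 7 digits)")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown GO category {self.category!r} (expected one of {CATEGORIES})"
            )


# A multiset of GO terms is a Counter keyed by GoTerm with counts >= 1.
GoMultiset = Counter


@dataclass
class AnnotationDB:
    """Compact accession -> GO-term multiset database (ProSeq-GO style)."""

    entries: dict[str, Counter] = field(default_factory=dict)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, accession: str) -> Counter | None:
        return self.entries.get(accession)


@dataclass
class HomologMap:
    """Per query: subject accessions ordered best-first by BLAST rank."""

    hits: dict[str, list[str]] = field(default_factory=dict)

    def homologs(self, query_id: str) -> list[str]:
        return self.hits.get(query_id, [])


@dataclass(frozen=True)
class GoVocabulary:
    """Ordered set of the T distinct GO terms of a training set.

    Lexicographic id order makes feature vectors reproducible across runs.
    """

    terms: tuple[GoTerm, ...]
    index: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def position(self, term: GoTerm | str) -> int | None:
        term_id = term.id if isinstance(term, GoTerm) else term
        return self.index.get(term_id)


@dataclass
class GoVector:
    """Length-T non-negative integer term-frequency vector.

    ``dropped`` lists query terms absent from the vocabulary (not an error;
    the hierarchical mapping module can recover their information).
    """

    counts: np.ndarray
    dropped: tuple[GoTerm, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("term frequencies must be non-negative")


@dataclass
class Dataset:
    """N proteins with GO multisets (and/or a feature matrix) and label sets.

    Labels are 1-based locations in {1..M}; every protein has at least one.
    """

    ids: list[str]
    label_sets: list[set[int]]
    M: int
    multisets: list[Counter] | None = None
    X: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.label_sets):
            raise ValueError("ids and label_sets length mismatch")
        for i, y in enumerate(self.label_sets):
            if not y:
                raise ValueError(f"protein {self.ids[i]} has an empty label set")
            if any(lab < 1 or lab > self.M for lab in y):
                raise ValueError(f"protein {self.ids[i]} has a label outside 1..{self.M}")

    @property
    def N(self) -> int:
        return len(self.ids)


def _iter_lines(stream: IO[str] | Iterable[str]):
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        yield lineno, line


def load_annotation_db(stream: IO[str] | Iterable[str]) -> AnnotationDB:
    """Read a compact annotation TSV: accession, GO id, category[, count].

    Duplicate (accession, term) lines aggregate their counts.  Malformed GO
    ids or categories raise :class:`ParseError` naming the line number.
    """
    entries: dict[str, Counter] = {}
    n_rows = 0
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise ParseError(f"line {lineno}: expected 3 or 4 tab-separated columns")
        accession, go_id, category = fields[0], fields[1], fields[2]
        count = 1
        if len(fields) == 4:
            try:
                count = int(fields[3])
            except ValueError:
                raise ParseError(f"line {lineno}: count column is not an integer") from None
            if count < 1:
                raise ParseError(f"line {lineno}: count must be >= 1")
        try:
            term = GoTerm(go_id, category)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        entries.setdefault(accession, Counter())[term] += count
        n_rows += 1
    if n_rows == 0:
        raise ParseError("annotation database is empty")
    return AnnotationDB(entries)


def gaf_to_compact(stream: IO[str] | Iterable[str]) -> AnnotationDB:
    """Convert a GAF 2.x association file into a compact AnnotationDB.

    Uses the DB object id (column 2), GO id (column 5) and aspect
    (column 9, C/F/P) of each association line; '!' comments are skipped.
    """
    entries: dict[str, Counter] = {}
    n_rows = 0
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"line {lineno}: GAF line has fewer than 9 columns")
        accession, go_id, aspect = fields[1], fields[4], fields[8]
        if aspect not in _GAF_ASPECT:
            raise ParseError(f"line {lineno}: unknown GAF aspect {aspect!r}")
        try:
            term = GoTerm(go_id, _GAF_ASPECT[aspect])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        entries.setdefault(accession, Counter())[term] += 1
        n_rows += 1
    if n_rows == 0:
        raise ParseError("GAF file contains no association lines")
    return AnnotationDB(entries)


def load_blast_tab(stream: IO[str] | Iterable[str]) -> HomologMap:
    """Read BLAST tabular output (outfmt 6) into a best-first homolog map.

    Hits are ranked by ascending E-value, ties broken by descending bit
    score and then subject id; duplicate subjects keep their best-ranked hit.
    """
    per_query: dict[str, dict[str, tuple[float, float]]] = {}
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"line {lineno}: expected >= 12 outfmt-6 columns")
        qseqid, sseqid = fields[0], fields[1]
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError:
            raise ParseError(f"line {lineno}: bad evalue/bitscore") from None
        best = per_query.setdefault(qseqid, {})
        key = (evalue, -bitscore)
        if sseqid not in best or key < best[sseqid]:
            best[sseqid] = key
    hits = {
        q: [s for s, _ in sorted(subs.items(), key=lambda kv: (kv[1], kv[0]))]
        for q, subs in per_query.items()
    }
    return HomologMap(hits)


def retrieve_go_terms(
    query_id: str,
    homolog_map: HomologMap,
    db: AnnotationDB,
    max_homologs: int = 5,
    merge_top_k: int = 1,
    exclude_self: bool = True,
) -> Counter:
    """Transfer GO annotation from the best annotated homolog(s).

    Scans the ranked homolog list (at most ``max_homologs`` entries,
    skipping the query's own accession when ``exclude_self``).  By default
    the multiset of the first annotated homolog is returned unchanged;
    ``merge_top_k > 1`` instead merges counts across the top-k annotated
    homologs.  Raises :class:`NullGoTerms` if nothing annotated is found.
    """
    if max_homologs < 1:
        raise ValueError("max_homologs must be >= 1")
    candidates = homolog_map.homologs(query_id)
    if exclude_self:
        candidates = [h for h in candidates if h != query_id]
    merged: Counter = Counter()
    n_found = 0
    for accession in candidates[:max_homologs]:
        terms = db.get(accession)
        if not terms:
            continue
        merged.update(terms)
        n_found += 1
        if n_found >= merge_top_k:
            break
    if n_found == 0:
        raise NullGoTerms(
            f"no annotated homolog for {query_id!r} within the top {max_homologs}"
        )
    return merged


def build_vocabulary(multisets: Iterable[Counter]) -> GoVocabulary:
    """Distinct union of all training GO terms, in lexicographic id order."""
    distinct: dict[str, GoTerm] = {}
    n_sets = 0
    for multiset in multisets:
        n_sets += 1
        for term in multiset:
            distinct[term.id] = term
    if n_sets == 0:
        raise ValueError("cannot build a vocabulary from zero multisets")
    ordered = tuple(distinct[tid] for tid in sorted(distinct))
    index = {term.id: j for j, term in enumerate(ordered)}
    return GoVocabulary(ordered, index)


def build_go_vector(multiset: Counter, vocab: GoVocabulary) -> GoVector:
    """Count vocabulary-term occurrences; out-of-vocabulary terms are dropped."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    counts = np.zeros(len(vocab), dtype=np.int64)
    dropped: list[GoTerm] = []
    for term, n in multiset.items():
        j = vocab.position(term)
        if j is None:
            dropped.append(term)
        else:
            counts[j] += n
    return GoVector(counts, tuple(sorted(dropped)))


def build_feature_matrix(
    multisets: Sequence[Counter], vocab: GoVocabulary
) -> np.ndarray:
    """Stack per-protein term-frequency vectors into an N x T matrix."""
    X = np.zeros((len(multisets), len(vocab)), dtype=np.float64)
    for i, multiset in enumerate(multisets):
        X[i] = build_go_vector(multiset, vocab).counts
    return X
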