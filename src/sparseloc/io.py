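"""Plain-text file formats used by the command-line interface.

Feature/annotation files share the compact annotation TSV (accession,
GO id, category[, count]); label files map a protein id to one or more
1-based location labels separated by semicolons.  FASTA is read through
Biopython when sequences are needed for id matching.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable

from .go_features import Dataset, ParseError


def read_label_file(stream: IO[str] | Iterable[str], M: int) -> tuple[list[str], list[set[int]]]:
    """Read 'id<TAB>m1;m2;...' lines into ids and 1-based label sets."""
    ids: list[str] = []
    label_sets: list[set[int]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected 'id<TAB>labels'")
        try:
            labels = {int(tok) for tok in fields[1].replace(",", ";").split(";") if tok}
        except ValueError:
            raise ParseError(f"line {lineno}: labels must be integers") from None
        if not labels:
            raise ParseError(f"line {lineno}: empty label set")
        if any(m < 1 or m > M for m in labels):
            raise ParseError(f"line {lineno}: label outside 1..{M}")
        ids.append(fields[0])
        label_sets.append(labels)
    if not ids:
        raise ParseError("label file is empty")
    return ids, label_sets


def write_label_file(path: str | Path, ids: list[str], label_sets: list[set[int]]) -> None:
    with open(path, "w") as fh:
        for pid, labels in zip(ids, label_sets):
            fh.write(f"{pid}\t{';'.join(str(m) for m in sorted(labels))}\n")


def synthetic_term_id(j: int) -> str:
    """Stable synthetic GO id for feature column j of a simulated dataset."""
    return f"GO:{1000000 + j:07d}"


def write_dataset_features(path: str | Path, dataset: Dataset) -> None:
    """Write a simulated count matrix as a compact annotation TSV.

    Column j becomes the synthetic term :func:`synthetic_term_id`, with the
    three taxonomies assigned round-robin.
    """
    if dataset.X is None:
        raise ValueError("dataset has no feature matrix")
    categories = ("CC", "MF", "BP")
    with open(path, "w") as fh:
        for i, pid in enumerate(dataset.ids):
            row = dataset.X[i]
            for j in row.nonzero()[0]:
                fh.write(
                    f"{pid}\t{synthetic_term_id(int(j))}\t"
                    f"{categories[int(j) % 3]}\t{int(row[j])}\n"
                )


def read_fasta_ids(path: str | Path) -> list[str]:
    """Sequence ids of a FASTA file (for matching against label files)."""
    from Bio import SeqIO

    return [record.id for record in SeqIO.parse(str(path), "fasta")]
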