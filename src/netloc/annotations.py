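"""Subcellular location annotations over a fixed 11-term vocabulary.

Three annotation sources share one vocabulary: experimentally determined
locations (SCL) and the outputs of two sequence-based predictors (MP, YC).
A protein with no surviving annotation is "Unknown", represented everywhere
as the empty set — no sentinel term.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "LocationVocabulary",
    "VOCABULARY",
    "RawAnnotationRecord",
    "AnnotationTable",
    "MultiplicitySummary",
    "clean_records",
    "merge_mapped",
    "location_members",
    "multiplicity_summary",
    "read_annotation_tsv",
    "read_raw_annotation_tsv",
    "write_annotation_tsv",
    "read_two_column_map",
]

#: Annotation qualifiers that mark an experimental record as unreliable;
#: matched case-insensitively and dropped.
DISCARD_QUALIFIERS = frozenset({"probable", "by similarity", "potential"})


@dataclass(frozen=True)
class LocationVocabulary:
    """The ordered, fixed set of subcellular location terms (index k ↔ l_k)."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    @property
    def m(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __iter__(self):
        return iter(self.terms)

    def index(self, term: str) -> int:
        return self.terms.index(term)

    def validate(self, terms: Iterable[str]) -> frozenset[str]:
        out = frozenset(terms)
        unknown = out - set(self.terms)
        if unknown:
            raise ValueError(f"terms outside the vocabulary: {sorted(unknown)}")
        return out


#: The 11 human subcellular compartments used throughout the package.
VOCABULARY = LocationVocabulary((
    "Cell membrane", "Cytoplasm", "ER", "Extracell", "Golgi",
    "Mitochondrion", "Nucleus", "Peroxisome", "Lysosome", "Endosome",
    "Microsome",
))


@dataclass(frozen=True)
class RawAnnotationRecord:
    """One raw annotation line: protein, free-text location, optional qualifier."""

    protein_id: str
    location: str
    qualifier: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein ID must be non-empty")


class AnnotationTable:
    """Per-source mapping protein → subset of the location vocabulary.

    Proteins absent from the mapping behave identically to proteins assigned
    the empty set ("Unknown"); lookups never raise for unknown proteins.
    """

    def __init__(self, source: str,
                 assignments: Optional[Mapping[str, Iterable[str]]] = None,
                 vocabulary: LocationVocabulary = VOCABULARY) -> None:
        self.source = source
        self.vocabulary = vocabulary
        self._assign: dict[str, frozenset[str]] = {}
        if assignments:
            for p, terms in assignments.items():
                self[p] = terms

    def __setitem__(self, protein: str, terms: Iterable[str]) -> None:
        validated = self.vocabulary.validate(terms)
        if validated:
            self._assign[protein] = validated
        else:
            self._assign.pop(protein, None)

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self._assign.get(protein, frozenset())

    get = __getitem__

    def __len__(self) -> int:
        return len(self._assign)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._assign == other._assign

    @property
    def annotated_proteins(self) -> set[str]:
        """Proteins with at least one assigned location."""
        return set(self._assign)

    def items(self):
        return self._assign.items()

    def copy(self, source: Optional[str] = None) -> "AnnotationTable":
        out = AnnotationTable(source or self.source, vocabulary=self.vocabulary)
        out._assign = dict(self._assign)
        return out


@dataclass
class MultiplicitySummary:
    """Locations-per-protein histogram and the derived locative arithmetic.

    A protein carrying k locations counts as k "locative proteins"; the mean
    multiplicity degree is locative count / annotated protein count.
    """

    histogram: dict[int, int]
    n_annotated: int
    locative_count: int
    mean_multiplicity: Optional[float]  # rounded to 2 decimals; None if no proteins

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int]) -> "MultiplicitySummary":
        hist = {int(k): int(v) for k, v in histogram.items() if v}
        if any(k < 1 for k in hist):
            raise ValueError("multiplicity must be >= 1")
        n = sum(hist.values())
        locative = sum(k * v for k, v in hist.items())
        mean = round(locative / n, 2) if n else None
        return cls(histogram=hist, n_annotated=n, locative_count=locative,
                   mean_multiplicity=mean)


def clean_records(records: Sequence[RawAnnotationRecord],
                  term_map: Optional[Mapping[str, str]] = None,
                  source: str = "SCL",
                  vocabulary: LocationVocabulary = VOCABULARY,
                  ) -> AnnotationTable:
    """Drop unreliable and unmappable annotations; aggregate per protein.

    Records qualified "Probable", "By Similarity" or "Potential" (case
    insensitive) are discarded.  Remaining location text is mapped through
    ``term_map`` (defaulting to identity on the canonical terms); text that
    maps nowhere is dropped with a logged count.
    """
    if term_map is None:
        term_map = {t: t for t in vocabulary}
    table = AnnotationTable(source, vocabulary=vocabulary)
    sets: dict[str, set[str]] = {}
    n_qualifier = n_unmapped = 0
    for rec in records:
        if rec.qualifier.strip().lower() in DISCARD_QUALIFIERS:
            n_qualifier += 1
            continue
        term = term_map.get(rec.location.strip())
        if term is None or term not in vocabulary:
            n_unmapped += 1
            continue
        sets.setdefault(rec.protein_id, set()).add(term)
    for p, terms in sets.items():
        table[p] = terms
    if n_qualifier or n_unmapped:
        logger.info("dropped %d qualified and %d unmappable annotation records",
                    n_qualifier, n_unmapped)
    return table


def merge_mapped(id_map: Mapping[str, Iterable[str]],
                 external_table: AnnotationTable,
                 source: Optional[str] = None) -> AnnotationTable:
    """Project annotations from external IDs onto network IDs.

    A network protein's location set is the union over all external proteins
    it maps to; proteins with no mapping, or whose mapped externals carry no
    surviving annotation, end up "Unknown" (empty set).
    """
    out = AnnotationTable(source or external_table.source,
                          vocabulary=external_table.vocabulary)
    for network_id, externals in id_map.items():
        merged: set[str] = set()
        for ext in externals:
            merged |= external_table[ext]
        if merged:
            out[network_id] = merged
    return out


def location_members(table: AnnotationTable, l_k: str) -> set[str]:
    """S_k(src): the set of proteins annotated with location ``l_k``."""
    if l_k not in table.vocabulary:
        raise ValueError(f"{l_k!r} is not in the location vocabulary")
    return {p for p, terms in table.items() if l_k in terms}


def multiplicity_summary(table: AnnotationTable) -> MultiplicitySummary:
    """Histogram of locations per annotated protein plus locative arithmetic."""
    hist = Counter(len(terms) for _, terms in table.items())
    return MultiplicitySummary.from_histogram(hist)


# -- tabular IO ----------------------------------------------------------

def _iter_rows(path: str | Path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_annotation_tsv(path: str | Path, source: str,
                        vocabulary: LocationVocabulary = VOCABULARY,
                        ) -> AnnotationTable:
    """Read a cleaned table: protein_id <TAB> pipe-separated terms."""
    table = AnnotationTable(source, vocabulary=vocabulary)
    for row in _iter_rows(path):
        if len(row) < 2 or not row[1].strip():
            continue
        terms = [t.strip() for t in row[1].split("|") if t.strip()]
        table[row[0].strip()] = set(terms) | set(table[row[0].strip()])
    return table


def read_raw_annotation_tsv(path: str | Path) -> list[RawAnnotationRecord]:
    """Read raw records: protein_id <TAB> location [<TAB> qualifier]."""
    records = []
    n_bad = 0
    for row in _iter_rows(path):
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            n_bad += 1
            continue
        qualifier = row[2].strip() if len(row) > 2 else ""
        records.append(RawAnnotationRecord(row[0].strip(), row[1].strip(), qualifier))
    if n_bad:
        logger.warning("skipped %d malformed annotation lines", n_bad)
    return records


def write_annotation_tsv(table: AnnotationTable, path: str | Path) -> None:
    order = {t: i for i, t in enumerate(table.vocabulary)}
    with open(path, "w") as fh:
        for p in sorted(table.annotated_proteins):
            terms = sorted(table[p], key=order.__getitem__)
            fh.write(f"{p}\t{'|'.join(terms)}\n")


def read_two_column_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column mapping file into key → set of values (1:many)."""
    mapping: dict[str, set[str]] = {}
    for row in _iter_rows(path):
        if len(row) < 2:
            continue
        mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return mapping
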