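"""PPI network container, interaction filtering and edge clustering coefficients.

The edge clustering coefficient (ECC) of an interaction is the number of
triangles the edge participates in, divided by the largest number of triangles
it could possibly participate in given its endpoint degrees,
``min(d_i - 1, d_j - 1)``.  Densely embedded interactions score near 1 and are
the ones whose endpoints tend to share subcellular compartments; peripheral
interactions score near 0.  ``ecc_normalized`` rescales ECC over a vertex's
incident edges so the weights a protein assigns to its neighbors sum to one —
note this makes it asymmetric in its two arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "BiogridColumns",
    "FilterReport",
    "PPINetwork",
    "filter_interactions",
    "read_interaction_tsv",
    "write_edge_tsv",
    "read_edge_tsv",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction table, before filtering.

    ``interaction_type`` is "physical" / "non-physical" (or None when the
    input dialect has no such column); ``evidence`` is a free experimental
    system tag such as "Co-localization".
    """

    interactor_a: str
    interactor_b: str
    organism_a: Optional[str] = None
    organism_b: Optional[str] = None
    interaction_type: Optional[str] = None
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.interactor_a or not self.interactor_b:
            raise ValueError("interactor IDs must be non-empty")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered-pair identity of the interaction."""
        a, b = self.interactor_a, self.interactor_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BiogridColumns:
    """0-based column indices of a tab-separated interaction file.

    Defaults follow the BioGRID TAB 2.0 layout (BioGRID IDs in columns 3/4,
    experimental system in 11, system type in 12, organism taxids in 15/16).
    Set an index to None when the dialect lacks that column.
    """

    interactor_a: int = 3
    interactor_b: int = 4
    evidence: Optional[int] = 11
    interaction_type: Optional[int] = 12
    organism_a: Optional[int] = 15
    organism_b: Optional[int] = 16

    @classmethod
    def simple(cls) -> "BiogridColumns":
        """Plain 2-column edge list: interactors only."""
        return cls(interactor_a=0, interactor_b=1, evidence=None,
                   interaction_type=None, organism_a=None, organism_b=None)


@dataclass
class FilterReport:
    """Counts removed by each interaction-filtering rule, in application order."""

    n_input: int = 0
    removed_organism: int = 0
    removed_self_loops: int = 0
    collapsed_duplicates: int = 0
    removed_non_physical: int = 0
    removed_evidence: int = 0
    n_edges: int = 0
    n_proteins: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class PPINetwork:
    """Undirected simple graph of protein IDs with cached ECC machinery.

    IDs are opaque strings compared exactly (no case folding).  Self-loops and
    duplicate edges are rejected at construction; every edge endpoint is a
    vertex.  ECC values and per-vertex incident-ECC sums are computed lazily
    and cached, since prediction sweeps query the same edges repeatedly.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self._g = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in self._g.edges()):
            raise ValueError("self-loops are not allowed in a PPI network")
        self._ecc_cache: dict[tuple[str, str], float] = {}
        self._incident_sum: dict[str, float] = {}

    # -- construction ----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   vertices: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            g.add_edge(u, v)
        return cls(g)

    # -- basic queries ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) if u <= v else (v, u) for u, v in self._g.edges()}

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def _require_vertex(self, p: str) -> None:
        if p not in self._g:
            raise KeyError(f"unknown protein {p!r}")

    def _require_edge(self, u: str, v: str) -> None:
        self._require_vertex(u)
        self._require_vertex(v)
        if not self._g.has_edge(u, v):
            raise KeyError(f"no interaction between {u!r} and {v!r}")

    def degree(self, p: str) -> int:
        """Number of distinct interaction partners of ``p``."""
        self._require_vertex(p)
        return self._g.degree(p)

    def neighbors(self, p: str) -> set[str]:
        """The adjacency set NE(p); never contains ``p`` itself."""
        self._require_vertex(p)
        return set(self._g.neighbors(p))

    # -- edge clustering coefficient -------------------------------------
    def triangle_count(self, p_i: str, p_j: str) -> int:
        """Triangles through the edge p_i–p_j: |NE(p_i) ∩ NE(p_j)|."""
        self._require_edge(p_i, p_j)
        a = self._g.adj[p_i]
        b = self._g.adj[p_j]
        if len(a) > len(b):
            a, b = b, a
        return sum(1 for w in a if w in b)

    def ecc(self, p_i: str, p_j: str) -> float:
        """Edge clustering coefficient in [0, 1]; symmetric in its arguments.

        When ``min(d_i - 1, d_j - 1)`` is zero no triangle is possible and the
        edge carries no clustering evidence, so the value is defined as 0.
        """
        key = (p_i, p_j) if p_i <= p_j else (p_j, p_i)
        cached = self._ecc_cache.get(key)
        if cached is not None:
            return cached
        self._require_edge(p_i, p_j)
        denom = min(self._g.degree(p_i) - 1, self._g.degree(p_j) - 1)
        value = self.triangle_count(p_i, p_j) / denom if denom > 0 else 0.0
        self._ecc_cache[key] = value
        return value

    def _ecc_incident_sum(self, p: str) -> float:
        s = self._incident_sum.get(p)
        if s is None:
            s = sum(self.ecc(p, v) for v in self._g.adj[p])
            self._incident_sum[p] = s
        return s

    def ecc_normalized(self, p_u: str, p_v: str) -> float:
        """ECC_N(p_u, p_v): ECC rescaled over p_u's incident edges.

        Σ_{v ∈ NE(p_u)} ECC_N(p_u, p_v) = 1 for every non-isolated p_u, which
        makes it usable directly as a neighbor weight; it is asymmetric,
        ECC_N(u, v) ≠ ECC_N(v, u) in general.  When every edge incident to
        p_u has ECC 0 the weights fall back to uniform 1/|NE(p_u)| so the
        neighborhood degenerates to an unweighted vote rather than dividing
        by zero.  This method is the single swap point for the normalization.
        """
        self._require_edge(p_u, p_v)
        total = self._ecc_incident_sum(p_u)
        if total == 0.0:
            return 1.0 / self._g.degree(p_u)
        return self.ecc(p_u, p_v) / total


def filter_interactions(records: Sequence[InteractionRecord],
                        target_organism: Optional[str] = None,
                        drop_evidence_tags: Iterable[str] = (),
                        ) -> tuple[PPINetwork, FilterReport]:
    """Apply the interaction-curation rules and build the network.

    Rules, in order: (1) keep only records where both organisms equal
    ``target_organism`` (skipped, with a logged notice, when organism columns
    are absent or no target is given); (2) drop self-interactions; (3) collapse
    duplicate records to one edge per unordered pair; (4) drop pairs with no
    physical support (every record typed non-physical); (5) drop pairs whose
    only evidence tags are all in ``drop_evidence_tags`` — this supports
    excluding interactions supported solely by co-localization experiments.
    """
    drop_tags = set(drop_evidence_tags)
    report = FilterReport(n_input=len(records))

    kept: list[InteractionRecord] = []
    organism_filter_active = target_organism is not None
    for rec in records:
        if organism_filter_active:
            if rec.organism_a is None or rec.organism_b is None:
                # dialect lacks organism columns: filter silently skipped
                pass
            elif rec.organism_a != target_organism or rec.organism_b != target_organism:
                report.removed_organism += 1
                continue
        if rec.interactor_a == rec.interactor_b:
            report.removed_self_loops += 1
            continue
        kept.append(rec)
    if not organism_filter_active:
        logger.info("no target organism given: organism filter skipped")

    # collapse to unordered pairs, pooling type and evidence support
    pairs: dict[tuple[str, str], list[InteractionRecord]] = {}
    for rec in kept:
        pairs.setdefault(rec.pair, []).append(rec)
    report.collapsed_duplicates = len(kept) - len(pairs)

    edges: list[tuple[str, str]] = []
    for pair, recs in pairs.items():
        types = {r.interaction_type for r in recs}
        if None not in types and types and all(t == "non-physical" for t in types):
            report.removed_non_physical += 1
            continue
        tags = {r.evidence for r in recs if r.evidence is not None}
        if drop_tags and tags and tags <= drop_tags:
            report.removed_evidence += 1
            continue
        edges.append(pair)

    net = PPINetwork.from_edges(edges)
    report.n_edges = net.n_edges
    report.n_proteins = net.n_vertices
    logger.info("filtered %d records to %d interactions covering %d proteins",
                report.n_input, report.n_edges, report.n_proteins)
    return net, report


# -- tabular IO ----------------------------------------------------------

def _iter_data_lines(path: str | Path) -> Iterator[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_interaction_tsv(path: str | Path,
                         columns: Optional[BiogridColumns] = None,
                         ) -> list[InteractionRecord]:
    """Read interaction records from a tab-separated file.

    Lines starting with '#' are ignored.  Unparseable lines are skipped with
    a logged warning; optional columns missing from a short row are left None.
    """
    cols = columns if columns is not None else BiogridColumns()
    records: list[InteractionRecord] = []
    n_skipped = 0

    def pick(row: list[str], idx: Optional[int]) -> Optional[str]:
        if idx is None or idx >= len(row):
            return None
        value = row[idx].strip()
        return value or None

    for row in _iter_data_lines(path):
        a = pick(row, cols.interactor_a)
        b = pick(row, cols.interactor_b)
        if a is None or b is None:
            n_skipped += 1
            continue
        records.append(InteractionRecord(
            interactor_a=a,
            interactor_b=b,
            organism_a=pick(row, cols.organism_a),
            organism_b=pick(row, cols.organism_b),
            interaction_type=pick(row, cols.interaction_type),
            evidence=pick(row, cols.evidence),
        ))
    if n_skipped:
        logger.warning("skipped %d unparseable interaction lines", n_skipped)
    return records


def write_edge_tsv(net: PPINetwork, path: str | Path) -> None:
    """Write the network as a 2-column tab-separated edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_tsv(path: str | Path) -> PPINetwork:
    """Read a 2-column edge list written by :func:`write_edge_tsv`."""
    edges = []
    for row in _iter_data_lines(path):
        if len(row) < 2:
            continue
        edges.append((row[0].strip(), row[1].strip()))
    return PPINetwork.from_edges(edges)
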