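"""Synthetic fixtures: planted-partition networks, planted locations, noisy predictors.

The generator emulates the statistical structure the meta-predictor relies
on: community structure in the interaction network (within-community edges
are densely embedded, hence high ECC), true location sets correlated within
communities, experimental annotations covering only about half the proteins,
and two base predictors that are noisy, incomplete renditions of the truth.
Community memberships are retained as ground truth for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationTable, LocationVocabulary, VOCABULARY
from .evaluation import MetricsReport, jackknife, multilabel_metrics
from .network import PPINetwork
from .predictor import PredictorConfig

__all__ = ["SimulationConfig", "SyntheticNetwork", "SyntheticAnnotations",
           "simulate_network", "simulate_annotations", "simulate_dataset",
           "benchmark", "benchmark_replicates", "BENCHMARK_ARMS"]

#: Locations-per-protein distribution roughly matching the observed human
#: breakdown (~70% single-location, ~25% dual, few higher).
DEFAULT_MULTIPLICITY = {1: 0.70, 2: 0.25, 3: 0.04, 4: 0.01}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 1000 proteins in 10 communities with a strong within/
    between edge-probability contrast (0.3 vs 0.01), experimental coverage of
    half the proteins, and base predictors that flip each of the 11 labels
    independently with probability 0.2 while covering 90% of proteins.
    """

    n_proteins: int = 1000
    n_communities: int = 10
    p_within: float = 0.3
    p_between: float = 0.01
    annotation_coverage: float = 0.5
    multiplicity_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLICITY))
    predictor_error: float = 0.2
    predictor_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_communities < 1:
            raise ValueError("n_proteins and n_communities must be positive")
        if self.n_communities > self.n_proteins:
            raise ValueError("more communities than proteins")
        for name in ("p_within", "p_between", "annotation_coverage",
                     "predictor_error", "predictor_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.multiplicity_dist.values())
        if not np.isclose(total, 1.0):
            raise ValueError("multiplicity_dist probabilities must sum to 1")
        if any(k < 1 for k in self.multiplicity_dist):
            raise ValueError("multiplicities must be >= 1")


@dataclass
class SyntheticNetwork:
    """A planted-partition network plus its ground-truth communities."""

    network: PPINetwork
    communities: dict[str, int]


@dataclass
class SyntheticAnnotations:
    """Planted truth plus the three derived observation tables."""

    truth: AnnotationTable
    scl: AnnotationTable
    mp: AnnotationTable
    yc: AnnotationTable


def _protein_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"P{i:0{width}d}" for i in range(n)]


def simulate_network(config: SimulationConfig) -> SyntheticNetwork:
    """Planted-partition graph: dense within communities, sparse between.

    Community sizes differ by at most one when n_proteins does not divide
    evenly.  Reproducible from config.seed.
    """
    base, extra = divmod(config.n_proteins, config.n_communities)
    sizes = [base + (1 if c < extra else 0) for c in range(config.n_communities)]
    k = config.n_communities
    p_matrix = [[config.p_within if i == j else config.p_between
                 for j in range(k)] for i in range(k)]
    g = nx.stochastic_block_model(sizes, p_matrix,
                                  seed=int(config.seed) % (2**31))
    ids = _protein_ids(config.n_proteins)
    mapping = dict(zip(g.nodes(), ids))
    communities = {mapping[node]: g.nodes[node]["block"] for node in g.nodes()}
    relabeled = nx.relabel_nodes(nx.Graph(g.edges()), mapping)
    relabeled.add_nodes_from(ids)
    return SyntheticNetwork(network=PPINetwork(relabeled),
                            communities=communities)


def simulate_annotations(sim_net: SyntheticNetwork, config: SimulationConfig,
                         vocabulary: LocationVocabulary = VOCABULARY,
                         ) -> SyntheticAnnotations:
    """Plant true location sets and derive the three observation tables.

    Each community draws a primary location (without replacement while terms
    last); each protein's truth set is its community primary plus extra
    locations drawn uniformly from the remaining terms, with set size from
    ``multiplicity_dist``.  SCL restricts the truth to a random
    annotation_coverage fraction.  MP and YC flip each label independently
    with probability predictor_error on a predictor_coverage fraction of
    proteins; a covered prediction emptied by the flips is back-filled with
    one uniformly drawn true term so covered predictors always call
    something.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 7])
    terms = list(vocabulary)
    m = vocabulary.m

    k = config.n_communities
    if k <= m:
        primaries = list(rng.choice(m, size=k, replace=False))
    else:
        primaries = list(rng.choice(m, size=k, replace=True))

    mult_values = sorted(config.multiplicity_dist)
    mult_probs = np.array([config.multiplicity_dist[v] for v in mult_values])
    mult_probs = mult_probs / mult_probs.sum()

    proteins = sorted(sim_net.communities)
    truth = AnnotationTable("TRUTH", vocabulary=vocabulary)
    for p in proteins:
        primary = primaries[sim_net.communities[p]]
        size = min(int(rng.choice(mult_values, p=mult_probs)), m)
        others = [i for i in range(m) if i != primary]
        extras = rng.choice(len(others), size=size - 1, replace=False)
        labels = {primary} | {others[i] for i in extras}
        truth[p] = {terms[i] for i in labels}

    scl = AnnotationTable("SCL", vocabulary=vocabulary)
    covered = rng.random(len(proteins)) < config.annotation_coverage
    for p, has_scl in zip(proteins, covered):
        if has_scl:
            scl[p] = truth[p]

    def noisy_predictor(name: str) -> AnnotationTable:
        table = AnnotationTable(name, vocabulary=vocabulary)
        covered = rng.random(len(proteins)) < config.predictor_coverage
        flips = rng.random((len(proteins), m)) < config.predictor_error
        for i, p in enumerate(proteins):
            if not covered[i]:
                continue
            true_idx = {vocabulary.index(t) for t in truth[p]}
            called = {j for j in range(m)
                      if (j in true_idx) != bool(flips[i, j])}
            if not called:
                called = {int(rng.choice(sorted(true_idx)))}
            table[p] = {terms[j] for j in called}
        return table

    return SyntheticAnnotations(truth=truth, scl=scl,
                                mp=noisy_predictor("MP"),
                                yc=noisy_predictor("YC"))


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[SyntheticNetwork, SyntheticAnnotations]:
    """Convenience: network and annotations from one config."""
    sim_net = simulate_network(config)
    return sim_net, simulate_annotations(sim_net, config)


BENCHMARK_ARMS = ("MP", "YC", "META_MP", "META_YC", "META_BOTH")


def benchmark(config: SimulationConfig,
              predictor_config: Optional[PredictorConfig] = None,
              ) -> dict[str, MetricsReport]:
    """Compare base predictors and meta-predictor arms on one synthetic dataset.

    Arms: each simulated base predictor scored directly against the held-out
    experimental truth; the meta-predictor run with each single base
    predictor; and the meta-predictor run with both.  Meta arms are evaluated
    by jackknife over the SCL-annotated proteins; base arms are scored on the
    same proteins, so all five reports are directly comparable.
    """
    predictor_config = predictor_config or PredictorConfig()
    sim_net, ann = simulate_dataset(config)
    net = sim_net.network
    vocab = ann.truth.vocabulary
    empty = AnnotationTable("EMPTY", vocabulary=vocab)

    eval_truth = AnnotationTable("SCL", vocabulary=vocab)
    for p in sorted(ann.scl.annotated_proteins & net.vertices):
        eval_truth[p] = ann.scl[p]

    reports = {
        "MP": multilabel_metrics(ann.mp, eval_truth, vocab),
        "YC": multilabel_metrics(ann.yc, eval_truth, vocab),
        # single-predictor meta arms place the lone source in the MP slot so
        # that it also serves as the fallback
        "META_MP": jackknife(net, ann.scl, ann.mp, empty, predictor_config, vocab),
        "META_YC": jackknife(net, ann.scl, ann.yc, empty, predictor_config, vocab),
        "META_BOTH": jackknife(net, ann.scl, ann.mp, ann.yc, predictor_config, vocab),
    }
    return reports


def benchmark_replicates(config: SimulationConfig,
                         predictor_config: Optional[PredictorConfig] = None,
                         seeds: Sequence[int] = range(10),
                         ) -> pd.DataFrame:
    """Benchmark over several seeds; one row per (seed, arm)."""
    rows = []
    for seed in seeds:
        reports = benchmark(replace(config, seed=int(seed)), predictor_config)
        for arm, rep in reports.items():
            rows.append({"seed": int(seed), "arm": arm, "AIM": rep.aim,
                         "CVR": rep.cvr, "ACC": rep.acc, "ATR": rep.atr,
                         "AFR": rep.afr, "n": rep.n})
    return pd.DataFrame(rows)
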