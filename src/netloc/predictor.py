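"""Network meta-prediction of subcellular locations.

For a protein with no experimental annotation, evidence flows in from its
interaction partners: each of the three annotation sources (experimental SCL
and the two sequence predictors MP and YC) contributes, per location, a
membership degree that combines (i) the probability of observing that
location among the protein's annotated neighbors and (ii) the ECC-normalized
weights of the neighbors that carry it.  Per-source thresholding turns
memberships into candidate sets, and a final combination intersects
network-supported locations with direct sequence predictions, with an
argmax-consensus escape hatch and a fallback to the stronger sequence
predictor when everything else comes up empty.

The algorithm proceeds in four steps per protein:

1. neighbor location probabilities per source (``neighbor_location_probability``);
2. membership degrees weighting neighbors by ECC_N (``membership_degree``);
3. per-source predicted sets NET_src via the relative threshold C and the
   evidence gate θ_src (``network_prediction``);
4. combination into the final set PRED (``combine``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotations import AnnotationTable, LocationVocabulary, VOCABULARY
from .network import PPINetwork

__all__ = [
    "PredictorConfig",
    "MembershipProfile",
    "PredictionResult",
    "IterationResult",
    "neighbor_location_probability",
    "membership_degree",
    "network_prediction",
    "combine",
    "predict_protein",
    "predict_all",
    "iterate",
]

SOURCES = ("SCL", "MP", "YC")


@dataclass(frozen=True)
class PredictorConfig:
    """Calibration parameters of the meta-predictor.

    ``C`` is the relative membership threshold in [0, 1]: a location enters a
    source's network prediction when its membership reaches C times the
    source's maximal membership.  ``theta_src`` gates each source on a minimum
    number of src-annotated neighbors; below it the source predicts nothing.
    Defaults are the calibrated values C=0.75, θ_SCL=1, θ_MP=θ_YC=60.
    """

    C: float = 0.75
    theta_scl: int = 1
    theta_mp: int = 60
    theta_yc: int = 60
    fallback_source: str = "MP"

    def __post_init__(self) -> None:
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("C must lie in [0, 1]")
        for name in ("theta_scl", "theta_mp", "theta_yc"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.fallback_source not in ("MP", "YC"):
            raise ValueError("fallback_source must be 'MP' or 'YC'")

    def theta(self, src: str) -> int:
        return {"SCL": self.theta_scl, "MP": self.theta_mp,
                "YC": self.theta_yc}[src]

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(C=raw.get("C", 0.75),
                   theta_scl=raw.get("theta_SCL", 1),
                   theta_mp=raw.get("theta_MP", 60),
                   theta_yc=raw.get("theta_YC", 60),
                   fallback_source=raw.get("fallback_source", "MP"))

    def to_dict(self) -> dict:
        return {"C": self.C, "theta_SCL": self.theta_scl,
                "theta_MP": self.theta_mp, "theta_YC": self.theta_yc,
                "fallback_source": self.fallback_source}


@dataclass
class MembershipProfile:
    """Everything computed for one protein on the way to its prediction."""

    protein_id: str
    memberships: dict[str, np.ndarray]      # per source, over the vocabulary
    gates: dict[str, bool]                  # θ_src gate satisfied?
    net_sets: dict[str, frozenset[str]]     # NET_src
    seq: frozenset[str] = frozenset()
    net_seq: frozenset[str] = frozenset()
    net: frozenset[str] = frozenset()
    pred: frozenset[str] = frozenset()
    provenance: str = ""


def _membership_form(prob: float, weight_sum: float) -> float:
    """Membership from location probability and summed ECC_N neighbor weight.

    exp(prob) amplifies locations frequent among annotated neighbors; the
    ECC_N weight sum concentrates credit on densely embedded partners.  Zero
    weight (no neighbor carries the location) gives membership 0.  Single swap
    point for the functional form.
    """
    if weight_sum == 0.0:
        return 0.0
    return math.exp(prob) * weight_sum


def neighbor_location_probability(net: PPINetwork, table: AnnotationTable,
                                  p_u: str, l_k: str) -> float:
    """P_k: probability of observing location ``l_k`` among p_u's annotated neighbors.

    The fraction of src-annotated neighbors whose term set contains ``l_k``;
    0 when no neighbor carries an annotation from this source.
    """
    if l_k not in table.vocabulary:
        raise ValueError(f"{l_k!r} is not in the location vocabulary")
    annotated = [v for v in net.neighbors(p_u) if table[v]]
    if not annotated:
        return 0.0
    return sum(1 for v in annotated if l_k in table[v]) / len(annotated)


def membership_degree(net: PPINetwork, table: AnnotationTable,
                      p_u: str, l_k: str) -> float:
    """m_src(p_u, l_k): ECC_N-weighted, probability-amplified neighbor evidence."""
    prob = neighbor_location_probability(net, table, p_u, l_k)
    weight = sum(net.ecc_normalized(p_u, v) for v in net.neighbors(p_u)
                 if l_k in table[v])
    return _membership_form(prob, weight)


def membership_vector(net: PPINetwork, table: AnnotationTable, p_u: str,
                      vocabulary: LocationVocabulary = VOCABULARY,
                      ) -> tuple[np.ndarray, int]:
    """All 11 membership degrees for one source in a single neighborhood pass.

    Returns the membership vector and the number of src-annotated neighbors
    (the quantity the θ gate tests).
    """
    index = {t: i for i, t in enumerate(vocabulary)}
    counts = np.zeros(vocabulary.m)
    weights = np.zeros(vocabulary.m)
    n_annotated = 0
    for v in net.neighbors(p_u):
        terms = table[v]
        if not terms:
            continue
        n_annotated += 1
        w = net.ecc_normalized(p_u, v)
        for t in terms:
            k = index[t]
            counts[k] += 1
            weights[k] += w
    m = np.zeros(vocabulary.m)
    if n_annotated:
        probs = counts / n_annotated
        for k in range(vocabulary.m):
            m[k] = _membership_form(probs[k], weights[k])
    return m, n_annotated


def network_prediction(net: PPINetwork, table: AnnotationTable, p_u: str,
                       config: PredictorConfig, src: Optional[str] = None,
                       vocabulary: LocationVocabulary = VOCABULARY,
                       ) -> frozenset[str]:
    """NET_src(p_u): locations whose membership reaches C × the maximum.

    Empty when all memberships are 0 or when fewer than θ_src neighbors carry
    a src annotation (the evidence gate).  Threshold comparison is inclusive,
    so the argmax location is always included when the gate passes.
    """
    m, n_annotated = membership_vector(net, table, p_u, vocabulary)
    theta = config.theta(src or table.source)
    return _threshold_set(m, n_annotated, theta, config.C, vocabulary)


def _threshold_set(m: np.ndarray, n_annotated: int, theta: int, C: float,
                   vocabulary: LocationVocabulary) -> frozenset[str]:
    if n_annotated < theta:
        return frozenset()
    upper = m.max(initial=0.0)
    if upper == 0.0:
        return frozenset()
    cutoff = C * upper
    return frozenset(t for k, t in enumerate(vocabulary) if m[k] >= cutoff)


def combine(p_u: str,
            net_scl: frozenset[str], net_mp: frozenset[str],
            net_yc: frozenset[str],
            mp_u: frozenset[str], yc_u: frozenset[str],
            memberships: Mapping[str, np.ndarray],
            config: PredictorConfig,
            vocabulary: LocationVocabulary = VOCABULARY,
            ) -> tuple[frozenset[str], str]:
    """Combine per-source network sets and direct sequence predictions into PRED.

    SEQ = MP ∪ YC (direct sequence calls); NET_SEQ = NET_MP ∪ NET_YC;
    NET = NET_SCL ∪ NET_SEQ.  A location is predicted when it is in
    NET ∩ SEQ (condition 1) or attains the maximal membership in every source
    that has any evidence (condition 2; all-zero sources are skipped).  If
    both conditions yield nothing, the fallback source's direct prediction is
    used.  Returns the prediction and its provenance
    ("condition1" / "condition2" / "condition1+condition2" / "fallback").
    """
    seq = mp_u | yc_u
    net_all = net_scl | net_mp | net_yc
    cond1 = net_all & seq

    active = [src for src in SOURCES
              if src in memberships and memberships[src].max(initial=0.0) > 0.0]
    if active:
        cond2 = set(vocabulary)
        for src in active:
            m = memberships[src]
            upper = m.max()
            cond2 &= {t for k, t in enumerate(vocabulary) if m[k] == upper}
        cond2 = frozenset(cond2)
    else:
        cond2 = frozenset()

    pred = cond1 | cond2
    if pred:
        parts = []
        if cond1 & pred:
            parts.append("condition1")
        if cond2 - cond1:
            parts.append("condition2")
        return frozenset(pred), "+".join(parts)
    fallback = mp_u if config.fallback_source == "MP" else yc_u
    return frozenset(fallback), "fallback"


def predict_protein(net: PPINetwork, scl: AnnotationTable,
                    mp: AnnotationTable, yc: AnnotationTable,
                    p_u: str, config: PredictorConfig,
                    vocabulary: LocationVocabulary = VOCABULARY,
                    ) -> MembershipProfile:
    """Run the four prediction steps for one protein.

    The protein's own experimental annotation is never consulted, which is
    what makes this directly usable for leave-one-out evaluation.
    """
    tables = {"SCL": scl, "MP": mp, "YC": yc}
    memberships: dict[str, np.ndarray] = {}
    gates: dict[str, bool] = {}
    net_sets: dict[str, frozenset[str]] = {}
    for src, table in tables.items():
        m, n_annotated = membership_vector(net, table, p_u, vocabulary)
        theta = config.theta(src)
        memberships[src] = m
        gates[src] = n_annotated >= theta
        net_sets[src] = _threshold_set(m, n_annotated, theta, config.C,
                                       vocabulary)

    pred, provenance = combine(p_u, net_sets["SCL"], net_sets["MP"],
                               net_sets["YC"], mp[p_u], yc[p_u],
                               memberships, config, vocabulary)
    profile = MembershipProfile(
        protein_id=p_u, memberships=memberships, gates=gates,
        net_sets=net_sets,
        seq=frozenset(mp[p_u] | yc[p_u]),
        net_seq=net_sets["MP"] | net_sets["YC"],
        net=net_sets["SCL"] | net_sets["MP"] | net_sets["YC"],
        pred=pred, provenance=provenance)
    return profile


@dataclass
class PredictionResult:
    """Final per-protein location calls plus how each call was reached."""

    table: AnnotationTable
    provenance: dict[str, str] = field(default_factory=dict)


def predict_all(net: PPINetwork, scl: AnnotationTable,
                mp: AnnotationTable, yc: AnnotationTable,
                config: Optional[PredictorConfig] = None,
                vocabulary: LocationVocabulary = VOCABULARY,
                ) -> PredictionResult:
    """Predict every experimentally unannotated protein in the network.

    Proteins with a nonempty experimental set pass through unchanged.
    Deterministic given its inputs.
    """
    config = config or PredictorConfig()
    out = AnnotationTable("PRED", vocabulary=vocabulary)
    provenance: dict[str, str] = {}
    for p in sorted(net.vertices):
        truth = scl[p]
        if truth:
            out[p] = truth
            provenance[p] = "experimental"
            continue
        profile = predict_protein(net, scl, mp, yc, p, config, vocabulary)
        if profile.pred:
            out[p] = profile.pred
        provenance[p] = profile.provenance
    return PredictionResult(table=out, provenance=provenance)


@dataclass
class IterationResult:
    """Output of repeated self-application of the meta-predictor."""

    rounds: list[AnnotationTable]
    fixed_point_round: Optional[int]  # first 1-based round equal to its predecessor


def iterate(net: PPINetwork, scl: AnnotationTable,
            mp: AnnotationTable, yc: AnnotationTable,
            config: Optional[PredictorConfig] = None, rounds: int = 2,
            vocabulary: LocationVocabulary = VOCABULARY,
            ) -> IterationResult:
    """Iterative prediction: feed each round's output back in as the sole predictor.

    Round 1 integrates both sequence predictors; from round 2 onward the
    previous round's output occupies the MP slot (with θ_MP from the config)
    and the YC slot is emptied.  Because each round is a deterministic
    function of the previous table, once two consecutive rounds agree every
    later round is identical; the first such round is reported.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    config = config or PredictorConfig()
    empty_yc = AnnotationTable("YC", vocabulary=vocabulary)
    tables: list[AnnotationTable] = []
    fixed_point: Optional[int] = None
    current = predict_all(net, scl, mp, yc, config, vocabulary).table
    tables.append(current)
    for r in range(2, rounds + 1):
        fed = current.copy(source="MP")
        nxt = predict_all(net, scl, fed, empty_yc, config, vocabulary).table
        tables.append(nxt)
        if fixed_point is None and nxt == current:
            fixed_point = r
        current = nxt
    return IterationResult(rounds=tables, fixed_point_round=fixed_point)
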