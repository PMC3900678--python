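"""Multi-label performance measures, jackknife protocol and grid calibration.

Five measures summarize a multi-label predictor over n proteins with m
possible locations, P the predicted and T the true set per protein:

- AIM (aiming / precision):       mean |P ∩ T| / |P|
- CVR (coverage / recall):        mean |P ∩ T| / |T|
- ACC (accuracy / Jaccard):       mean |P ∩ T| / |P ∪ T|
- ATR (absolute-true rate):       fraction of proteins with P = T exactly
- AFR (absolute-false rate):      mean |P Δ T| / m  (Hamming loss)

AIM, CVR, ACC, ATR are higher-better; AFR is lower-better.  ATR is the
harshest measure: a single over- or under-predicted location voids the
protein.  A protein with an empty prediction contributes 0 to AIM rather
than being skipped, which would inflate it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationTable, LocationVocabulary, VOCABULARY
from .network import PPINetwork
from .predictor import PredictorConfig, predict_protein

__all__ = ["MetricsReport", "GridSpec", "multilabel_metrics", "jackknife",
           "grid_search"]


@dataclass(frozen=True)
class MetricsReport:
    """The five multi-label measures over an evaluation set of n proteins."""

    aim: float
    cvr: float
    acc: float
    atr: float
    afr: float
    n: int
    m: int = 11

    def rounded(self, ndigits: int = 3) -> dict:
        return {k: round(getattr(self, k), ndigits)
                for k in ("aim", "cvr", "acc", "atr", "afr")} | {
                    "n": self.n, "m": self.m}


def multilabel_metrics(pred: AnnotationTable, truth: AnnotationTable,
                       vocabulary: LocationVocabulary = VOCABULARY,
                       ) -> MetricsReport:
    """Score predictions against truth over all proteins with nonempty truth."""
    proteins = sorted(truth.annotated_proteins)
    if not proteins:
        raise ValueError("evaluation set is empty: no annotated proteins in truth")
    m = vocabulary.m
    aim = cvr = acc = atr = afr = 0.0
    for p in proteins:
        T = truth[p]
        P = pred[p]
        inter = len(P & T)
        aim += inter / len(P) if P else 0.0
        cvr += inter / len(T)
        acc += inter / len(P | T)
        atr += 1.0 if P == T else 0.0
        afr += len(P ^ T) / m
    n = len(proteins)
    return MetricsReport(aim=aim / n, cvr=cvr / n, acc=acc / n,
                         atr=atr / n, afr=afr / n, n=n, m=m)


def jackknife(net: PPINetwork, scl: AnnotationTable, mp: AnnotationTable,
              yc: AnnotationTable, config: Optional[PredictorConfig] = None,
              vocabulary: LocationVocabulary = VOCABULARY,
              ) -> MetricsReport:
    """Leave-one-out evaluation over the experimentally annotated proteins.

    Each SCL-annotated protein in the network is treated, in turn, as if it
    had no experimental annotation and re-predicted from its neighbors (whose
    annotations stay in place) plus its direct sequence predictions; the
    result is compared with the held-out truth.  Deterministic and
    independent of iteration order.
    """
    config = config or PredictorConfig()
    targets = sorted(scl.annotated_proteins & net.vertices)
    if len(targets) < 2:
        raise ValueError("jackknife needs at least 2 annotated proteins in the network")
    pred = AnnotationTable("PRED", vocabulary=vocabulary)
    truth = AnnotationTable("SCL", vocabulary=vocabulary)
    for p in targets:
        # the prediction steps never consult p's own experimental set,
        # so blanking it is implicit
        profile = predict_protein(net, scl, mp, yc, p, config, vocabulary)
        pred[p] = profile.pred
        truth[p] = scl[p]
    return multilabel_metrics(pred, truth, vocabulary)


@dataclass(frozen=True)
class GridSpec:
    """Calibration grid; θ_MP and θ_YC are tied to one shared value list."""

    c_values: tuple[float, ...]
    theta_scl_values: tuple[int, ...]
    theta_seq_values: tuple[int, ...]  # shared by θ_MP and θ_YC

    def __post_init__(self) -> None:
        if not (self.c_values and self.theta_scl_values and self.theta_seq_values):
            raise ValueError("all grid value lists must be nonempty")

    @property
    def n_trials(self) -> int:
        return (len(self.c_values) * len(self.theta_scl_values)
                * len(self.theta_seq_values))

    def configs(self):
        """Enumerate in C-outer, θ_SCL-middle, tied-θ-inner order."""
        for c, t_scl, t_seq in itertools.product(
                self.c_values, self.theta_scl_values, self.theta_seq_values):
            yield PredictorConfig(C=c, theta_scl=t_scl,
                                  theta_mp=t_seq, theta_yc=t_seq)

    @classmethod
    def default(cls) -> "GridSpec":
        """The calibration grid used for the human dataset: 10×20×10 = 2000 trials."""
        return cls(
            c_values=tuple(round(0.5 + 0.05 * i, 2) for i in range(10)),
            theta_scl_values=tuple(range(1, 21)),
            theta_seq_values=tuple(range(10, 101, 10)),
        )


def grid_search(net: PPINetwork, scl: AnnotationTable, mp: AnnotationTable,
                yc: AnnotationTable, grid: Optional[GridSpec] = None,
                objective: str = "atr",
                vocabulary: LocationVocabulary = VOCABULARY,
                ) -> tuple[PredictorConfig, pd.DataFrame]:
    """Exhaustive calibration by jackknife over the grid.

    Returns the first configuration (in enumeration order) attaining the
    maximal objective, plus the full trial table with one row per
    configuration.
    """
    grid = grid or GridSpec.default()
    if objective not in ("aim", "cvr", "acc", "atr", "afr"):
        raise ValueError(f"unknown objective {objective!r}")
    rows = []
    best_config: Optional[PredictorConfig] = None
    best_value = -np.inf
    for config in grid.configs():
        report = jackknife(net, scl, mp, yc, config, vocabulary)
        value = getattr(report, objective)
        if objective == "afr":
            value = -value  # lower is better
        rows.append({"C": config.C, "theta_SCL": config.theta_scl,
                     "theta": config.theta_mp,
                     "AIM": report.aim, "CVR": report.cvr, "ACC": report.acc,
                     "ATR": report.atr, "AFR": report.afr})
        if value > best_value:  # strict: ties keep the earlier config
            best_value = value
            best_config = config
    return best_config, pd.DataFrame(rows)
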