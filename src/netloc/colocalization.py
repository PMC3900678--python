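"""Co-localization score Q and its relationship with ECC.

Q for an interacting pair is the Jaccard overlap of the two experimental
location sets; it is undefined when either protein is unannotated.  Binning
interactions by ECC and averaging Q per bin exposes the (approximately
linear) trend that densely embedded interactions co-localize more often —
the empirical justification for weighting neighbor evidence by ECC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .annotations import AnnotationTable
from .network import PPINetwork

__all__ = ["colocalization_score", "EdgeScore", "BinStat", "ColocProfile",
           "edge_scores", "profile"]


def colocalization_score(set_i: Iterable[str],
                         set_j: Iterable[str]) -> Optional[float]:
    """Q_ij = |set_i ∩ set_j| / |set_i ∪ set_j|; None when either set is empty.

    1 iff the sets are identical (and nonempty); 0 iff they are disjoint.
    """
    a, b = frozenset(set_i), frozenset(set_j)
    if not a or not b:
        return None
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class EdgeScore:
    u: str
    v: str
    ecc: float
    q: float


@dataclass
class BinStat:
    lo: float
    hi: float
    n: int
    mean_ecc: Optional[float]
    mean_q: Optional[float]


@dataclass
class ColocProfile:
    """ECC-binned co-localization profile and its linear fit.

    Bins are left-closed right-open over [0, 1), with ECC = 1.0 folded into
    the last bin (cliques do occur).  The fit is ordinary least squares
    through the nonempty bins' (mean ECC, mean Q) points, as is the Pearson
    correlation r; with fewer than 2 nonempty bins the fit is omitted, and
    with zero variance in either coordinate slope and r are 0 by convention.
    """

    bins: list[BinStat]
    n_edges: int
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "bins": [vars(b) for b in self.bins],
        }


def edge_scores(net: PPINetwork, scl: AnnotationTable) -> list[EdgeScore]:
    """(ECC, Q) for every edge whose both endpoints carry experimental annotations."""
    out = []
    for u, v in sorted(net.edges):
        q = colocalization_score(scl[u], scl[v])
        if q is None:
            continue
        out.append(EdgeScore(u=u, v=v, ecc=net.ecc(u, v), q=q))
    return out


def profile(net: PPINetwork, scl: AnnotationTable, n_bins: int = 10,
            fit_on_bins: bool = True) -> ColocProfile:
    """Bin doubly-annotated edges by ECC; fit mean Q against mean ECC.

    ``fit_on_bins=False`` fits on the raw per-edge (ECC, Q) points instead of
    the bin means.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scores = edge_scores(net, scl)
    edges_ecc = np.array([s.ecc for s in scores])
    edges_q = np.array([s.q for s in scores])

    width = 1.0 / n_bins
    bins: list[BinStat] = []
    for k in range(n_bins):
        lo, hi = k * width, (k + 1) * width
        if k == n_bins - 1:
            mask = (edges_ecc >= lo) & (edges_ecc <= 1.0)
        else:
            mask = (edges_ecc >= lo) & (edges_ecc < hi)
        n = int(mask.sum())
        bins.append(BinStat(
            lo=lo, hi=hi, n=n,
            mean_ecc=float(edges_ecc[mask].mean()) if n else None,
            mean_q=float(edges_q[mask].mean()) if n else None,
        ))

    prof = ColocProfile(bins=bins, n_edges=len(scores))
    if fit_on_bins:
        xs = np.array([b.mean_ecc for b in bins if b.n])
        ys = np.array([b.mean_q for b in bins if b.n])
    else:
        xs, ys = edges_ecc, edges_q
    if len(xs) >= 2:
        if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
            prof.slope, prof.intercept, prof.r = 0.0, float(np.mean(ys)), 0.0
        else:
            fit = stats.linregress(xs, ys)
            prof.slope = float(fit.slope)
            prof.intercept = float(fit.intercept)
            prof.r = float(fit.rvalue)
    return prof
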