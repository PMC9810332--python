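"""Relevance correlation between phenotypes and its benchmarking metrics.

Two phenotypes' relevance profiles (R-score vectors over the same contexts)
are compared by Spearman rank correlation ("relevance correlation"), a proxy
for their phenotypic correlation.  Agreement between relevance correlations
and gold-standard phenotypic correlations over a set of phenotype pairs is
scored by Pearson correlation, mean squared error, and Kraskov-style
k-nearest-neighbour mutual information (in nats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma

logger = logging.getLogger(__name__)


def relevance_correlation(Rp: np.ndarray, Rq: np.ndarray) -> float:
    """Spearman correlation of two relevance profiles.

    Computed as Pearson on average ranks, which reduces to the classical
    1 - 6*sum(d^2)/(M(M^2-1)) formula exactly when ranks are tie-free
    (R vectors can tie at 0, hence the average-rank convention).
    """
    Rp = np.asarray(Rp, float)
    Rq = np.asarray(Rq, float)
    if Rp.shape != Rq.shape or Rp.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if len(Rp) < 3:
        raise ValueError("need at least 3 contexts")
    if np.ptp(Rp) == 0 or np.ptp(Rq) == 0:
        raise ValueError("relevance correlation undefined for a constant profile")
    rho, _ = stats.spearmanr(Rp, Rq)
    return float(rho)


def pairwise_relevance_matrix(profiles: dict[str, np.ndarray]) -> pd.DataFrame:
    """Square table of relevance correlations over all phenotype pairs."""
    ids = list(profiles)
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rho = relevance_correlation(profiles[a], profiles[b])
            out.loc[a, b] = out.loc[b, a] = rho
    return out


@dataclass
class MetricReport:
    pcc: float
    mse: float
    mi: float | None = None
    mi_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"pcc": self.pcc, "mse": self.mse,
                              "mi": self.mi, "mi_k": self.mi_k}])


def correlation_metrics(
    phenotypic: Sequence[float], relevance: Sequence[float]
) -> MetricReport:
    """Pearson correlation and mean squared error between the two pair-vectors.

    A zero-variance input leaves the Pearson coefficient undefined (NaN with
    a warning); the MSE is always returned.
    """
    x = np.asarray(phenotypic, float)
    y = np.asarray(relevance, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    mse = float(np.mean((x - y) ** 2))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("correlation_metrics: zero variance; PCC undefined")
        return MetricReport(pcc=float("nan"), mse=mse)
    pcc = float(np.corrcoef(x, y)[0, 1])
    return MetricReport(pcc=pcc, mse=mse)


def ksg_mutual_information(
    x: Sequence[float], y: Sequence[float], k: int = 3, seed: int = 0
) -> float:
    """Kraskov k-nearest-neighbour mutual information estimate, in nats.

    Algorithm 1 of the KSG estimator: for each point, eps is the max-norm
    distance to its k-th neighbour in the joint space; n_x and n_y count
    marginal neighbours strictly within eps, and

        MI = psi(k) + psi(n) - mean(psi(n_x + 1) + psi(n_y + 1)).

    Ties are broken by an infinitesimal seeded jitter (1e-10 * sd).
    """
    x = np.asarray(x, float).copy()
    y = np.asarray(y, float).copy()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have the same length")
    if n < 2 * k + 2:
        raise ValueError(f"need n >= {2 * k + 2} points for k={k}")
    rng = np.random.default_rng(seed)
    x += 1e-10 * max(x.std(), 1e-30) * rng.standard_normal(n)
    y += 1e-10 * max(y.std(), 1e-30) * rng.standard_normal(n)

    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([x, y]))
    # k+1 because the query point is its own nearest neighbour
    eps = tree.query(np.column_stack([x, y]), k=k + 1,
                     p=np.inf)[0][:, k]
    xs = np.sort(x)
    ys = np.sort(y)
    # strict inequality on both sides; subtract 1 for the point itself
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right") - 1)
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right") - 1)
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(nx + 1) + digamma(ny + 1)))


def profile_vector(frame: pd.DataFrame, kind: str = "r") -> np.ndarray:
    """Extract an ordering-stable context vector from a relevance table.

    ``kind``: "r" (R score, the default representation), "enrichment", or
    "neglogp" (ablation correlates).
    """
    if kind == "r":
        return frame["R"].to_numpy(float)
    if kind == "enrichment":
        return frame["enrichment"].to_numpy(float)
    if kind == "neglogp":
        return -np.log10(np.maximum(frame["p_enr"].to_numpy(float), 1e-300))
    raise ValueError(f"unknown kind {kind!r}")
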