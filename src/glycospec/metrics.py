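"""Spectral similarity metrics, multi-task loss and isomer-ranking score.

The single shared SA/DP transform lives here: SA = (2/pi)·arccos(DP), where
DP is the cosine similarity (normalized dot product) of two non-negative
intensity vectors.  All other modules import these functions so the identity
holds bit-consistently across the codebase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "dot_product",
    "spectral_angle",
    "sa_from_dp",
    "dp_from_sa",
    "total_loss",
    "dwa_update",
    "ranking_score",
    "LossWeights",
    "RankingWeights",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of (SA_total, SA_peptide, SA_glycan, MSE_ratio[, SA_B])."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0
    w5: float | None = None

    def __post_init__(self) -> None:
        vals = [self.w1, self.w2, self.w3, self.w4]
        if self.w5 is not None:
            vals.append(self.w5)
        if any(w < 0 for w in vals):
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class RankingWeights:
    alpha: float = 0.5
    beta: float = 0.5


def dot_product(s1, s2) -> float:
    """Cosine similarity of two non-negative intensity vectors (in [0, 1])."""
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("intensity vectors differ in length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("dot product undefined for an all-zero vector")
    return float(np.dot(a, b) / (na * nb))


def sa_from_dp(dp: float) -> float:
    """SA = (2/pi)·arccos(DP)."""
    return 2.0 / math.pi * math.acos(min(1.0, max(-1.0, dp)))


def dp_from_sa(sa: float) -> float:
    """Inverse transform: DP = cos(pi/2 · SA)."""
    return math.cos(math.pi / 2.0 * sa)


def spectral_angle(s1, s2) -> float:
    """Spectral angle loss in [0, 1]; 0 iff the vectors are proportional."""
    return sa_from_dp(dot_product(s1, s2))


def total_loss(
    sa_total: float,
    sa_pep: float,
    sa_gly: float,
    mse_ratio: float,
    w: LossWeights = LossWeights(),
    sa_B: float | None = None,
) -> float:
    """Weighted multi-task objective; the B term is added when supplied."""
    loss = w.w1 * sa_total + w.w2 * sa_pep + w.w3 * sa_gly + w.w4 * mse_ratio
    if sa_B is not None:
        w5 = 1.0 if w.w5 is None else w.w5
        loss += w5 * sa_B
    return loss


def dwa_update(
    loss_prev: Sequence[float],
    loss_prev2: Sequence[float],
    temperature: float = 2.0,
) -> np.ndarray:
    """Dynamic weight average over K tasks.

    ``r_k = L_k(t-1) / L_k(t-2)``; weights are ``K · softmax(r / T)`` so they
    always sum to the task count K.
    """
    l1 = np.asarray(loss_prev, dtype=float)
    l2 = np.asarray(loss_prev2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("need two equal-length loss vectors")
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("past losses must be positive for DWA")
    r = l1 / l2
    e = np.exp(r / temperature - np.max(r / temperature))
    return len(r) * e / e.sum()


def ranking_score(
    sa_Y: float, sa_B: float | None, w: RankingWeights = RankingWeights()
) -> float:
    """Isomer-ranking score: alpha·(1 − SA_Y) + beta·(1 − SA_B).

    When no B term is available (e.g. high-mannose glycans or a model without
    a B head) the score degrades to the Y term renormalized by alpha.
    """
    if sa_B is None:
        return (w.alpha * (1.0 - sa_Y)) / w.alpha if w.alpha else 0.0
    return w.alpha * (1.0 - sa_Y) + w.beta * (1.0 - sa_B)
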