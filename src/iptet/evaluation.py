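"""Model-fit statistics: RMSE, MAE and the Willmott index of agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalMetrics",
    "rmse",
    "mae",
    "mae_literal",
    "index_of_agreement",
    "slope_through_origin",
    "evaluate",
]


@dataclass(frozen=True)
class EvalMetrics:
    """Agreement statistics between observed and predicted series."""

    rmse: float
    mae: float
    d_ia: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "d_ia": self.d_ia, "n": self.n}

    def to_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.to_dict().items())


def _pairs(O, P):
    O = np.asarray(O, dtype=float)
    P = np.asarray(P, dtype=float)
    if O.shape != P.shape:
        raise ValueError(f"length mismatch: {O.shape} vs {P.shape}")
    if O.size == 0:
        raise ValueError("empty series")
    return O.ravel(), P.ravel()


def rmse(O, P) -> float:
    """Root mean square error of predictions P against observations O."""
    O, P = _pairs(O, P)
    return float(np.sqrt(np.mean((O - P) ** 2)))


def mae(O, P) -> float:
    """Mean absolute error, mean |O_i − P_i|."""
    O, P = _pairs(O, P)
    return float(np.mean(np.abs(O - P)))


def mae_literal(O, P) -> float:
    """Scatter of observations around the prediction mean, mean |O_i − P̄|.

    Not a pairwise error measure; kept only for comparison with sources
    that print this form under the MAE label.
    """
    O, P = _pairs(O, P)
    return float(np.mean(np.abs(O - P.mean())))


def index_of_agreement(O, P) -> float:
    """Willmott index of agreement d_IA ∈ [0, 1]; 1 iff O = P elementwise.

    d_IA = 1 − Σ(O_i − P_i)² / Σ(|P_i − Ō| + |O_i − Ō|)².
    """
    O, P = _pairs(O, P)
    obar = O.mean()
    denom = np.sum((np.abs(P - obar) + np.abs(O - obar)) ** 2)
    if denom == 0:
        raise ValueError(
            "index of agreement undefined: observations and predictions "
            "are all equal to the observation mean"
        )
    d = 1.0 - np.sum((O - P) ** 2) / denom
    # mathematically bounded in [0, 1]; clamp rounding spill at the edges
    return float(min(1.0, max(0.0, d)))


def slope_through_origin(O, P) -> float:
    """OLS slope of O on P with no intercept (the y = b·x regression)."""
    O, P = _pairs(O, P)
    denom = np.sum(P * P)
    if denom == 0:
        raise ValueError("predictions are identically zero")
    return float(np.sum(O * P) / denom)


def evaluate(O, P) -> EvalMetrics:
    """All three agreement statistics for one observed/predicted pair."""
    O, P = _pairs(O, P)
    return EvalMetrics(
        rmse=rmse(O, P), mae=mae(O, P), d_ia=index_of_agreement(O, P), n=O.size
    )
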