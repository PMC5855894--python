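"""Least-squares power-series score fusion.

The fused score of an N-modality score vector s = (s_1, ..., s_N) is

    S_f = lambda_0 + sum_{m=1..M} sum_{n=1..N} lambda_{m,n} * s_n^m

i.e. the dot product of lambda with the expansion
g(s) = [1, s_1, ..., s_N, s_1^2, ..., s_N^2, ..., s_1^M, ..., s_N^M]
(modality-major within each power). Stacking g(s_i) over k labelled samples
(targets y_i = 1 for the user class, 0 for imposters) gives the design
matrix; lambda minimizes ||y - g lambda||^2 / 2, solved by a numerically
stable least-squares factorization (equivalent to the normal equations
(g'g)^-1 g'y when g'g is nonsingular, and the pseudo-inverse solution when
it is not).

The accept/reject decision is S_f >= threshold (a tie accepts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScoreSample:
    """Per-modality match scores plus the true class (user=1, imposter=0)."""

    s: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (imposter) or 1 (user)")


@dataclass
class DesignMatrix:
    g: np.ndarray  # k x (1 + M*N)
    y: np.ndarray  # k targets in {0, 1}
    M: int
    N: int


@dataclass
class FusionModel:
    lam: np.ndarray   # (1 + M*N,) coefficients
    M: int
    N: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float).ravel()
        if self.lam.size != 1 + self.M * self.N:
            raise ValueError("lambda length must be 1 + M*N")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _expand(scores: np.ndarray, M: int) -> np.ndarray:
    """Power-series expansion rows [1, s.., s^2.., ..., s^M..]."""
    k, n = scores.shape
    cols = [np.ones((k, 1))]
    for m in range(1, M + 1):
        cols.append(scores ** m)
    return np.hstack(cols)


def build_design(scores: list[ScoreSample] | np.ndarray,
                 M: int,
                 labels: np.ndarray | None = None) -> DesignMatrix:
    """Build the k x (1 + M*N) design matrix, rows in input order."""
    if M < 1:
        raise ValueError("power-series order M must be >= 1")
    if isinstance(scores, np.ndarray):
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        if labels is None:
            raise ValueError("labels required with an array of scores")
        y = np.asarray(labels, dtype=float).ravel()
    else:
        lens = {s.s.size for s in scores}
        if len(lens) > 1:
            raise ValueError(f"inconsistent modality counts: {sorted(lens)}")
        S = np.vstack([s.s for s in scores])
        y = np.array([s.label for s in scores], dtype=float)
    if S.shape[0] != y.size:
        raise ValueError("scores and labels must have equal length")
    return DesignMatrix(g=_expand(S, M), y=y, M=M, N=S.shape[1])


def fit_fusion(design: DesignMatrix, threshold: float = 0.5) -> FusionModel:
    """Least-squares fit of the fusion coefficients.

    Rank-deficient designs fall through to the minimum-norm pseudo-inverse
    solution (same minimizer of the residual).
    """
    if design.g.size == 0:
        raise ValueError("empty design matrix")
    lam, *_ = np.linalg.lstsq(design.g, design.y, rcond=None)
    return FusionModel(lam=lam, M=design.M, N=design.N, threshold=threshold)


def fuse(model: FusionModel, s: np.ndarray) -> float:
    """Fused score g(s) . lambda for one score vector."""
    s = np.asarray(s, dtype=float).ravel()
    if s.size != model.N:
        raise ValueError(f"expected {model.N} modality scores, got {s.size}")
    row = _expand(s[None, :], model.M)[0]
    return float(row @ model.lam)


def fuse_batch(model: FusionModel, scores: np.ndarray) -> np.ndarray:
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[1] != model.N:
        raise ValueError(f"expected {model.N} modality scores per row")
    return _expand(S, model.M) @ model.lam


def decide(model: FusionModel, s_f: float) -> bool:
    """Accept iff the fused score reaches the threshold (tie accepts)."""
    return bool(s_f >= model.threshold)
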