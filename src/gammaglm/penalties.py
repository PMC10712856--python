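"""Sparsity penalties for the penalized gamma-divergence objective.

Implements the folded-concave SCAD and MCP penalties and the Lasso, all
scaled by a common tuning parameter ``lambda_n``, together with their first
derivatives.  Every member satisfies the class-P contract: nondecreasing on
[0, inf), zero at zero, with a continuous derivative on (0, inf).

SCAD (Fan & Li) with shape ``alpha > 2``::

    P(t) = lambda_n * t                                   t <= lambda_n
         = -(t^2 - 2*alpha*lambda_n*t + lambda_n^2)
           / (2*(alpha - 1))                              lambda_n < t <= alpha*lambda_n
         = (alpha + 1) * lambda_n^2 / 2                   t > alpha*lambda_n

MCP (Zhang) with shape ``v > 0``::

    P(t) = lambda_n * integral_0^t (1 - x/(lambda_n*v))_+ dx
         = lambda_n * t - t^2/(2*v)                       t <= lambda_n*v
         = lambda_n^2 * v / 2                             t > lambda_n*v

Lasso::

    P(t) = lambda_n * t
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["PenaltySpec", "penalty_value", "penalty_deriv"]

VALID_KINDS = ("none", "scad", "mcp", "lasso")

# Fan & Li's convention for the SCAD shape; the MCP shape default mirrors
# common practice for binary models.
DEFAULT_SCAD_ALPHA = 3.7
DEFAULT_MCP_V = 3.0


@dataclass(frozen=True)
class PenaltySpec:
    """Which penalty to apply and its tuning/shape parameters.

    Parameters
    ----------
    kind : {"none", "scad", "mcp", "lasso"}
    lambda_n : float
        Nonnegative tuning parameter; multiplies every penalty, including
        the Lasso.
    alpha : float
        SCAD shape parameter, must exceed 2.
    v : float
        MCP shape parameter, must be positive.
    """

    kind: str = "none"
    lambda_n: float = 1.0
    alpha: float = DEFAULT_SCAD_ALPHA
    v: float = DEFAULT_MCP_V

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}; expected one of {VALID_KINDS}")
        if not np.isfinite(self.lambda_n) or self.lambda_n < 0:
            raise ValueError(f"lambda_n must be finite and >= 0, got {self.lambda_n}")
        if self.kind == "scad" and not self.alpha > 2:
            raise ValueError(f"SCAD requires alpha > 2, got {self.alpha}")
        if self.kind == "mcp" and not self.v > 0:
            raise ValueError(f"MCP requires v > 0, got {self.v}")


def _check_nonnegative(t: NDArray[np.floating]) -> None:
    if np.any(t < 0):
        raise ValueError("penalty argument t must be nonnegative")


def penalty_value(t: ArrayLike, spec: PenaltySpec) -> NDArray[np.floating]:
    """Evaluate P_{lambda_n}(t) elementwise for t >= 0."""
    t = np.asarray(t, dtype=float)
    _check_nonnegative(t)
    lam = spec.lambda_n
    if spec.kind == "none" or lam == 0.0:
        return np.zeros_like(t)
    if spec.kind == "lasso":
        return lam * t
    if spec.kind == "scad":
        a = spec.alpha
        linear = lam * t
        quad = -(t * t - 2.0 * a * lam * t + lam * lam) / (2.0 * (a - 1.0))
        plateau = (a + 1.0) * lam * lam / 2.0
        return np.where(t <= lam, linear, np.where(t <= a * lam, quad, plateau))
    # mcp
    v = spec.v
    rising = lam * t - t * t / (2.0 * v)
    plateau = lam * lam * v / 2.0
    return np.where(t <= lam * v, rising, plateau)


def penalty_deriv(t: ArrayLike, spec: PenaltySpec) -> NDArray[np.floating]:
    """Evaluate P'_{lambda_n}(t) elementwise for t >= 0.

    The Lasso derivative is the constant ``lambda_n`` away from the origin;
    at t = 0 the subgradient value 0 is returned so that unpenalized
    stationary points of the smooth part remain stationary.
    """
    t = np.asarray(t, dtype=float)
    _check_nonnegative(t)
    lam = spec.lambda_n
    if spec.kind == "none" or lam == 0.0:
        return np.zeros_like(t)
    if spec.kind == "lasso":
        return np.where(t == 0.0, 0.0, lam)
    if spec.kind == "scad":
        a = spec.alpha
        middle = (a * lam - t) / (a - 1.0)
        return np.where(t <= lam, lam, np.where(t <= a * lam, middle, 0.0))
    # mcp
    return lam * np.clip(1.0 - t / (lam * spec.v), 0.0, None)
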