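"""Core gamma-divergence mathematics for binary GLMs.

The model is a binary GLM: the success probability is pi(x; beta) = h(x' beta)
with h the logistic sigmoid or the standard-normal CDF (probit).  Robustness
to mislabeled responses comes from replacing the log-likelihood with the
empirical gamma-divergence ("type-zero density power divergence") objective.
Each sample contributes

    phi_i = [pi_i^{y_i} (1 - pi_i)^{1 - y_i}]^gamma
            / [pi_i^{gamma+1} + (1 - pi_i)^{gamma+1}]^{gamma/(gamma+1)},

a quantity in (0, 1] that doubles as the sample's credibility weight omega_i:
small phi_i marks a likely mislabeled sample.  The penalized objective

    Q(beta) = sum_i phi_i - n * sum_j P_{lambda_n}(|beta_j|)

is MAXIMIZED; optimizers in :mod:`gammaglm.mgc` descend on -Q.  As
gamma -> 0, maximizing Q recovers ordinary maximum likelihood.

All probability work is done in the log domain with log-sum-exp so that
extreme linear predictors never overflow; probabilities are clipped to
[1e-12, 1 - 1e-12].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import log_expit, log_ndtr

from .penalties import PenaltySpec, penalty_deriv, penalty_value

__all__ = [
    "Dataset",
    "ModelConfig",
    "FitResult",
    "LINKS",
    "add_intercept",
    "success_prob",
    "sample_term",
    "sample_term_logit_form",
    "sample_gradients",
    "objective",
    "objective_gradient",
    "predict",
]

LINKS = ("logit", "probit")

PROB_CLIP = 1e-12
_LOG_CLIP_LO = np.log(PROB_CLIP)
_LOG_CLIP_HI = np.log1p(-PROB_CLIP)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _as_binary(v: ArrayLike, name: str) -> NDArray[np.int8]:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int8)


@dataclass
class Dataset:
    """A feature matrix with observed (possibly noisy) binary labels.

    ``y_true`` and ``flip_mask`` are optional ground-truth bookkeeping used
    by the simulation harness: when both are present, ``flip_mask[i]`` is
    true exactly when ``y_observed[i] != y_true[i]``.
    """

    X: NDArray[np.floating]
    y_observed: NDArray[np.int8]
    y_true: Optional[NDArray[np.int8]] = None
    flip_mask: Optional[NDArray[np.bool_]] = None
    feature_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        self.y_observed = _as_binary(self.y_observed, "y_observed")
        n = self.X.shape[0]
        if self.y_observed.shape != (n,):
            raise ValueError(
                f"y_observed has shape {self.y_observed.shape}, expected ({n},)")
        if self.y_true is not None:
            self.y_true = _as_binary(self.y_true, "y_true")
            if self.y_true.shape != (n,):
                raise ValueError("y_true length does not match X")
        if self.flip_mask is not None:
            self.flip_mask = np.asarray(self.flip_mask, dtype=bool)
            if self.flip_mask.shape != (n,):
                raise ValueError("flip_mask length does not match X")
            if self.y_true is not None and not np.array_equal(
                    self.flip_mask, self.y_observed != self.y_true):
                raise ValueError("flip_mask inconsistent with y_observed vs y_true")
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: ArrayLike) -> "Dataset":
        """Row subset (used for batching and train/test splitting)."""
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[idx],
            y_observed=self.y_observed[idx],
            y_true=None if self.y_true is None else self.y_true[idx],
            flip_mask=None if self.flip_mask is None else self.flip_mask[idx],
            feature_names=self.feature_names,
        )


@dataclass
class ModelConfig:
    """Hyperparameters for the penalized gamma-divergence fit.

    Defaults follow the standard operating point of the method:
    gamma = 0.5, lambda = 1, detection threshold Tv = 0.5 and learning
    rate eta = 0.01.
    """

    gamma: float = 0.5
    link: str = "logit"
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    learning_rate: float = 0.01
    threshold: float = 0.5          # Tv: weights below it are flagged noisy
    max_epochs: int = 500
    batch_size: Union[int, str] = "full"
    tol: float = 1e-6
    sparsity_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold Tv must lie in [0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size != "full" and (not isinstance(self.batch_size, (int, np.integer)) or self.batch_size < 1):
            raise ValueError("batch_size must be a positive integer or 'full'")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    """Output of a fit: coefficients, per-sample weights and diagnostics.

    ``beta`` is the raw iterate; ``beta_sparse`` zeroes entries smaller in
    magnitude than the reporting tolerance (plain gradient iterations never
    land on exact zeros).  ``weights`` are the phi_i in (0, 1] evaluated at
    ``beta``; ``noisy_flags`` marks weights below the detection threshold.
    """

    beta: NDArray[np.floating]
    beta_sparse: NDArray[np.floating]
    weights: NDArray[np.floating]
    noisy_flags: NDArray[np.bool_]
    objective_trace: NDArray[np.floating]
    converged: bool
    n_epochs_run: int

    def __post_init__(self) -> None:
        if len(self.objective_trace) != self.n_epochs_run:
            raise ValueError("objective_trace length must equal n_epochs_run")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Link functions and probabilities
# ---------------------------------------------------------------------------

def add_intercept(X: ArrayLike) -> NDArray[np.floating]:
    """Prepend a constant-1 column (the model itself carries no intercept)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _check_beta(X: NDArray, beta: ArrayLike) -> NDArray[np.floating]:
    beta = np.asarray(beta, dtype=float).ravel()
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but beta has length {beta.shape[0]}")
    if not np.isfinite(beta).all():
        raise ValueError("beta contains non-finite entries")
    return beta


def _log_probs(z: NDArray, link: str) -> tuple[NDArray, NDArray]:
    """Return (log pi, log(1 - pi)) evaluated overflow-safely and clipped."""
    if link == "logit":
        logp, log1mp = log_expit(z), log_expit(-z)
    elif link == "probit":
        logp, log1mp = log_ndtr(z), log_ndtr(-z)
    else:
        raise ValueError(f"link must be one of {LINKS}, got {link!r}")
    return (np.clip(logp, _LOG_CLIP_LO, _LOG_CLIP_HI),
            np.clip(log1mp, _LOG_CLIP_LO, _LOG_CLIP_HI))


def success_prob(X: ArrayLike, beta: ArrayLike, link: str = "logit") -> NDArray[np.floating]:
    """P(Y = 1 | x) = h(x' beta), strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = _check_beta(X, beta)
    logp, _ = _log_probs(X @ beta, link)
    return np.exp(logp)


# ---------------------------------------------------------------------------
# The per-sample gamma-divergence term phi_i (= detection weight omega_i)
# ---------------------------------------------------------------------------

def _log_phi(logp: NDArray, log1mp: NDArray, y: NDArray, gamma: float) -> NDArray:
    g1 = gamma + 1.0
    log_lik = np.where(y == 1, logp, log1mp)
    # log S with S = pi^{g+1} + (1-pi)^{g+1}, via log-sum-exp
    log_s = np.logaddexp(g1 * logp, g1 * log1mp)
    return gamma * log_lik - (gamma / g1) * log_s


def sample_term(X: ArrayLike, y: ArrayLike, beta: ArrayLike,
                gamma: float, link: str = "logit") -> NDArray[np.floating]:
    """Per-sample objective term / credibility weight phi_i in (0, 1]."""
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValueError(f"gamma must be positive, got {gamma}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = _check_beta(X, beta)
    y = _as_binary(y, "y")
    logp, log1mp = _log_probs(X @ beta, link)
    return np.exp(_log_phi(logp, log1mp, y, gamma))


def sample_term_logit_form(X: ArrayLike, y: ArrayLike, beta: ArrayLike,
                           gamma: float) -> NDArray[np.floating]:
    """Logistic-specific algebraic form of phi_i,

        [exp{y (gamma+1) x'beta} / (1 + exp{(gamma+1) x'beta})]^{gamma/(gamma+1)},

    kept as an independent route for cross-checking the general form.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = _check_beta(X, beta)
    y = np.asarray(y, dtype=float).ravel()
    # clip the predictor to the range implied by the probability clip so
    # this route matches the clipped general form exactly
    z_max = _LOG_CLIP_HI - _LOG_CLIP_LO
    z = (gamma + 1.0) * np.clip(X @ beta, -z_max, z_max)
    # log of the bracket: y*z - log(1 + e^z) = (y-1)*z + log_expit(z) stably
    log_bracket = np.where(y == 1, log_expit(z), log_expit(z) - z)
    return np.exp((gamma / (gamma + 1.0)) * log_bracket)


def sample_gradients(X: ArrayLike, y: ArrayLike, beta: ArrayLike,
                     gamma: float, link: str = "logit"
                     ) -> tuple[NDArray[np.floating], NDArray[np.floating]]:
    """Per-sample terms and their gradients.

    Returns
    -------
    phi : (n,) array
        The per-sample weights phi_i.
    grad : (n, d) array
        Row i is d phi_i / d beta.  The chain rule gives
        d phi/d z = phi * gamma * [(y - pi)/(pi(1-pi))
                     - (pi^gamma - (1-pi)^gamma)/S] * h'(z).
    """
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValueError(f"gamma must be positive, got {gamma}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = _check_beta(X, beta)
    y = _as_binary(y, "y")
    z = X @ beta
    logp, log1mp = _log_probs(z, link)
    phi = np.exp(_log_phi(logp, log1mp, y, gamma))

    g1 = gamma + 1.0
    log_s = np.logaddexp(g1 * logp, g1 * log1mp)
    # (pi^gamma - (1-pi)^gamma) / S, each term evaluated in the log domain
    s_ratio = np.exp(gamma * logp - log_s) - np.exp(gamma * log1mp - log_s)
    pi = np.exp(logp)

    if link == "logit":
        # h'(z) = pi (1 - pi) cancels the likelihood-score denominator
        dlog_dz = gamma * ((y - pi) - s_ratio * np.exp(logp + log1mp))
    else:
        # probit: h'(z) = standard normal pdf; pdf/(pi(1-pi)) stays bounded
        log_pdf = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
        score = np.exp(log_pdf - logp - log1mp) * (y - pi)
        dlog_dz = gamma * (score - s_ratio * np.exp(log_pdf))

    dphi_dz = phi * dlog_dz
    if not np.isfinite(dphi_dz).all():
        bad = int(np.flatnonzero(~np.isfinite(dphi_dz))[0])
        raise FloatingPointError(f"non-finite per-sample gradient at sample index {bad}")
    return phi, dphi_dz[:, None] * X


# ---------------------------------------------------------------------------
# Objective Q and its gradient
# ---------------------------------------------------------------------------

def _penalty_total(beta: NDArray, spec: PenaltySpec) -> float:
    return float(penalty_value(np.abs(beta), spec).sum())


def objective(dataset: Dataset, beta: ArrayLike, config: ModelConfig) -> float:
    """Penalized objective Q(beta) = sum_i phi_i - n * sum_j P(|beta_j|).

    Higher is better; optimizers minimize -Q.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    phi = sample_term(dataset.X, dataset.y_observed, beta, config.gamma, config.link)
    return float(phi.sum() - dataset.n * _penalty_total(beta, config.penalty))


def objective_gradient(dataset: Dataset, beta: ArrayLike, config: ModelConfig
                       ) -> NDArray[np.floating]:
    """Analytic gradient of Q; the penalty uses subgradient 0 at beta_j = 0."""
    beta = np.asarray(beta, dtype=float).ravel()
    _, grads = sample_gradients(dataset.X, dataset.y_observed, beta,
                                config.gamma, config.link)
    pen = penalty_deriv(np.abs(beta), config.penalty) * np.sign(beta)
    return grads.sum(axis=0) - dataset.n * pen


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(X: ArrayLike, beta: ArrayLike, link: str = "logit") -> NDArray[np.int8]:
    """Label 1 when the fitted success probability is >= 1/2, else 0."""
    return (success_prob(X, beta, link) >= 0.5).astype(np.int8)
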