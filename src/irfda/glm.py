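"""Functional logistic regression on FPCA scores.

One binary Bernoulli-logit model per functional group: the linear
predictor is the intercept plus the inner product of the coefficient
function with the centered spectrum, which in the PC basis reduces to a
plain logistic regression on the K scores.  Fitting is maximum likelihood
by iteratively reweighted least squares with step-halving; perfectly
separated responses are detected and refit with a small ridge on the
slope coefficients.  Imbalanced groups can be rebalanced beforehand by
seeded minority oversampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .fpca import FpcaBasis, ScoreMatrix
from .io import GROUPS


class SeparationWarning(UserWarning):
    """Emitted when a group model is perfectly separable."""


@dataclass(frozen=True)
class GroupClassifier:
    """Fitted logistic model for one functional group."""

    group: str
    intercept: float
    coefficients: np.ndarray  # (K,)
    threshold: float = 0.5
    basis_ref: str = ""
    separation: bool = False
    stderr: np.ndarray | None = None  # (K+1,) intercept first, if available

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown functional group {self.group!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )

    @property
    def k(self) -> int:
        return int(self.coefficients.size)

    def save(self, path: str | Path) -> None:
        payload = {
            "group": self.group,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "threshold": self.threshold,
            "basis_ref": self.basis_ref,
            "separation": self.separation,
            "stderr": None if self.stderr is None else list(self.stderr),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GroupClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            group=d["group"],
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            threshold=float(d["threshold"]),
            basis_ref=d.get("basis_ref", ""),
            separation=bool(d.get("separation", False)),
            stderr=None if d.get("stderr") is None else np.asarray(d["stderr"]),
        )


def oversample_minority(
    scores: np.ndarray,
    labels: np.ndarray,
    target_count: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample positive rows with replacement up to ``target_count``.

    The original positives are kept and additional positives are drawn
    with replacement (seeded) until exactly ``target_count`` positive rows
    exist; negatives are untouched.  The combined rows are then shuffled
    deterministically by the same seed.
    """
    labels = np.asarray(labels, dtype=bool)
    pos_idx = np.flatnonzero(labels)
    if pos_idx.size == 0:
        raise ValueError("oversampling requires at least one positive example")
    if target_count < pos_idx.size:
        raise ValueError(
            f"target_count {target_count} below current positive count {pos_idx.size}"
        )
    rng = np.random.default_rng(seed)
    extra = rng.choice(pos_idx, size=target_count - pos_idx.size, replace=True)
    keep = np.concatenate([np.arange(labels.size), extra])
    order = rng.permutation(keep.size)
    keep = keep[order]
    return np.asarray(scores)[keep], labels[keep]


@dataclass
class _IrlsResult:
    beta: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    cov: np.ndarray | None


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(1 + exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol_ll: float = 1e-8,
    tol_grad: float = 1e-6,
) -> _IrlsResult:
    """Newton/IRLS with step-halving; ridge applies to slopes, not intercept."""
    n, d = x.shape
    beta = np.zeros(d)
    mask = np.ones(d)
    mask[0] = 0.0  # intercept unpenalized
    pen = ridge * mask

    def objective(b: np.ndarray) -> float:
        return _bernoulli_loglik(x @ b, y) - 0.5 * float(np.sum(pen * b**2))

    ll = objective(beta)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        wdiag = np.clip(p * (1.0 - p), 1e-12, None)
        grad = x.T @ (y - p) - pen * beta
        if np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
        hess = (x * wdiag[:, None]).T @ x + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving until the penalized log-likelihood improves
        new_ll = objective(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_ll = objective(beta + step)
            halvings += 1
        beta = beta + step
        if new_ll - ll < tol_ll:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # separation heuristic: near-perfect fit with runaway coefficients
    eta = x @ beta
    p = expit(eta)
    deviance = -2.0 * _bernoulli_loglik(eta, y)
    if (deviance < 1e-6 and np.max(np.abs(beta)) > 10.0) or np.max(np.abs(beta)) > 1e3:
        separated = True

    cov = None
    if not separated:
        wdiag = np.clip(p * (1.0 - p), 1e-12, None)
        hess = (x * wdiag[:, None]).T @ x + np.diag(pen)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = None
    return _IrlsResult(beta, objective(beta), converged, separated, cov)


def fit_group_model(
    scores: ScoreMatrix | np.ndarray,
    labels: np.ndarray,
    group: str,
    threshold: float = 0.5,
    max_iter: int = 100,
    ridge_on_separation: float = 1e-4,
    basis_ref: str = "",
) -> GroupClassifier:
    """Fit one group's logistic model by MLE on the PC scores.

    If perfect separation is detected the model is refit with a small
    ridge on the slope coefficients and flagged, with a warning.
    """
    f = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    y = np.asarray(labels, dtype=float)
    if f.shape[0] != y.size:
        raise ValueError("scores and labels disagree in length")
    if y.min() == y.max():
        raise ValueError(f"{group}: both classes must be present to fit")
    x = np.column_stack([np.ones(y.size), f])
    res = _irls(x, y, ridge=0.0, max_iter=max_iter)
    separated = res.separated
    if separated:
        warnings.warn(
            f"{group}: perfect separation detected; refitting with ridge "
            f"{ridge_on_separation} on the slopes",
            SeparationWarning,
            stacklevel=2,
        )
        res = _irls(x, y, ridge=ridge_on_separation, max_iter=max_iter)
    stderr = None
    if res.cov is not None:
        stderr = np.sqrt(np.clip(np.diag(res.cov), 0.0, None))
    return GroupClassifier(
        group=group,
        intercept=float(res.beta[0]),
        coefficients=res.beta[1:],
        threshold=threshold,
        basis_ref=basis_ref,
        separation=separated,
        stderr=stderr,
    )


def predict_probability(model: GroupClassifier, score_row: np.ndarray) -> float:
    """Logistic transform of the linear predictor for one compound."""
    f = np.asarray(score_row, dtype=float)
    if f.shape != (model.k,):
        raise ValueError(f"score row length {f.shape} does not match K={model.k}")
    return float(expit(model.intercept + model.coefficients @ f))


def predict_probabilities(model: GroupClassifier, scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    f = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    if f.shape[1] != model.k:
        raise ValueError(f"score columns {f.shape[1]} do not match K={model.k}")
    return expit(model.intercept + f @ model.coefficients)


def classify(model: GroupClassifier, probability: float) -> bool:
    """Positive when the probability strictly exceeds the threshold."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    return probability > model.threshold


def coefficient_function(model: GroupClassifier, basis: FpcaBasis) -> np.ndarray:
    """Evaluate beta(alpha) = sum_k beta_k phi_k(alpha) on the grid."""
    if model.basis_ref and model.basis_ref != basis.basis_id:
        raise ValueError("model was fitted on a different basis")
    if model.k > basis.k_max:
        raise ValueError("model has more coefficients than the basis has components")
    return model.coefficients @ basis.eigenfunctions[: model.k]
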