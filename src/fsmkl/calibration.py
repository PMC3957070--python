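"""Sigmoid posterior calibration, ambiguous-label pruning and cautious
prediction.

The SVM margin value f is mapped to a class-+1 posterior with the sigmoid

    p(+1 | f) = 1 / (1 + exp(A f + B)),

(A, B) fitted by minimizing the cross-entropy of the training decisions
against targets ``t_i = (y_i + 1)/2``, using Levenberg-Marquardt damping of
the Newton step.  On separable decision values the unsmoothed maximum
likelihood diverges (A -> -inf); Platt-style target smoothing
``t+ = (N+ + 1)/(N+ + 2)``, ``t- = 1/(N- + 2)`` (on by default) keeps the fit
well-posed.

Two uses of the posterior:

* pruning — training samples whose own label has posterior below a threshold
  (0.8 in the reference protocol) are removed and the model refitted once;
* cautious prediction — a label is emitted only when max(p, 1-p) reaches the
  confidence threshold (0.95 in the reference protocol), otherwise the
  classifier abstains; the coverage/accuracy tradeoff over thresholds is the
  classifier's operating curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .mkl_core import MklModel, decision_values

__all__ = [
    "SigmoidParams",
    "PredictionSet",
    "CalibrationError",
    "fit_sigmoid",
    "posterior",
    "calibrate_model",
    "remove_ambiguous",
    "cautious_predict",
    "coverage_accuracy_curve",
]


class CalibrationError(RuntimeError):
    """Sigmoid fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: tuple[float, float]):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class SigmoidParams:
    """Slope/offset of the posterior sigmoid.  A is negative whenever larger
    decision values favor class +1."""

    A: float
    B: float


def posterior(f, params: SigmoidParams) -> np.ndarray:
    """p(+1 | f) = 1/(1 + exp(A f + B)), kept strictly inside (0, 1)."""
    f = np.asarray(f, dtype=float)
    p = expit(-(params.A * f + params.B))
    return np.clip(p, 1e-300, 1.0 - 1e-16)


def _cross_entropy(f: np.ndarray, t: np.ndarray, A: float, B: float) -> float:
    z = A * f + B
    # -sum t log p + (1-t) log(1-p) with p = sigma(-z); stable via logaddexp:
    # log p = -log(1+e^z), log(1-p) = z - log(1+e^z)
    lse = np.logaddexp(0.0, z)
    return float(np.sum(t * lse + (1.0 - t) * (lse - z)))


def fit_sigmoid(f, labels, smooth_targets: bool = True,
                max_iter: int = 500, grad_tol: float = 1e-8,
                damping: float = 1e-3) -> SigmoidParams:
    """Fit (A, B) by cross-entropy minimization with Levenberg-Marquardt
    damping (damping x10 on a rejected step, /10 on an accepted one; stop at
    gradient norm < ``grad_tol`` or after ``max_iter`` iterations).

    With ``smooth_targets`` the class targets are shrunk Platt-style, which
    keeps the optimum finite even when the decision values separate the
    classes; without it, separable inputs raise :class:`CalibrationError`.
    """
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(labels.y if hasattr(labels, "y") else labels,
                   dtype=float).ravel()
    if f.size != y.size:
        raise ValueError("decision values and labels differ in length")
    if f.size < 4:
        raise ValueError("sigmoid fit requires at least 4 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("sigmoid fit requires both classes")

    n_pos = float(np.sum(y > 0))
    n_neg = float(np.sum(y < 0))
    if smooth_targets:
        t_pos = (n_pos + 1.0) / (n_pos + 2.0)
        t_neg = 1.0 / (n_neg + 2.0)
    else:
        t_pos, t_neg = 1.0, 0.0
    t = np.where(y > 0, t_pos, t_neg)

    # start at the constant predictor matching the base rate
    A = 0.0
    B = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    E = _cross_entropy(f, t, A, B)
    lam = damping

    for _ in range(max_iter):
        p = expit(-(A * f + B))
        r = t - p                     # dE/dz = p - t with z = A f + B
        gA = float(np.sum(r * f))     # dE/dA
        gB = float(np.sum(r))
        gnorm = float(np.hypot(gA, gB))
        if gnorm < grad_tol:
            _check_divergence(E, f.size, smooth_targets, A, B)
            return SigmoidParams(A=A, B=B)
        w = p * (1.0 - p)
        hAA = float(np.sum(w * f * f))
        hAB = float(np.sum(w * f))
        hBB = float(np.sum(w))
        H = np.array([[hAA + lam, hAB], [hAB, hBB + lam]])
        try:
            dA, dB = np.linalg.solve(H, [-gA, -gB])
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        if np.hypot(dA, dB) < 1e-10 * (1.0 + np.hypot(A, B)):
            _check_divergence(E, f.size, smooth_targets, A, B)
            return SigmoidParams(A=A, B=B)   # step below float resolution
        E_try = _cross_entropy(f, t, A + dA, B + dB)
        if E_try < E:
            A, B = A + dA, B + dB
            E = E_try
            lam = max(lam / 10.0, 1e-12)
        else:
            lam *= 10.0
    _check_divergence(E, f.size, smooth_targets, A, B)
    raise CalibrationError(
        f"sigmoid fit did not converge in {max_iter} iterations "
        f"(gradient norm {gnorm:.2e}); decision values may be separable — "
        "enable target smoothing", (A, B)
    )


def _check_divergence(E: float, n: int, smooth_targets: bool,
                      A: float, B: float) -> None:
    # with hard 0/1 targets a vanishing cross-entropy means the decision
    # values are separable and the likelihood has no finite maximizer
    if not smooth_targets and E < 1e-6 * n:
        raise CalibrationError(
            "cross-entropy vanished: decision values are separable and "
            "A diverges to -inf; enable target smoothing", (A, B)
        )


def calibrate_model(model: MklModel, bank, smooth_targets: bool = True,
                    ) -> MklModel:
    """Fit the posterior sigmoid on the model's own training decision values
    and store (A, B) on the model (returned for chaining)."""
    f = _training_decisions(model, bank)
    params = fit_sigmoid(f, model.y_train, smooth_targets=smooth_targets)
    model.calibration = (params.A, params.B)
    return model


def _training_decisions(model: MklModel, bank) -> np.ndarray:
    comp = np.tensordot(model.weights, bank.stack(), axes=1)
    return comp @ (model.alpha * model.y_train) + model.bias


def _own_label_posterior(model: MklModel, f: np.ndarray) -> np.ndarray:
    if model.calibration is None:
        raise ValueError("calibration required")
    p_pos = posterior(f, SigmoidParams(*model.calibration))
    return np.where(model.y_train > 0, p_pos, 1.0 - p_pos)


def remove_ambiguous(model: MklModel, bank, labels,
                     theta_train: float = 0.8) -> np.ndarray:
    """Indices of training samples whose own-label posterior is >= theta_train.

    Samples strictly below the threshold are ambiguous and dropped (the
    boundary is kept); the caller refits on the retained set — one pruning
    round only.  Raises if pruning would empty a class.
    """
    if not (0.0 <= theta_train < 1.0):
        raise ValueError("theta_train must lie in [0, 1)")
    y = np.asarray(labels.y if hasattr(labels, "y") else labels, dtype=int)
    if not np.array_equal(y, model.y_train):
        raise ValueError("labels do not match the model's training labels")
    f = _training_decisions(model, bank)
    p_own = _own_label_posterior(model, f)
    retained = np.flatnonzero(p_own >= theta_train - 1e-12)  # boundary kept
    if retained.size == 0 or len(np.unique(y[retained])) < 2:
        raise ValueError("pruning removed an entire class")
    return retained


@dataclass
class PredictionSet:
    """Per-sample decision value, posterior and (possibly abstaining) label."""

    sample_ids: list[str]
    f: np.ndarray
    posterior: np.ndarray        # p(+1 | f)
    predicted: np.ndarray        # +1 / -1; meaningful only where not abstained
    abstained: np.ndarray        # bool mask
    theta_predict: float
    coverage: float
    accuracy: float | None = None   # on the predicted subset, when labels known

    def to_frame(self) -> pd.DataFrame:
        label = [("ABSTAIN" if a else str(int(p)))
                 for p, a in zip(self.predicted, self.abstained)]
        return pd.DataFrame({
            "sample": self.sample_ids, "f": self.f,
            "posterior": self.posterior, "label": label,
        })


def cautious_predict(model: MklModel, projected: np.ndarray,
                     theta_predict: float = 0.95,
                     labels=None,
                     sample_ids: list[str] | None = None) -> PredictionSet:
    """Predict only where max(p, 1-p) >= theta_predict, else abstain.

    Coverage is the predicted fraction; accuracy (over the predicted subset)
    is reported when true labels are supplied.
    """
    if model.calibration is None:
        raise ValueError("calibration required")
    if not (0.5 <= theta_predict < 1.0):
        raise ValueError("theta_predict must lie in [0.5, 1)")
    f = decision_values(model, projected)
    p = posterior(f, SigmoidParams(*model.calibration))
    conf = np.maximum(p, 1.0 - p)
    abstained = conf < theta_predict - 1e-12   # exact boundary predicts
    predicted = np.where(f >= 0, 1, -1)
    coverage = float(np.mean(~abstained))
    accuracy = None
    if labels is not None:
        y = np.asarray(labels.y if hasattr(labels, "y") else labels, dtype=int)
        mask = ~abstained
        if mask.any():
            accuracy = float(np.mean(predicted[mask] == y[mask]))
    if sample_ids is None:
        sample_ids = [str(i) for i in range(f.size)]
    return PredictionSet(sample_ids=list(sample_ids), f=f, posterior=p,
                         predicted=predicted, abstained=abstained,
                         theta_predict=theta_predict, coverage=coverage,
                         accuracy=accuracy)


def coverage_accuracy_curve(model: MklModel, projected: np.ndarray,
                            labels, theta_grid) -> pd.DataFrame:
    """Coverage and accuracy of the cautious classifier over a threshold grid.

    One row per theta; coverage is non-increasing in theta and accuracy is NaN
    where nothing is predicted.
    """
    theta_grid = list(theta_grid)
    if not theta_grid:
        raise ValueError("theta grid is empty")
    rows = []
    for theta in theta_grid:
        ps = cautious_predict(model, projected, theta_predict=float(theta),
                              labels=labels)
        n_pred = int(np.sum(~ps.abstained))
        rows.append({
            "theta": float(theta), "n_predicted": n_pred,
            "coverage": ps.coverage,
            "accuracy": ps.accuracy if n_pred else float("nan"),
        })
    return pd.DataFrame(rows)
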