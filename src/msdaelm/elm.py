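"""Extreme learning machine (ELM) with three output-weight solvers.

An ELM is a single-hidden-layer feedforward network whose input weights ω
and biases b are drawn at random and never trained; only the output weight
matrix φ is solved, linearly, from the hidden-layer response

    G[i, j] = g(ω_j · x_i + b_j).

Solvers:

``pinv``
    minimum-norm least squares, φ = G⁺Y (Moore–Penrose pseudoinverse).
``ridge_closed_form`` (default)
    the closed form φ = (GᵀG + (1/β)I)⁻¹ GᵀY, kept verbatim with the 1/β
    placement — note that a *larger* β therefore means *weaker*
    regularization (β = 0.05 is a penalty of 20), the opposite of the usual
    +βI convention in the ELM literature.
``l1_coordinate_descent``
    the lasso problem min_φ ½‖Gφ − Y‖² + β‖φ‖₁ solved per output column by
    coordinate descent, yielding sparse output weights.

The ridge closed form and the L1 objective are distinct problems (an L1
problem has no such closed form); both are exposed so either reading can be
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.linear_model import Lasso

from .data import LabeledFeatureSet
from .errors import ConfigurationError, InputError

__all__ = [
    "ELMModel",
    "elm_init",
    "hidden_output",
    "solve_pinv",
    "solve_ridge_closed_form",
    "solve_l1",
    "elm_fit_predict",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    """Random hidden layer plus (optionally solved) output weights."""

    input_weights: np.ndarray  # ω, (n_features, L)
    biases: np.ndarray  # b, (L,)
    hidden_size: int
    activation: str
    output_weights: np.ndarray | None = None  # φ, (L, n_classes)
    beta: float = 0.05
    solver: str = "ridge_closed_form"
    seed: int = 0

    def sparsity(self) -> int:
        """Number of exactly zero output-weight entries (0 when unsolved)."""
        if self.output_weights is None:
            return 0
        return int(np.sum(self.output_weights == 0.0))


def elm_init(
    n_features: int, L: int = 1000, activation: str = "sigmoid", seed: int = 0
) -> ELMModel:
    """Draw ω and b i.i.d. uniform on [−1, 1] from a seeded generator."""
    if n_features < 1 or L < 1:
        raise ConfigurationError("n_features and L must be positive")
    if activation not in _ACTIVATIONS:
        raise ConfigurationError(
            f"activation must be one of {sorted(_ACTIVATIONS)}"
        )
    rng = np.random.default_rng(seed)
    omega = rng.uniform(-1.0, 1.0, size=(n_features, L))
    b = rng.uniform(-1.0, 1.0, size=L)
    return ELMModel(omega, b, L, activation, seed=seed)


def hidden_output(X: np.ndarray, model: ELMModel) -> np.ndarray:
    """Hidden-layer response G with G[i, j] = g(ω_j · x_i + b_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_weights.shape[0]:
        raise InputError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.input_weights.shape[0]})"
        )
    return _ACTIVATIONS[model.activation](X @ model.input_weights + model.biases)


def solve_pinv(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights φ = G⁺Y."""
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape[0] != Y.shape[0]:
        raise InputError("G and Y must have equal row counts")
    return np.linalg.pinv(G) @ Y


def solve_ridge_closed_form(G: np.ndarray, Y: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """φ = (GᵀG + (1/β)I)⁻¹ GᵀY — the regularized closed form, verbatim.

    Solved as a symmetric positive-definite system; larger β means weaker
    regularization under this 1/β placement.
    """
    if beta <= 0:
        raise ConfigurationError(f"beta must be > 0, got {beta}")
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape[0] != Y.shape[0]:
        raise InputError("G and Y must have equal row counts")
    L = G.shape[1]
    A = G.T @ G + (1.0 / beta) * np.eye(L)
    return scipy.linalg.solve(A, G.T @ Y, assume_a="pos")


def solve_l1(
    G: np.ndarray, Y: np.ndarray, beta: float = 0.05,
    tol: float = 1e-6, max_iter: int = 100_000,
) -> np.ndarray:
    """Lasso output weights: min_φ ½‖Gφ − y‖² + β‖φ‖₁ per output column.

    Solved by coordinate descent (scikit-learn backend, objective rescaled
    to its 1/(2n) convention).  Raises if the solver hits ``max_iter``
    without reaching ``tol``.
    """
    if beta <= 0:
        raise ConfigurationError(f"beta must be > 0, got {beta}")
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if G.shape[0] != Y.shape[0]:
        raise InputError("G and Y must have equal row counts")
    n = G.shape[0]
    cols = []
    for j in range(Y.shape[1]):
        lasso = Lasso(alpha=beta / n, fit_intercept=False, tol=tol,
                      max_iter=max_iter)
        import warnings as _w

        from sklearn.exceptions import ConvergenceWarning
        with _w.catch_warnings():
            _w.simplefilter("error", category=ConvergenceWarning)
            try:
                lasso.fit(G, Y[:, j])
            except ConvergenceWarning as w:
                raise RuntimeError(
                    f"L1 solver did not reach tolerance {tol} within "
                    f"{max_iter} sweeps on output column {j}: {w}"
                ) from w
        cols.append(lasso.coef_.copy())
    return np.stack(cols, axis=1)


_SOLVERS = {
    "pinv": lambda G, Y, beta: solve_pinv(G, Y),
    "ridge_closed_form": solve_ridge_closed_form,
    "l1_coordinate_descent": solve_l1,
}
# CLI-friendly aliases
_SOLVERS["ridge"] = _SOLVERS["ridge_closed_form"]
_SOLVERS["l1"] = _SOLVERS["l1_coordinate_descent"]


def elm_fit_predict(
    train: LabeledFeatureSet,
    test: LabeledFeatureSet,
    L: int = 1000,
    activation: str = "sigmoid",
    beta: float = 0.05,
    solver: str = "ridge_closed_form",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ELMModel]:
    """Fit an ELM on one-hot labels and score a test set.

    Returns ``(scores, predicted_labels, model)`` where ``scores`` is the
    raw output matrix G_test·φ; the class-1 column is the ROC score and the
    predicted label is the argmax.
    """
    if train.labels is None:
        raise InputError("training set must be labeled")
    if test.n_features != train.n_features:
        raise InputError(
            f"test feature dimension {test.n_features} does not match "
            f"train ({train.n_features})"
        )
    if solver not in _SOLVERS:
        raise ConfigurationError(
            f"solver must be one of {sorted(_SOLVERS)}, got {solver!r}"
        )
    classes = np.unique(train.labels)
    Y = np.zeros((train.n_samples, len(classes)))
    for k, c in enumerate(classes):
        Y[train.labels == c, k] = 1.0
    model = elm_init(train.n_features, L, activation, seed)
    model.beta = beta
    model.solver = solver
    G = hidden_output(train.features, model)
    model.output_weights = _SOLVERS[solver](G, Y, beta)
    scores = hidden_output(test.features, model) @ model.output_weights
    predicted = classes[np.argmax(scores, axis=1)]
    return scores, predicted, model
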