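"""Kernel extreme learning machine binary classifier.

Training solves the regularized dual system (I/c + K) w = y in closed
form, where K is the Gaussian kernel matrix of the training inputs with
themselves, c the regularization coefficient (larger c = weaker
regularization) and y the {+1, -1} label encoding. Prediction is the
kernel expansion score k(x, X_train) . w with a sign decision; a score of
exactly 0 maps to +1.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

__all__ = ["KELMModel", "gaussian_kernel_matrix", "kelm_train", "kelm_predict"]


@dataclass
class KELMModel:
    train_inputs: np.ndarray
    train_labels: np.ndarray  # {+1, -1}
    kernel_width: float
    regularization: float
    dual_weights: np.ndarray

    def save(self, path) -> None:
        """Serialize to a flat text file (inputs, labels, k, c, weights)."""
        with open(path, "w") as fh:
            fh.write(f"kernel_width\t{self.kernel_width!r}\n")
            fh.write(f"regularization\t{self.regularization!r}\n")
            for name, arr in (
                ("train_inputs", self.train_inputs),
                ("train_labels", self.train_labels),
                ("dual_weights", self.dual_weights),
            ):
                buf = io.StringIO()
                np.savetxt(buf, np.atleast_2d(arr), delimiter="\t")
                body = buf.getvalue().strip("\n")
                fh.write(f"[{name}]\n{body}\n")

    @classmethod
    def load(cls, path) -> "KELMModel":
        sections: dict[str, list[str]] = {}
        scalars: dict[str, float] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("[") and line.endswith("]"):
                    current = line[1:-1]
                    sections[current] = []
                elif current is None:
                    key, val = line.split("\t")
                    scalars[key] = float(val)
                else:
                    sections[current].append(line)

        def arr(name):
            return np.loadtxt(io.StringIO("\n".join(sections[name])), delimiter="\t")

        return cls(
            train_inputs=np.atleast_2d(arr("train_inputs")),
            train_labels=np.atleast_1d(arr("train_labels")),
            kernel_width=scalars["kernel_width"],
            regularization=scalars["regularization"],
            dual_weights=np.atleast_1d(arr("dual_weights")),
        )


def gaussian_kernel_matrix(A: np.ndarray, B: np.ndarray, kernel_width: float) -> np.ndarray:
    """Gaussian kernel matrix, entry (i, j) = exp(-||A_i - B_j||^2 / (2 k^2))."""
    if kernel_width <= 0:
        raise ValueError(f"kernel_width must be positive, got {kernel_width}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column mismatch: A has {A.shape[1]} features, B has {B.shape[1]}"
        )
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * kernel_width**2))


def _encode_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = np.unique(y)
    if not np.all(np.isin(vals, (-1, 1))):
        raise ValueError(f"labels must be in {{+1, -1}}, got values {vals}")
    if vals.size < 2:
        warnings.warn("degenerate training set: only one class present", stacklevel=3)
    return y.astype(float)


def kelm_train(
    X: np.ndarray, y: np.ndarray, regularization: float, kernel_width: float
) -> KELMModel:
    """Fit the KELM by solving (K + I/c) w = y with a symmetric solver.

    Falls back to least squares if the factorization fails (k near 0 can
    make K numerically singular even with the ridge term).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yv = _encode_labels(y)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if regularization <= 0:
        raise ValueError(f"regularization must be positive, got {regularization}")
    K = gaussian_kernel_matrix(X, X, kernel_width)
    system = K + np.eye(n) / regularization
    try:
        w = solve(system, yv, assume_a="pos")
    except np.linalg.LinAlgError:
        w, *_ = np.linalg.lstsq(system, yv, rcond=None)
    if not np.all(np.isfinite(w)):
        raise ArithmeticError(
            f"KELM solve produced non-finite weights (k={kernel_width}, c={regularization})"
        )
    return KELMModel(
        train_inputs=X,
        train_labels=yv.copy(),
        kernel_width=kernel_width,
        regularization=regularization,
        dual_weights=w,
    )


def kelm_predict(model: KELMModel, X_new: np.ndarray):
    """Score and classify new samples; returns ``(scores, labels)``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.empty(0), np.empty(0)
    X_new = np.atleast_2d(X_new)
    if X_new.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"feature mismatch: model trained on {model.train_inputs.shape[1]} "
            f"features, got {X_new.shape[1]}"
        )
    Knew = gaussian_kernel_matrix(X_new, model.train_inputs, model.kernel_width)
    scores = Knew @ model.dual_weights
    labels = np.where(scores >= 0.0, 1.0, -1.0)
    return scores, labels
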