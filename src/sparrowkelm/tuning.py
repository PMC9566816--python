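"""Self-adaptive search of the KELM hyperparameters (k, c).

The enhanced sparrow search runs over a 2-dimensional log2 box with
10-fold cross-validated misclassification (1 - mean ACC) as fitness; the
fold partition is fixed for the whole tuning run so candidates are
comparable. The incumbent is transformed back to (k_opt, c_opt).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .data_io import Dataset, kfold_indices
from .egssa import EGSSAConfig, optimize_egssa
from .metrics import compute_metrics, confusion

__all__ = ["TuneConfig", "TuneResult", "cv_fitness", "psas_tune"]


@dataclass
class TuneConfig:
    # hyperparameter boxes, searched in log2 space
    k_bounds: Tuple[float, float] = (2.0**-10, 2.0**10)
    c_bounds: Tuple[float, float] = (2.0**-10, 2.0**10)
    folds: int = 10
    pop_size: int = 10
    iter_max: int = 50
    shuffle_seed: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("k_bounds", self.k_bounds), ("c_bounds", self.c_bounds)):
            if lo <= 0 or hi <= lo:
                raise ValueError(f"{name} must be a positive interval, got ({lo}, {hi})")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class TuneResult:
    k_opt: float
    c_opt: float
    cv_fitness_history: np.ndarray  # best (1 - ACC) per optimizer iteration
    fold_assignments: List[np.ndarray]
    best_cv_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.best_cv_accuracy = 1.0 - float(self.cv_fitness_history[-1])

    def save_manifest(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k_opt": self.k_opt,
                    "c_opt": self.c_opt,
                    "best_cv_accuracy": self.best_cv_accuracy,
                    "cv_fitness_history": list(map(float, self.cv_fitness_history)),
                    "fold_assignments": [f.tolist() for f in self.fold_assignments],
                    "seed": seed,
                },
                fh,
                indent=1,
            )


def _cv_accuracy(theta, dataset: Dataset, folds: List[np.ndarray], sq=None) -> float:
    """Mean k-fold accuracy of a KELM at theta = (log2 k, log2 c).

    Equivalent to training via ``kelm_train`` on every fold complement but
    reuses one pairwise squared-distance matrix across candidates, which is
    what makes the tuning loop affordable (the kernel only depends on the
    distances and k).
    """
    from scipy.linalg import cho_factor, cho_solve
    from scipy.spatial.distance import cdist

    log2_k, log2_c = theta
    k = float(2.0**log2_k)
    c = float(2.0**log2_c)
    X, y = dataset.features, dataset.labels
    n = X.shape[0]
    if sq is None:
        sq = cdist(X, X, metric="sqeuclidean")
    K = np.exp(-sq / (2.0 * k**2))
    accs = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        Ktr = K[np.ix_(train_idx, train_idx)] + np.eye(train_idx.size) / c
        ytr = y[train_idx]
        try:
            w = cho_solve(cho_factor(Ktr, check_finite=False), ytr, check_finite=False)
        except np.linalg.LinAlgError:
            w, *_ = np.linalg.lstsq(Ktr, ytr, rcond=None)
        if not np.all(np.isfinite(w)):
            raise ArithmeticError(f"KELM solve failed at (k={k}, c={c})")
        scores = K[np.ix_(test_idx, train_idx)] @ w
        pred = np.where(scores >= 0.0, 1.0, -1.0)
        accs.append(compute_metrics(confusion(y[test_idx], pred)).acc)
    return float(np.mean(accs))


def cv_fitness(theta, dataset: Dataset, folds: int = 10, shuffle_seed=None) -> float:
    """1 - mean cross-validated accuracy of a KELM at theta = (log2 k, log2 c)."""
    assignments = kfold_indices(dataset.n_samples, folds, seed=shuffle_seed)
    return 1.0 - _cv_accuracy(theta, dataset, assignments)


def psas_tune(dataset: Dataset, config: Optional[TuneConfig] = None) -> TuneResult:
    """Tune (k, c) by running the enhanced sparrow search over the log2 box."""
    if config is None:
        config = TuneConfig()
    from scipy.spatial.distance import cdist

    folds = min(config.folds, dataset.n_samples)
    assignments = kfold_indices(dataset.n_samples, folds, seed=config.shuffle_seed)
    sq = cdist(dataset.features, dataset.features, metric="sqeuclidean")

    def objective(theta):
        return 1.0 - _cv_accuracy(theta, dataset, assignments, sq=sq)

    opt = EGSSAConfig(
        pop_size=config.pop_size,
        dim=2,
        lower=[np.log2(config.k_bounds[0]), np.log2(config.c_bounds[0])],
        upper=[np.log2(config.k_bounds[1]), np.log2(config.c_bounds[1])],
        iter_max=config.iter_max,
        seed=config.seed,
    )
    best_theta, _, curve = optimize_egssa(objective, opt)
    return TuneResult(
        k_opt=float(2.0 ** best_theta[0]),
        c_opt=float(2.0 ** best_theta[1]),
        cv_fitness_history=curve,
        fold_assignments=assignments,
    )
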