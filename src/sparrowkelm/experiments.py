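"""Experiment orchestration: benchmark suites, paired statistics, CV pipeline.

Two experiment families are wired up here. The first runs registered
optimizers over the 23 benchmark functions for R independent seeded runs
and aggregates avg/std per (function, optimizer) cell, followed by a
paired signed-rank comparison of the per-function means. The second is the
disease-prediction pipeline: an outer k-fold loop that tunes (k, c),
trains the KELM and scores the held-out fold with the four
confusion-matrix metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import sqrt
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .benchmarks import make_benchmark
from .data_io import Dataset, apply_minmax, fit_minmax, kfold_indices
from .egssa import EGSSAConfig, optimize_egssa
from .kelm import kelm_predict, kelm_train
from .metrics import MetricSet, compute_metrics, confusion
from .ssa import SwarmConfig, optimize_ssa
from .tuning import TuneConfig, TuneResult, psas_tune

__all__ = [
    "OPTIMIZERS",
    "register_optimizer",
    "BenchmarkReport",
    "SignedRankResult",
    "PipelineConfig",
    "PredictionReport",
    "run_benchmark_suite",
    "paired_signed_rank",
    "run_disease_pipeline",
]

# An optimizer plug-in maps (objective, SwarmConfig) -> (position, fitness, curve).
Optimizer = Callable[[Callable, SwarmConfig], Tuple[np.ndarray, float, np.ndarray]]


def _egssa_adapter(objective, config: SwarmConfig):
    egc = EGSSAConfig(
        pop_size=config.pop_size,
        dim=config.dim,
        lower=config.lower,
        upper=config.upper,
        iter_max=config.iter_max,
        ST=config.ST,
        PD=config.PD,
        SD=config.SD,
        epsilon=config.epsilon,
        seed=config.seed,
    )
    return optimize_egssa(objective, egc)


OPTIMIZERS: Dict[str, Optimizer] = {
    "ssa": optimize_ssa,
    "egssa": _egssa_adapter,
}


def register_optimizer(name: str, fn: Optimizer) -> None:
    """Register a third-party optimizer under the optimize contract."""
    OPTIMIZERS[name] = fn


@dataclass
class BenchmarkReport:
    functions: List[str]
    optimizers: List[str]
    runs: int
    raw: Dict[Tuple[str, str], np.ndarray]  # (function, optimizer) -> R best values
    failures: Dict[Tuple[str, str], str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def mean(self, function: str, optimizer: str) -> float:
        return float(np.mean(self.raw[(function, optimizer)]))

    def std(self, function: str, optimizer: str) -> float:
        return float(np.std(self.raw[(function, optimizer)], ddof=0))

    def means(self, optimizer: str) -> np.ndarray:
        return np.array([self.mean(f, optimizer) for f in self.functions])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.functions:
            for stat in ("avg", "std"):
                row = {"function": f, "stat": stat}
                for o in self.optimizers:
                    if (f, o) in self.failures:
                        row[o] = np.nan
                    else:
                        row[o] = self.mean(f, o) if stat == "avg" else self.std(f, o)
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_benchmark_suite(
    functions: Sequence[str],
    optimizers: Sequence[str],
    runs: int = 30,
    pop_size: int = 30,
    iter_max: int = 500,
    base_seed: int = 0,
) -> BenchmarkReport:
    """Run each optimizer ``runs`` times on each function; run r uses seed
    base_seed + r. Per-cell crashes are recorded, not raised."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    unknown = [o for o in optimizers if o not in OPTIMIZERS]
    if unknown:
        raise KeyError(f"unregistered optimizers: {unknown}")

    raw: Dict[Tuple[str, str], np.ndarray] = {}
    failures: Dict[Tuple[str, str], str] = {}
    for fname in functions:
        bench = make_benchmark(fname)
        for oname in optimizers:
            values = []
            try:
                for r in range(runs):
                    seed = base_seed + r
                    noise_rng = np.random.default_rng([seed, 0xF7])
                    objective = (
                        (lambda x, _b=bench, _r=noise_rng: _b.evaluate(x, _r))
                        if bench.stochastic
                        else bench.evaluate
                    )
                    config = SwarmConfig(
                        pop_size=pop_size,
                        dim=bench.dim,
                        lower=bench.lower_bound,
                        upper=bench.upper_bound,
                        iter_max=iter_max,
                        seed=seed,
                    )
                    _, best, _ = OPTIMIZERS[oname](objective, config)
                    values.append(best)
                raw[(fname, oname)] = np.array(values)
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                failures[(fname, oname)] = f"{type(exc).__name__}: {exc}"
    return BenchmarkReport(
        functions=list(functions),
        optimizers=list(optimizers),
        runs=runs,
        raw=raw,
        failures=failures,
        config={
            "runs": runs,
            "pop_size": pop_size,
            "iter_max": iter_max,
            "base_seed": base_seed,
        },
    )


@dataclass(frozen=True)
class SignedRankResult:
    n_better: int
    n_equal: int
    n_worse: int
    w_plus: float
    w_minus: float
    z: float
    p_two_sided: float


def paired_signed_rank(
    means_a: Sequence[float], means_b: Sequence[float], zero_tol: float = 1e-12
) -> SignedRankResult:
    """Paired signed-rank comparison of per-function means.

    Differences d = means_b - means_a (d > 0 means algorithm A is better on
    minimization). Differences within ``zero_tol`` of 0 count as ties and
    are dropped before ranking; remaining |d| get ascending mid-ranks.
    z uses the normal approximation without continuity or tie correction.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("means_a and means_b must be equal-length 1-d vectors")
    d = b - a
    tied = np.abs(d) <= zero_tol
    n_equal = int(np.sum(tied))
    d = d[~tied]
    if d.size == 0:
        raise ValueError("no non-tied pairs: all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    m = d.size
    mean_w = m * (m + 1) / 4.0
    sd_w = sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w_plus - mean_w) / sd_w
    p = 2.0 * norm.sf(abs(z))
    return SignedRankResult(
        n_better=int(np.sum(d > 0)),
        n_equal=n_equal,
        n_worse=int(np.sum(d < 0)),
        w_plus=w_plus,
        w_minus=w_minus,
        z=float(z),
        p_two_sided=float(min(p, 1.0)),
    )


def ranksum_per_function(runs_a: np.ndarray, runs_b: np.ndarray) -> float:
    """Secondary mode: two-sample rank-sum p-value over the raw run values
    of a single function."""
    from scipy.stats import mannwhitneyu

    return float(mannwhitneyu(runs_a, runs_b, alternative="two-sided").pvalue)


@dataclass
class PipelineConfig:
    folds: int = 10
    tune: TuneConfig = field(default_factory=TuneConfig)
    seed: Optional[int] = 0
    # "nested": per-fold normalization and tuning (leakage-free, default);
    # "paper": normalize and tune once on the full dataset, then k-fold eval.
    mode: str = "nested"

    def __post_init__(self) -> None:
        if self.mode not in ("nested", "paper"):
            raise ValueError("mode must be 'nested' or 'paper'")


@dataclass
class PredictionReport:
    fold_metrics: List[Optional[MetricSet]]
    tune_results: List[Optional[TuneResult]]
    config: PipelineConfig
    fold_errors: Dict[int, str] = field(default_factory=dict)
    # (test indices, predicted labels) per completed fold, for resampling checks
    fold_predictions: List[Optional[Tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=list
    )

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.fold_metrics if m is not None])

    def mean(self, attr: str) -> float:
        return float(np.mean(self._values(attr)))

    def std(self, attr: str) -> float:
        return float(np.std(self._values(attr), ddof=1)) if len(self._values(attr)) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for attr in ("acc", "sensitivity", "specificity", "mcc"):
            row = {"metric": attr, "mean": self.mean(attr), "std": self.std(attr)}
            for i, m in enumerate(self.fold_metrics, start=1):
                row[f"{i}#"] = getattr(m, attr) if m is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _fit_and_score(X_train, y_train, X_test, y_test, k, c):
    model = kelm_train(X_train, y_train, regularization=c, kernel_width=k)
    _, pred = kelm_predict(model, X_test)
    return compute_metrics(confusion(y_test, pred)), pred


def run_disease_pipeline(ds: Dataset, config: Optional[PipelineConfig] = None) -> PredictionReport:
    """Outer k-fold evaluation of the tuned KELM on a preprocessed dataset."""
    if config is None:
        config = PipelineConfig()
    if np.any(np.isnan(ds.features)):
        raise ValueError("dataset still contains missing values; run drop_missing first")
    n = ds.n_samples
    base_seed = 0 if config.seed is None else config.seed
    outer = kfold_indices(n, config.folds, seed=base_seed)

    shared_tune: Optional[TuneResult] = None
    X_full = ds.features
    if config.mode == "paper":
        X_full = apply_minmax(ds.features, fit_minmax(ds.features))
        full_ds = replace(ds, features=X_full)
        shared_tune = psas_tune(
            full_ds,
            replace(config.tune, seed=base_seed + 1, shuffle_seed=base_seed + 1),
        )

    fold_metrics: List[Optional[MetricSet]] = []
    tune_results: List[Optional[TuneResult]] = []
    fold_predictions: List[Optional[Tuple[np.ndarray, np.ndarray]]] = []
    errors: Dict[int, str] = {}
    for fold_idx, test_idx in enumerate(outer):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        try:
            if config.mode == "paper":
                X_train, X_test = X_full[train_mask], X_full[test_idx]
                tune = shared_tune
            else:
                params = fit_minmax(ds.features[train_mask])
                X_train = apply_minmax(ds.features[train_mask], params)
                X_test = apply_minmax(ds.features[test_idx], params)
                train_ds = Dataset(
                    features=X_train,
                    labels=ds.labels[train_mask],
                    feature_names=ds.feature_names,
                    provenance=ds.provenance + [f"outer fold {fold_idx} training split"],
                )
                tune = psas_tune(
                    train_ds,
                    replace(
                        config.tune,
                        seed=base_seed + fold_idx + 1,
                        shuffle_seed=base_seed + fold_idx + 1,
                    ),
                )
            metric, pred = _fit_and_score(
                X_train, ds.labels[train_mask], X_test, ds.labels[test_idx],
                tune.k_opt, tune.c_opt,
            )
            fold_metrics.append(metric)
            tune_results.append(tune)
            fold_predictions.append((np.asarray(test_idx), pred))
        except Exception as exc:  # noqa: BLE001 - fold-level isolation
            errors[fold_idx] = f"{type(exc).__name__}: {exc}"
            fold_metrics.append(None)
            tune_results.append(None)
            fold_predictions.append(None)
    if errors:
        warnings.warn(
            f"{len(errors)} fold(s) failed; aggregate covers completed folds only: {errors}",
            stacklevel=2,
        )
    return PredictionReport(
        fold_metrics=fold_metrics,
        tune_results=tune_results,
        config=config,
        fold_errors=errors,
        fold_predictions=fold_predictions,
    )
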