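"""The 23 classical benchmark functions used to exercise the optimizers.

Each function is a box-constrained minimization problem. F1-F7 are
unimodal, F8-F13 multimodal in 30 dimensions, F14-F23 fixed-dimension
multimodal. Constants for the Shekel, Kowalik, Hartmann and foxholes
families are the canonical literature tables; ``printed_optimum`` is the
reference minimum value commonly tabulated for each function.

All evaluators are pure except F7, which adds a uniform [0, 1) noise term
and therefore takes an RNG. Evaluation outside the box is permitted (the
optimizers clip before evaluating).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["BenchmarkFunction", "make_benchmark", "FUNCTION_NAMES", "registry_frame"]

FUNCTION_NAMES = tuple(f"F{i}" for i in range(1, 24))


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named box-constrained objective with its reference optimum."""

    name: str
    dim: int
    lower_bound: float
    upper_bound: float
    printed_optimum: float
    category: str
    _evaluator: Callable[..., float] = field(repr=False, compare=False)
    stochastic: bool = False
    # where the printed string disagrees with the analytic optimum (F8)
    printed_optimum_note: Optional[str] = None

    def __call__(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        return self.evaluate(x, rng)

    def evaluate(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(
                f"{self.name} expects a vector of length {self.dim}, got shape {x.shape}"
            )
        if self.stochastic:
            if rng is None:
                rng = np.random.default_rng()
            return float(self._evaluator(x, rng))
        return float(self._evaluator(x))


# --- penalty helper shared by F12/F13 ---

def _u(x: np.ndarray, a: float, k: float, m: float) -> np.ndarray:
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return out


def _f1(x):
    return np.sum(x**2)


def _f2(x):
    ax = np.abs(x)
    return np.sum(ax) + np.prod(ax)


def _f3(x):
    return np.sum(np.cumsum(x) ** 2)


def _f4(x):
    return np.max(np.abs(x))


def _f5(x):
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _f6(x):
    # [x + 0.5] read as round-half-up, i.e. floor(x + 0.5)
    return np.sum(np.floor(x + 0.5) ** 2)


def _f7(x, rng):
    n = x.size
    return np.sum(np.arange(1, n + 1) * x**4) + rng.uniform(0.0, 1.0)


def _f8(x):
    return np.sum(-x * np.sin(np.sqrt(np.abs(x))))


def _f9(x):
    return np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _f10(x):
    n = x.size
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _f11(x):
    n = x.size
    return (
        np.sum(x**2) / 4000.0
        - np.prod(np.cos(x / np.sqrt(np.arange(1, n + 1))))
        + 1.0
    )


def _f12(x):
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return np.pi / n * term + np.sum(_u(x, 10.0, 100.0, 4.0))


def _f13(x):
    term = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return 0.1 * term + np.sum(_u(x, 5.0, 100.0, 4.0))


# --- fixed-dimension constants (canonical tables) ---

_base = np.array([-32.0, -16.0, 0.0, 16.0, 32.0])
_FOXHOLES_A = np.vstack([np.tile(_base, 5), np.repeat(_base, 5)])  # 2 x 25

_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])

_HARTMANN3_A = np.array(
    [[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]]
)
_HARTMANN3_C = np.array([1.0, 1.2, 3.0, 3.2])
_HARTMANN3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.0381, 0.5743, 0.8828],
    ]
)

_HARTMANN6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_HARTMANN6_C = np.array([1.0, 1.2, 3.0, 3.2])
_HARTMANN6_P = np.array(
    [
        [0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
        [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
        [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
        [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381],
    ]
)

_SHEKEL_A = np.array(
    [
        [4.0, 4.0, 4.0, 4.0],
        [1.0, 1.0, 1.0, 1.0],
        [8.0, 8.0, 8.0, 8.0],
        [6.0, 6.0, 6.0, 6.0],
        [3.0, 7.0, 3.0, 7.0],
        [2.0, 9.0, 2.0, 9.0],
        [5.0, 5.0, 3.0, 3.0],
        [8.0, 1.0, 8.0, 1.0],
        [6.0, 2.0, 6.0, 2.0],
        [7.0, 3.6, 7.0, 3.6],
    ]
)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _f14(x):
    inner = np.arange(1, 26) + np.sum((x[:, None] - _FOXHOLES_A) ** 6, axis=0)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / inner))


def _f15(x):
    b = _KOWALIK_B
    num = x[0] * (b**2 + b * x[1])
    den = b**2 + b * x[2] + x[3]
    return np.sum((_KOWALIK_A - num / den) ** 2)


def _f16(x):
    x1, x2 = x
    return (
        4.0 * x1**2
        - 2.1 * x1**4
        + x1**6 / 3.0
        + x1 * x2
        - 4.0 * x2**2
        + 4.0 * x2**4
    )


def _f17(x):
    x1, x2 = x
    return (
        (x2 - 5.1 / (4.0 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _f18(x):
    x1, x2 = x
    a = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1**2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2**2
    )
    b = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1**2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2**2
    )
    return a * b


def _hartmann(x, a, c, p):
    return -np.sum(c * np.exp(-np.sum(a * (x[None, :] - p) ** 2, axis=1)))


def _f19(x):
    return _hartmann(x, _HARTMANN3_A, _HARTMANN3_C, _HARTMANN3_P)


def _f20(x):
    return _hartmann(x, _HARTMANN6_A, _HARTMANN6_C, _HARTMANN6_P)


def _shekel(x, m):
    diff = x[None, :] - _SHEKEL_A[:m]
    return -np.sum(1.0 / (np.sum(diff**2, axis=1) + _SHEKEL_C[:m]))


def _f21(x):
    return _shekel(x, 5)


def _f22(x):
    return _shekel(x, 7)


def _f23(x):
    return _shekel(x, 10)


# name -> (evaluator, dim, lower, upper, printed_optimum, category, stochastic)
_REGISTRY = {
    "F1": (_f1, 30, -100.0, 100.0, 0.0, "unimodal", False),
    "F2": (_f2, 30, -10.0, 10.0, 0.0, "unimodal", False),
    "F3": (_f3, 30, -100.0, 100.0, 0.0, "unimodal", False),
    "F4": (_f4, 30, -100.0, 100.0, 0.0, "unimodal", False),
    "F5": (_f5, 30, -30.0, 30.0, 0.0, "unimodal", False),
    "F6": (_f6, 30, -100.0, 100.0, 0.0, "unimodal", False),
    "F7": (_f7, 30, -1.28, 1.28, 0.0, "unimodal", True),
    "F8": (_f8, 30, -500.0, 500.0, -418.9829 * 30, "multimodal", False),
    "F9": (_f9, 30, -5.12, 5.12, 0.0, "multimodal", False),
    "F10": (_f10, 30, -32.0, 32.0, 0.0, "multimodal", False),
    "F11": (_f11, 30, -600.0, 600.0, 0.0, "multimodal", False),
    "F12": (_f12, 30, -50.0, 50.0, 0.0, "multimodal", False),
    "F13": (_f13, 30, -50.0, 50.0, 0.0, "multimodal", False),
    "F14": (_f14, 2, -65.0, 65.0, 1.0, "fixed_dimension_multimodal", False),
    "F15": (_f15, 4, -5.0, 5.0, 0.00030, "fixed_dimension_multimodal", False),
    "F16": (_f16, 2, -5.0, 5.0, -1.0316, "fixed_dimension_multimodal", False),
    "F17": (_f17, 2, -5.0, 5.0, 0.398, "fixed_dimension_multimodal", False),
    "F18": (_f18, 2, -2.0, 2.0, 3.0, "fixed_dimension_multimodal", False),
    # the commonly tabulated [1, 3] range for the 3-d Hartmann function is a
    # long-propagated typo: the minimizer lies in [0, 1]^3 and the tabulated
    # minimum -3.86 is unreachable on [1, 3]^3, so the canonical box is used.
    "F19": (_f19, 3, 0.0, 1.0, -3.86, "fixed_dimension_multimodal", False),
    "F20": (_f20, 6, 0.0, 1.0, -3.32, "fixed_dimension_multimodal", False),
    "F21": (_f21, 4, 0.0, 10.0, -10.1532, "fixed_dimension_multimodal", False),
    "F22": (_f22, 4, 0.0, 10.0, -10.4028, "fixed_dimension_multimodal", False),
    "F23": (_f23, 4, 0.0, 10.0, -10.5363, "fixed_dimension_multimodal", False),
}


def make_benchmark(name: str) -> BenchmarkFunction:
    """Build one of the 23 benchmark functions by name (``"F1"``..``"F23"``)."""
    try:
        fn, dim, lo, hi, opt, cat, stoch = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no such benchmark: {name!r} (expected F1..F23)") from None
    note = "tabulated as -418.9829 x 5 despite dim 30" if name == "F8" else None
    return BenchmarkFunction(
        name=name,
        dim=dim,
        lower_bound=lo,
        upper_bound=hi,
        printed_optimum=opt,
        category=cat,
        _evaluator=fn,
        stochastic=stoch,
        printed_optimum_note=note,
    )


def registry_frame():
    """Machine-readable registry of all 23 functions as a DataFrame."""
    import pandas as pd

    rows = []
    for name in FUNCTION_NAMES:
        f = make_benchmark(name)
        rows.append(
            {
                "name": f.name,
                "dim": f.dim,
                "lower_bound": f.lower_bound,
                "upper_bound": f.upper_bound,
                "printed_optimum": f.printed_optimum,
                "category": f.category,
                "stochastic": f.stochastic,
            }
        )
    return pd.DataFrame(rows)
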