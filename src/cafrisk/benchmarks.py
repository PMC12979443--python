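"""The classic 23-function benchmark suite (F1-F23) and a comparison protocol.

F1-F7 are high-dimensional unimodal problems probing exploitation, F8-F13
high-dimensional multimodal problems probing exploration, and F14-F23
fixed-dimension multimodal problems (Shekel foxholes, Kowalik, camel, Branin,
Goldstein-Price, Hartman, Shekel families).  Canonical dimensions and bounds
are used (30 for F1-F13).  Minimization convention throughout; the stored
``known_optimum`` is the global minimum value.

F7's additive noise is derived from a hash of the evaluated position and a
seed, so every function in the suite is a pure, reproducible function.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .optimizer import OptimizationResult, OptimizerConfig, SearchSpace, optimize

__all__ = [
    "BenchmarkFunction",
    "ProtocolResult",
    "BENCHMARK_IDS",
    "make_benchmark",
    "run_protocol",
    "igkso_factory",
    "gkso_factory",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    id: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    modality: str  # "unimodal" | "multimodal"
    known_optimum: float
    evaluate: Callable[[np.ndarray], float] = field(repr=False)
    known_position: np.ndarray | None = field(default=None, repr=False)

    @property
    def space(self) -> SearchSpace:
        return SearchSpace(self.lower, self.upper)


def _u_penalty(x: np.ndarray, a: float, k: float, m: float) -> np.ndarray:
    out = np.zeros_like(x)
    out = np.where(x > a, k * (x - a) ** m, out)
    out = np.where(x < -a, k * (-x - a) ** m, out)
    return out


def _f1(x):  # sphere
    return float(np.sum(x * x))


def _f2(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _f3(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _f4(x):
    return float(np.max(np.abs(x)))


def _f5(x):  # Rosenbrock
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _f6(x):  # step
    return float(np.sum(np.floor(x + 0.5) ** 2))


def _make_f7(noise_seed: int):
    def _f7(x):
        i = np.arange(1, x.size + 1)
        base = float(np.sum(i * x**4))
        h = zlib.crc32(np.ascontiguousarray(x, dtype=float).tobytes()) ^ noise_seed
        noise = np.random.default_rng(h).random()
        return base + noise

    return _f7


def _f8(x):  # Schwefel 2.26
    return float(np.sum(-x * np.sin(np.sqrt(np.abs(x)))))


def _f9(x):  # Rastrigin
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _f10(x):  # Ackley
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + math.e
    )


def _f11(x):  # Griewank
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _f12(x):  # penalized 1
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / n * term + np.sum(_u_penalty(x, 10.0, 100.0, 4.0)))


def _f13(x):  # penalized 2
    term = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * term + np.sum(_u_penalty(x, 5.0, 100.0, 4.0)))


_FOXHOLE_A = np.array(
    [
        [-32, -16, 0, 16, 32] * 5,
        [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
    ],
    dtype=float,
)


def _f14(x):  # Shekel's foxholes
    diff = x[:, None] - _FOXHOLE_A  # (2, 25)
    denom = np.arange(1, 26) + np.sum(diff**6, axis=0)
    return float(1.0 / (1.0 / 500.0 + np.sum(1.0 / denom)))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
     0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _f15(x):  # Kowalik
    b = _KOWALIK_B
    model = x[0] * (b * b + b * x[1]) / (b * b + b * x[2] + x[3])
    return float(np.sum((_KOWALIK_A - model) ** 2))


def _f16(x):  # six-hump camel back
    x1, x2 = x
    return float(
        4 * x1**2 - 2.1 * x1**4 + x1**6 / 3.0 + x1 * x2 - 4 * x2**2 + 4 * x2**4
    )


def _f17(x):  # Branin
    x1, x2 = x
    return float(
        (x2 - 5.1 / (4 * np.pi**2) * x1**2 + 5 / np.pi * x1 - 6) ** 2
        + 10 * (1 - 1 / (8 * np.pi)) * np.cos(x1)
        + 10
    )


def _f18(x):  # Goldstein-Price
    x1, x2 = x
    a = 1 + (x1 + x2 + 1) ** 2 * (
        19 - 14 * x1 + 3 * x1**2 - 14 * x2 + 6 * x1 * x2 + 3 * x2**2
    )
    b = 30 + (2 * x1 - 3 * x2) ** 2 * (
        18 - 32 * x1 + 12 * x1**2 + 48 * x2 - 36 * x1 * x2 + 27 * x2**2
    )
    return float(a * b)


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3, 10, 30], [0.1, 10, 35], [3, 10, 30], [0.1, 10, 35]], dtype=float)
_H3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.0381, 0.5743, 0.8828],
    ]
)


def _f19(x):  # Hartman 3
    inner = np.sum(_H3_A * (x - _H3_P) ** 2, axis=1)
    return float(-np.sum(_H3_ALPHA * np.exp(-inner)))


_H6_A = np.array(
    [
        [10, 3, 17, 3.5, 1.7, 8],
        [0.05, 10, 17, 0.1, 8, 14],
        [3, 3.5, 1.7, 10, 17, 8],
        [17, 8, 0.05, 10, 0.1, 14],
    ],
    dtype=float,
)
_H6_P = np.array(
    [
        [0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
        [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
        [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
        [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381],
    ]
)


def _f20(x):  # Hartman 6
    inner = np.sum(_H6_A * (x - _H6_P) ** 2, axis=1)
    return float(-np.sum(_H3_ALPHA * np.exp(-inner)))


_SHEKEL_C = np.array(
    [
        [4, 4, 4, 4],
        [1, 1, 1, 1],
        [8, 8, 8, 8],
        [6, 6, 6, 6],
        [3, 7, 3, 7],
        [2, 9, 2, 9],
        [5, 5, 3, 3],
        [8, 1, 8, 1],
        [6, 2, 6, 2],
        [7, 3.6, 7, 3.6],
    ],
    dtype=float,
)
_SHEKEL_BETA = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _make_shekel(m: int):
    def _shekel(x):
        diff = _SHEKEL_C[:m] - x
        return float(-np.sum(1.0 / (np.sum(diff * diff, axis=1) + _SHEKEL_BETA[:m])))

    return _shekel


# id -> (fn or factory, dim, lower, upper, modality, f_min, argmin or None)
_SUITE: dict[str, tuple] = {
    "F1": (_f1, 30, -100, 100, "unimodal", 0.0, "zeros"),
    "F2": (_f2, 30, -10, 10, "unimodal", 0.0, "zeros"),
    "F3": (_f3, 30, -100, 100, "unimodal", 0.0, "zeros"),
    "F4": (_f4, 30, -100, 100, "unimodal", 0.0, "zeros"),
    "F5": (_f5, 30, -30, 30, "unimodal", 0.0, "ones"),
    "F6": (_f6, 30, -100, 100, "unimodal", 0.0, "zeros"),
    "F7": ("noise", 30, -1.28, 1.28, "unimodal", 0.0, None),
    "F8": (_f8, 30, -500, 500, "multimodal", -418.9828872724338 * 30, None),
    "F9": (_f9, 30, -5.12, 5.12, "multimodal", 0.0, "zeros"),
    "F10": (_f10, 30, -32, 32, "multimodal", 0.0, "zeros"),
    "F11": (_f11, 30, -600, 600, "multimodal", 0.0, "zeros"),
    "F12": (_f12, 30, -50, 50, "multimodal", 0.0, "neg_ones"),
    "F13": (_f13, 30, -50, 50, "multimodal", 0.0, "ones"),
    "F14": (_f14, 2, -65.536, 65.536, "multimodal", 0.998003837794, None),
    "F15": (_f15, 4, -5, 5, "multimodal", 0.0003074859878, None),
    "F16": (_f16, 2, -5, 5, "multimodal", -1.0316284534898774, None),
    "F17": (_f17, 2, (-5, 0), (10, 15), "multimodal", 0.39788735772973816, None),
    "F18": (_f18, 2, -2, 2, "multimodal", 3.0, None),
    "F19": (_f19, 3, 0, 1, "multimodal", -3.8627797873327005, None),
    "F20": (_f20, 6, 0, 1, "multimodal", -3.322368011391339, None),
    "F21": (_make_shekel(5), 4, 0, 10, "multimodal", -10.153199679058231, None),
    "F22": (_make_shekel(7), 4, 0, 10, "multimodal", -10.402940566818664, None),
    "F23": (_make_shekel(10), 4, 0, 10, "multimodal", -10.536409816692023, None),
}

BENCHMARK_IDS: tuple[str, ...] = tuple(_SUITE)


def make_benchmark(id: str, noise_seed: int = 0) -> BenchmarkFunction:
    """Build benchmark function F1..F23 with canonical dimension and bounds."""
    if id not in _SUITE:
        raise KeyError(f"unknown benchmark id {id!r}; valid ids: {', '.join(_SUITE)}")
    fn, dim, lo, hi, modality, fmin, arg = _SUITE[id]
    if fn == "noise":
        fn = _make_f7(noise_seed)
    lower = np.array(lo, dtype=float) if isinstance(lo, tuple) else np.full(dim, float(lo))
    upper = np.array(hi, dtype=float) if isinstance(hi, tuple) else np.full(dim, float(hi))
    pos = None
    if arg == "zeros":
        pos = np.zeros(dim)
    elif arg == "ones":
        pos = np.ones(dim)
    elif arg == "neg_ones":
        pos = -np.ones(dim)
    return BenchmarkFunction(
        id=id,
        dim=dim,
        lower=lower,
        upper=upper,
        modality=modality,
        known_optimum=float(fmin),
        evaluate=fn,
        known_position=pos,
    )


# ---------------------------------------------------------------------------
# Comparison protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    per_rep_best: list[float]
    mean_curve: np.ndarray
    config_echo: dict
    curves: np.ndarray = field(repr=False, default=None)
    bounds_violations: list[bool] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_rep_best": [float(v) for v in self.per_rep_best],
            "mean_curve": [float(v) for v in self.mean_curve],
            "config_echo": self.config_echo,
            "bounds_violations": list(self.bounds_violations),
        }


def igkso_factory(objective, space, seed, population=30, iterations=200, **kw) -> OptimizationResult:
    cfg = OptimizerConfig(population=population, iterations=iterations, seed=seed,
                          variant="igkso", **kw)
    return optimize(objective, space, cfg)


def gkso_factory(objective, space, seed, population=30, iterations=200, **kw) -> OptimizationResult:
    cfg = OptimizerConfig(population=population, iterations=iterations, seed=seed,
                          variant="gkso", **kw)
    return optimize(objective, space, cfg)


def run_protocol(
    optimizer_factory: Callable[..., OptimizationResult],
    fn: BenchmarkFunction,
    population: int = 30,
    iterations: int = 200,
    repetitions: int = 30,
    base_seed: int = 0,
) -> ProtocolResult:
    """Run `repetitions` independent optimizer runs on one benchmark.

    Repetition r uses seed base_seed + r.  The mean curve is the elementwise
    mean of the per-repetition best-so-far curves.  Positions evaluated
    outside the bounds are flagged per repetition (a protocol failure of the
    optimizer under test, not an exception).
    """
    if population < 2 or iterations < 1 or repetitions < 1:
        raise ValueError("population >= 2, iterations >= 1, repetitions >= 1 required")
    space = fn.space
    curves = np.empty((repetitions, iterations))
    per_rep_best: list[float] = []
    violations: list[bool] = []
    for r in range(repetitions):
        violated = False

        def checked(x, _fn=fn.evaluate, _space=space):
            nonlocal violated
            if not _space.contains(x):
                violated = True
            return _fn(x)

        res = optimizer_factory(
            checked, space, base_seed + r, population=population, iterations=iterations
        )
        curves[r] = res.convergence_curve
        per_rep_best.append(float(res.best_fitness))
        violations.append(violated)
    return ProtocolResult(
        per_rep_best=per_rep_best,
        mean_curve=curves.mean(axis=0),
        config_echo={
            "function": fn.id,
            "population": population,
            "iterations": iterations,
            "repetitions": repetitions,
            "base_seed": base_seed,
            "seeds": [base_seed + r for r in range(repetitions)],
        },
        curves=curves,
        bounds_violations=violations,
    )
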