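"""In-house Shapley-value attribution for fitted risk models.

The value function is the marginal (interventional) expectation over a
background sample: v(S) is the mean model output when the explained row's
features in S are kept and the complement is replaced by background rows.
For d <= 12 features all 2^d coalitions are enumerated and the classical
Shapley weights applied (exact mode, efficiency holds to machine precision);
otherwise uniformly random feature permutations are sampled and marginal
contributions averaged (sampled mode, with per-feature Monte-Carlo standard
errors).  Attributions are computed on the model's probability-scale output
by default; pass a wrapped predictor for log-odds.

Beyond per-row attributions, the module provides cohort-level mean-|phi|
importance ranking, waterfall/force/decision view data for single
predictions, and dependence scatter data coloured by a second feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Attribution",
    "GlobalImportance",
    "shapley_values",
    "global_importance",
    "explanation_views",
    "dependence_data",
]

_EXACT_LIMIT = 12


@dataclass
class Attribution:
    base_value: float
    contributions: np.ndarray
    prediction: float
    feature_values: np.ndarray
    feature_names: tuple[str, ...]
    mode: str  # exact | sampled
    mc_se: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "base_value": self.base_value,
            "prediction": self.prediction,
            "mode": self.mode,
            "features": {
                n: {"value": _jsonable(v), "phi": float(p)}
                for n, v, p in zip(self.feature_names, self.feature_values, self.contributions)
            },
        }
        if self.mc_se is not None:
            d["mc_se"] = {n: float(s) for n, s in zip(self.feature_names, self.mc_se)}
        return d


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _as_matrix(rows) -> tuple[np.ndarray, tuple[str, ...]]:
    """To a 2-D array; mixed-type frames stay as object arrays."""
    if isinstance(rows, pd.DataFrame):
        numeric = all(pd.api.types.is_numeric_dtype(d) for d in rows.dtypes)
        arr = rows.to_numpy(dtype=float if numeric else object)
        return arr, tuple(map(str, rows.columns))
    arr = np.atleast_2d(np.asarray(rows))
    return arr, tuple(f"x{i + 1}" for i in range(arr.shape[1]))


def _score_fn(predictor, names, object_dtype) -> Callable[[np.ndarray], np.ndarray]:
    if callable(predictor) and not hasattr(predictor, "score"):
        base = predictor
    else:
        base = predictor.score
    if object_dtype:
        # rebuild a typed frame so mixed categorical/numeric models score
        return lambda X: np.asarray(
            base(pd.DataFrame(list(X), columns=list(names)).infer_objects()), dtype=float
        )
    return lambda X: np.asarray(base(X), dtype=float)


def _coalition_values_exact(f, x, background, d):
    """v(mask) for every coalition mask, via batched hybrid-row evaluation."""
    nb = background.shape[0]
    values = np.empty(2**d)
    masks = np.arange(2**d)
    bits = ((masks[:, None] >> np.arange(d)) & 1).astype(bool)  # (2^d, d)
    chunk = max(1, 262144 // nb)
    for start in range(0, 2**d, chunk):
        sel = bits[start : start + chunk]  # (m, d)
        m = sel.shape[0]
        # coalition features take the explained row's values, the rest the background's
        rowrep = np.broadcast_to(x, (m, nb, d))
        hybrid = np.where(sel[:, None, :], rowrep, np.broadcast_to(background, (m, nb, d)))
        scores = f(hybrid.reshape(m * nb, d)).reshape(m, nb)
        values[start : start + m] = scores.mean(axis=1)
    return values


def _exact(f, x, background, names) -> Attribution:
    d = x.size
    v = _coalition_values_exact(f, x, background, d)
    # precompute weights |S|!(d-|S|-1)!/d!
    fact = [math.factorial(i) for i in range(d + 1)]
    w = np.array([fact[s] * fact[d - s - 1] / fact[d] for s in range(d)])
    popcount = np.array([bin(m).count("1") for m in range(2**d)])
    phi = np.zeros(d)
    for i in range(d):
        bit = 1 << i
        without = np.flatnonzero((np.arange(2**d) & bit) == 0)
        s = popcount[without]
        phi[i] = np.sum(w[s] * (v[without | bit] - v[without]))
    base = float(v[0])
    pred = float(v[-1])
    return Attribution(
        base_value=base, contributions=phi, prediction=pred,
        feature_values=x.copy(), feature_names=names, mode="exact",
    )


def _sampled(f, x, background, names, n_perm, seed) -> Attribution:
    d = x.size
    rng = np.random.default_rng(seed)
    nb = background.shape[0]
    cache: dict[int, float] = {}

    def value(mask_bits: int) -> float:
        if mask_bits not in cache:
            sel = np.array([(mask_bits >> i) & 1 for i in range(d)], dtype=bool)
            hybrid = background.copy()
            hybrid[:, sel] = x[sel]
            cache[mask_bits] = float(f(hybrid).mean())
        return cache[mask_bits]

    contribs = np.zeros((n_perm, d))
    for p in range(n_perm):
        order = rng.permutation(d)
        mask = 0
        prev = value(0)
        for i in order:
            mask |= 1 << int(i)
            cur = value(mask)
            contribs[p, i] = cur - prev
            prev = cur
    phi = contribs.mean(axis=0)
    mc_se = contribs.std(axis=0, ddof=1) / math.sqrt(n_perm) if n_perm > 1 else np.zeros(d)
    return Attribution(
        base_value=value(0), contributions=phi, prediction=value((1 << d) - 1),
        feature_values=x.copy(), feature_names=names, mode="sampled", mc_se=mc_se,
    )


def shapley_values(
    predictor,
    row,
    background,
    mode: str = "exact",
    n_perm: int = 256,
    seed: int = 0,
) -> Attribution:
    """Shapley attribution of one prediction against a background sample.

    ``predictor`` is either a callable mapping a feature matrix to scores or
    an object with a ``score`` method (e.g. a TrainedPredictor).  Exact mode
    requires at most 12 features; sampled mode draws ``n_perm`` seeded
    uniform permutations.
    """
    bg, bg_names = _as_matrix(background)
    if bg.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    xrow, names = _as_matrix(row)
    if xrow.shape[0] != 1:
        raise ValueError("explain exactly one row at a time")
    object_dtype = bg.dtype == object or xrow.dtype == object
    x = xrow[0] if object_dtype else xrow[0].astype(float)
    bg = bg if object_dtype else bg.astype(float)
    if bg.shape[1] != x.size:
        raise ValueError("row and background have different feature counts")
    if isinstance(background, pd.DataFrame):
        names = bg_names
    f = _score_fn(predictor, names, object_dtype)
    if mode == "exact":
        if x.size > _EXACT_LIMIT:
            raise ValueError(
                f"exact mode enumerates 2^d coalitions; d = {x.size} exceeds {_EXACT_LIMIT}"
            )
        return _exact(f, x, bg, names)
    if mode == "sampled":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        return _sampled(f, x, bg, names, n_perm, seed)
    raise ValueError("mode must be 'exact' or 'sampled'")


@dataclass
class GlobalImportance:
    mean_abs: dict[str, float]
    ranking: list[str]

    def to_dict(self) -> dict:
        return {"mean_abs": self.mean_abs, "ranking": self.ranking}


def global_importance(attributions: Sequence[Attribution]) -> GlobalImportance:
    """Cohort-level importance: mean |phi| per feature, ranked descending.

    Ties are broken by original feature order.
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    names = attributions[0].feature_names
    for a in attributions:
        if a.feature_names != names:
            raise ValueError("attributions have inconsistent feature sets")
    phis = np.abs(np.stack([a.contributions for a in attributions]))
    mean_abs = phis.mean(axis=0)
    order = sorted(range(len(names)), key=lambda i: (-mean_abs[i], i))
    return GlobalImportance(
        mean_abs={names[i]: float(mean_abs[i]) for i in range(len(names))},
        ranking=[names[i] for i in order],
    )


def explanation_views(attribution: Attribution) -> dict:
    """Waterfall / force / decision view data for one attribution.

    Waterfall and decision order features by descending |phi| and accumulate
    from the base value to the prediction; force partitions features into
    risk-increasing (phi > 0) and risk-decreasing (phi < 0) sets.
    """
    names = attribution.feature_names
    phi = attribution.contributions
    order = sorted(range(len(names)), key=lambda i: (-abs(phi[i]), i))
    running = attribution.base_value
    waterfall = []
    for i in order:
        running += float(phi[i])
        waterfall.append(
            {
                "feature": names[i],
                "value": _jsonable(attribution.feature_values[i]),
                "phi": float(phi[i]),
                "cumulative": running,
            }
        )
    force = {
        "base_value": attribution.base_value,
        "prediction": attribution.prediction,
        "increasing": [
            {"feature": names[i], "phi": float(phi[i])} for i in order if phi[i] > 0
        ],
        "decreasing": [
            {"feature": names[i], "phi": float(phi[i])} for i in order if phi[i] < 0
        ],
    }
    decision = {
        "start": attribution.base_value,
        "path": [
            {"feature": w["feature"], "cumulative": w["cumulative"]} for w in waterfall
        ],
        "end": attribution.prediction,
    }
    return {"waterfall": waterfall, "force": force, "decision": decision}


def dependence_data(
    attributions: Sequence[Attribution],
    feature: str,
    color_feature: str,
) -> list[tuple]:
    """Dependence scatter: (feature value, phi, colour value) per explained row."""
    if not attributions:
        raise ValueError("need at least one attribution")
    names = attributions[0].feature_names
    for f in (feature, color_feature):
        if f not in names:
            raise KeyError(f"unknown feature {f!r}")
    i = names.index(feature)
    j = names.index(color_feature)
    return [
        (
            _jsonable(a.feature_values[i]),
            float(a.contributions[i]),
            _jsonable(a.feature_values[j]),
        )
        for a in attributions
    ]
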