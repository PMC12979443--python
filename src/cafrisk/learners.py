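"""Uniform train/score contract over the four base learners.

Logistic regression (LR), back-propagation neural network (BP), support
vector machine (SVM) and gradient-boosted trees (XGBoost) are wrapped behind
one interface: a hyperparameter-space registry, range validation before
training, leakage-safe preprocessing (continuous features z-scored with
training statistics only, categoricals one-hot encoded, binaries passed
through), and a ``score`` method returning values in [0, 1].

LR, BP and XGBoost scores are predicted probabilities; the SVM score is the
decision function squashed through a logistic, a monotone score in [0, 1]
(no Platt calibration, which would require an inner CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "HyperparamSpec",
    "LearnerSpec",
    "TrainedPredictor",
    "LEARNER_NAMES",
    "BP_ARCHITECTURES",
    "make_space",
    "train",
]

LEARNER_NAMES = ("lr", "bp", "svm", "xgb")

# Candidate hidden-layer architectures for the BP network, encoded as a
# categorical hyperparameter.
BP_ARCHITECTURES: tuple[tuple[int, ...], ...] = ((50,), (100,), (50, 50))


@dataclass(frozen=True)
class HyperparamSpec:
    """One tunable hyperparameter: kind, range/categories, optional gating.

    ``active_when = (other_name, required_value)`` marks a conditional
    parameter (e.g. polynomial degree only matters for the poly kernel).
    """

    name: str
    kind: str  # continuous | log_uniform | integer | categorical
    range: tuple[float, float] | None = None
    categories: tuple | None = None
    active_when: tuple[str, object] | None = None

    def __post_init__(self) -> None:
        if self.kind in ("continuous", "log_uniform", "integer"):
            if self.range is None or not self.range[0] < self.range[1]:
                raise ValueError(f"{self.name}: ranged kind needs lo < hi")
            if self.kind == "log_uniform" and self.range[0] <= 0:
                raise ValueError(f"{self.name}: log-uniform range must be positive")
        elif self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"{self.name}: categorical kind needs categories")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.categories
        lo, hi = self.range
        if self.kind == "integer":
            return float(value).is_integer() and lo <= value <= hi
        return lo <= value <= hi


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    space: tuple[HyperparamSpec, ...]
    seed_sensitive: bool


_SPACES: dict[str, LearnerSpec] = {
    "lr": LearnerSpec(
        name="lr",
        seed_sensitive=False,
        space=(
            HyperparamSpec("penalty", "categorical", categories=("l1", "l2")),
            HyperparamSpec("C", "log_uniform", range=(0.001, 100.0)),
            HyperparamSpec("max_iter", "integer", range=(50, 500)),
        ),
    ),
    "bp": LearnerSpec(
        name="bp",
        seed_sensitive=True,
        space=(
            HyperparamSpec("hidden_layer_sizes", "categorical", categories=BP_ARCHITECTURES),
            HyperparamSpec("activation", "categorical", categories=("relu", "tanh", "logistic")),
            HyperparamSpec("learning_rate_init", "log_uniform", range=(0.0001, 0.1)),
            HyperparamSpec("alpha", "log_uniform", range=(0.0001, 0.1)),
            HyperparamSpec("batch_size", "integer", range=(16, 128)),
        ),
    ),
    "svm": LearnerSpec(
        name="svm",
        seed_sensitive=False,
        space=(
            HyperparamSpec("C", "log_uniform", range=(0.1, 100.0)),
            HyperparamSpec("kernel", "categorical", categories=("linear", "rbf", "poly")),
            HyperparamSpec("gamma", "log_uniform", range=(0.0001, 10.0)),
            HyperparamSpec("degree", "integer", range=(2, 5), active_when=("kernel", "poly")),
        ),
    ),
    "xgb": LearnerSpec(
        name="xgb",
        seed_sensitive=True,
        space=(
            HyperparamSpec("learning_rate", "continuous", range=(0.01, 0.3)),
            HyperparamSpec("max_depth", "integer", range=(3, 12)),
            HyperparamSpec("min_child_weight", "integer", range=(1, 10)),
            HyperparamSpec("subsample", "continuous", range=(0.5, 1.0)),
            HyperparamSpec("colsample_bytree", "continuous", range=(0.5, 1.0)),
            HyperparamSpec("reg_alpha", "continuous", range=(0.0, 1.0)),
            HyperparamSpec("reg_lambda", "continuous", range=(0.0, 2.0)),
        ),
    ),
}


def make_space(name: str) -> LearnerSpec:
    """Hyperparameter space registry for learner 'lr' | 'bp' | 'svm' | 'xgb'."""
    if name not in _SPACES:
        raise KeyError(f"unknown learner {name!r}; valid names: {', '.join(_SPACES)}")
    return _SPACES[name]


def _validate_hyperparams(spec: LearnerSpec, hyperparams: Mapping) -> dict:
    out = {}
    by_name = {h.name: h for h in spec.space}
    for h in spec.space:
        if h.name not in hyperparams:
            raise ValueError(f"{spec.name}: missing hyperparameter {h.name!r}")
        v = hyperparams[h.name]
        if not h.contains(v):
            raise ValueError(f"{spec.name}: {h.name}={v!r} outside its allowed range")
        out[h.name] = v
    extra = set(hyperparams) - set(by_name)
    if extra:
        raise ValueError(f"{spec.name}: unknown hyperparameters {sorted(extra)}")
    return out


def _infer_kinds(X: pd.DataFrame) -> dict[str, str]:
    kinds = {}
    for c in X.columns:
        col = X[c]
        if not pd.api.types.is_numeric_dtype(col):
            kinds[c] = "categorical"
        elif set(pd.unique(col)) <= {0, 1}:
            kinds[c] = "binary"
        else:
            kinds[c] = "continuous"
    return kinds


def _build_estimator(name: str, hp: Mapping, seed: int):
    if name == "lr":
        # Table-style "penalty" in {l1, l2} mapped onto the l1_ratio API
        return LogisticRegression(
            l1_ratio=1.0 if hp["penalty"] == "l1" else 0.0,
            C=hp["C"], max_iter=int(hp["max_iter"]),
            solver="liblinear", random_state=seed,
        )
    if name == "bp":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp["hidden_layer_sizes"]),
            activation=hp["activation"],
            learning_rate_init=hp["learning_rate_init"],
            alpha=hp["alpha"],
            batch_size=int(hp["batch_size"]),
            max_iter=500,
            random_state=seed,
        )
    if name == "svm":
        return SVC(
            C=hp["C"], kernel=hp["kernel"], gamma=hp["gamma"],
            degree=int(hp.get("degree", 3)), random_state=seed,
        )
    if name == "xgb":
        return XGBClassifier(
            n_estimators=100,
            learning_rate=hp["learning_rate"],
            max_depth=int(hp["max_depth"]),
            min_child_weight=hp["min_child_weight"],
            subsample=hp["subsample"],
            colsample_bytree=hp["colsample_bytree"],
            reg_alpha=hp["reg_alpha"],
            reg_lambda=hp["reg_lambda"],
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            tree_method="hist",
        )
    raise KeyError(name)


@dataclass
class TrainedPredictor:
    """A fitted pipeline with a probability-like score in [0, 1]."""

    pipeline: Pipeline = field(repr=False)
    learner: str = ""
    hyperparams: dict = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    kinds: dict[str, str] = field(default_factory=dict)
    n_train: int = 0
    seed: int = 0

    numeric_only: bool = False

    def score(self, X) -> np.ndarray:
        X = self._coerce(X)
        if self.learner == "svm":
            z = self.pipeline.decision_function(X)
            s = 1.0 / (1.0 + np.exp(-z))
        else:
            s = self.pipeline.predict_proba(X)[:, 1]
        return np.clip(np.asarray(s, dtype=float), 0.0, 1.0)

    def _coerce(self, X):
        if self.numeric_only:
            if isinstance(X, pd.DataFrame):
                X = X[self.feature_names].to_numpy(dtype=float)
            return np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names]
        X = np.atleast_2d(np.asarray(X))
        return pd.DataFrame(X, columns=self.feature_names)

    @property
    def metadata(self) -> dict:
        return {
            "learner": self.learner,
            "hyperparams": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.hyperparams.items()
            },
            "features": list(self.feature_names),
            "n_train": self.n_train,
            "seed": self.seed,
        }


def train(
    name: str,
    hyperparams: Mapping,
    X: pd.DataFrame,
    y,
    seed: int = 0,
    kinds: Mapping[str, str] | None = None,
) -> TrainedPredictor:
    """Fit one base learner with validated hyperparameters.

    Preprocessing statistics (z-scoring, one-hot categories) come from the
    training rows only; held-out data never influences the fitted transform.
    """
    spec = make_space(name)
    hp = _validate_hyperparams(spec, hyperparams)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcomes contain a single class")

    hp_fit = dict(hp)
    n_rows = len(X)
    if name == "bp":
        hp_fit["batch_size"] = int(min(hp["batch_size"], n_rows))

    # fast path: purely numeric feature matrix, z-scoring only
    numeric_only = not isinstance(X, pd.DataFrame) and (
        kinds is None or all(k == "continuous" for k in kinds.values())
    )
    if numeric_only:
        Xn = np.asarray(X, dtype=float)
        if Xn.ndim != 2 or Xn.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(Xn)):
            raise ValueError("non-finite feature values")
        pipe = Pipeline([("pre", StandardScaler()), ("est", _build_estimator(name, hp_fit, seed))])
        pipe.fit(Xn, y)
        names = list(kinds) if kinds is not None else [f"x{i+1}" for i in range(Xn.shape[1])]
        return TrainedPredictor(
            pipeline=pipe, learner=name, hyperparams=dict(hp), feature_names=names,
            kinds={n: "continuous" for n in names}, n_train=len(Xn), seed=seed,
            numeric_only=True,
        )

    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [str(c) for c in X.columns]
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    num = X.select_dtypes(include=[np.number])
    if not np.all(np.isfinite(num.to_numpy(dtype=float))):
        raise ValueError("non-finite feature values")

    kinds = dict(kinds) if kinds is not None else _infer_kinds(X)
    cont = [c for c in X.columns if kinds.get(c, "continuous") == "continuous"]
    cat = [c for c in X.columns if kinds.get(c) == "categorical"]
    binary = [c for c in X.columns if kinds.get(c) == "binary"]
    pre = ColumnTransformer(
        [
            ("cont", StandardScaler(), cont),
            ("cat", OneHotEncoder(handle_unknown="ignore"), cat),
            ("bin", "passthrough", binary),
        ],
        remainder="drop",
    )
    est = _build_estimator(name, hp_fit, seed)
    pipe = Pipeline([("pre", pre), ("est", est)])
    pipe.fit(X, y)
    return TrainedPredictor(
        pipeline=pipe,
        learner=name,
        hyperparams=dict(hp),
        feature_names=list(X.columns),
        kinds=kinds,
        n_train=len(X),
        seed=seed,
    )
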