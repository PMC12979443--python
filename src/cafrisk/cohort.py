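"""Synthetic knee-osteoarthritis (KOA) cohorts for concern-about-falling (CAF) modelling.

The study population this package targets is a two-hospital KOA cohort
(n = 541) dichotomised by the Falls Efficacy Scale-International: FES-I >= 28
defines the CAF group (n = 360) against the no-CAF group (n = 181).  The raw
records are not public; what is published are group-wise means/SDs for the
continuous clinical variables and category counts for the discrete ones.
This module generates cohorts that match those published marginals:

* features with published per-group distributions (age, BMI, sex, knee
  extensor moment, TUG time, KL grade, WOMAC pain, HADS anxiety) are drawn
  per outcome group;
* features published only at the whole-cohort level (disease duration, gait
  speed, WOMAC stiffness/function, employment, education, living mode, MRI
  findings) are drawn group-independently.

Marginals do not pin down the joint distribution, so by default features are
independent within a group; an optional Gaussian copula over the continuous
block lets callers impose a correlation structure.  Continuous draws are
rejection-resampled into plausibility ranges (e.g. TUG > 0) so moments stay
close to their targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "CohortTable",
    "GenerationConfig",
    "default_schema",
    "generate",
    "label_from_fesi",
    "planted_signal_dataset",
]

OUTCOME = "CAF"


@dataclass(frozen=True)
class FeatureSpec:
    """Per-feature generative description, parameterised per outcome group.

    For ``kind == "continuous"``: ``moments[g] = (mean, sd)`` for group g in
    {0, 1} and ``clamp = (lo, hi)`` is a plausibility range enforced by
    rejection resampling.  For ``kind in ("binary", "categorical")``:
    ``categories`` lists the levels and ``probs[g]`` their probabilities.
    """

    name: str
    kind: str  # continuous | binary | categorical
    moments: Mapping[int, tuple[float, float]] | None = None
    clamp: tuple[float, float] | None = None
    categories: Sequence | None = None
    probs: Mapping[int, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if not self.moments:
                raise ValueError(f"{self.name}: continuous spec needs moments")
            for g, (_, sd) in self.moments.items():
                if sd <= 0:
                    raise ValueError(f"{self.name}: sd must be > 0 (group {g})")
        elif self.kind in ("binary", "categorical"):
            if not self.categories or not self.probs:
                raise ValueError(f"{self.name}: discrete spec needs categories and probs")
            for g, p in self.probs.items():
                p = np.asarray(p, dtype=float)
                if len(p) != len(self.categories):
                    raise ValueError(f"{self.name}: probs/categories length mismatch")
                if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                    raise ValueError(f"{self.name}: probabilities must be >= 0 and sum to 1")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass
class CohortTable:
    """Typed patient table with a binary CAF outcome column.

    ``kinds`` maps every feature column to continuous/binary/categorical;
    the table is validated to be complete (no missing values) on creation.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    outcome: str = OUTCOME

    def __post_init__(self) -> None:
        if self.outcome not in self.frame.columns:
            raise ValueError(f"outcome column {self.outcome!r} missing")
        if self.frame.isna().any().any():
            bad = [
                (int(i), c)
                for c in self.frame.columns
                for i in self.frame.index[self.frame[c].isna()]
            ]
            raise ValueError(f"missing values at (row, column): {bad[:5]}")
        vals = set(pd.unique(self.frame[self.outcome]))
        if not vals <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, found {sorted(vals)!r}")
        unknown = set(self.kinds) - set(self.frame.columns)
        if unknown:
            raise ValueError(f"kinds refer to unknown columns {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.outcome]

    @property
    def n(self) -> int:
        return len(self.frame)

    def outcome_values(self) -> np.ndarray:
        return self.frame[self.outcome].to_numpy(dtype=int)

    def features(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        return self.frame[list(names) if names is not None else self.feature_names]

    def subset(self, index) -> "CohortTable":
        return CohortTable(
            self.frame.loc[index].reset_index(drop=True), dict(self.kinds), self.outcome
        )

    def kind_of(self, name: str) -> str:
        return self.kinds.get(name, "continuous")


@dataclass(frozen=True)
class GenerationConfig:
    n_caf: int = 360
    n_nocaf: int = 181
    seed: int = 0
    correlation: np.ndarray | None = None  # latent correlation over continuous features

    def __post_init__(self) -> None:
        if self.n_caf < 1 or self.n_nocaf < 1:
            raise ValueError("group sizes must be >= 1")


def _cont(name, caf, nocaf, clamp):
    return FeatureSpec(name=name, kind="continuous", moments={1: caf, 0: nocaf}, clamp=clamp)


def default_schema() -> list[FeatureSpec]:
    """Published-marginal schema of the KOA/CAF study cohort.

    Group-wise parameters come from the published CAF (n=360) vs no-CAF
    (n=181) univariate comparison; features compared only between training
    and testing splits use the training-set (n=433) marginals for both groups.
    """
    n1, n0 = 360, 181
    return [
        _cont("age", (67.35, 14.23), (61.85, 13.77), (18.0, 100.0)),
        _cont("bmi", (24.97, 3.78), (23.12, 3.15), (12.0, 55.0)),
        FeatureSpec(
            name="sex_female", kind="binary", categories=(0, 1),
            probs={1: (78 / n1, 282 / n1), 0: (86 / n0, 95 / n0)},
        ),
        _cont("knee_extensor_moment", (1.05, 0.32), (1.45, 0.41), (0.05, 4.0)),
        _cont("tug_time", (14.52, 3.85), (10.11, 2.46), (2.0, 60.0)),
        FeatureSpec(
            name="kl_grade3", kind="binary", categories=(0, 1),
            probs={1: (202 / n1, 158 / n1), 0: (130 / n0, 51 / n0)},
        ),
        _cont("womac_pain", (6.45, 2.01), (4.73, 1.24), (0.0, 20.0)),
        _cont("hads_anxiety", (10.83, 3.31), (9.11, 2.59), (0.0, 21.0)),
        # whole-cohort marginals (training set, n = 433), group-independent
        _cont("duration", (15.82, 4.62), (15.82, 4.62), (0.5, 60.0)),
        _cont("gait_speed", (0.92, 0.21), (0.92, 0.21), (0.1, 2.5)),
        _cont("womac_stiffness", (2.15, 0.49), (2.15, 0.49), (0.0, 8.0)),
        _cont("womac_function", (22.53, 9.25), (22.53, 9.25), (0.0, 68.0)),
        FeatureSpec(
            name="employment", kind="categorical",
            categories=("employed", "unemployed", "retired"),
            probs={g: (81 / 433, 121 / 433, 231 / 433) for g in (0, 1)},
        ),
        FeatureSpec(
            name="education", kind="categorical",
            categories=("primary_or_below", "middle_school", "college_or_above"),
            probs={g: (155 / 433, 234 / 433, 44 / 433) for g in (0, 1)},
        ),
        FeatureSpec(
            name="living_mode", kind="categorical",
            categories=("alone", "with_spouse", "with_children", "whole_family"),
            probs={g: (41 / 433, 232 / 433, 61 / 433, 99 / 433) for g in (0, 1)},
        ),
        FeatureSpec(
            name="mri_bone_marrow_edema", kind="binary", categories=(0, 1),
            probs={g: (244 / 433, 189 / 433) for g in (0, 1)},
        ),
        FeatureSpec(
            name="mri_joint_effusion", kind="binary", categories=(0, 1),
            probs={g: (277 / 433, 156 / 433) for g in (0, 1)},
        ),
    ]


def _draw_continuous(
    rng: np.random.Generator, n: int, mean: float, sd: float, clamp: tuple[float, float] | None
) -> np.ndarray:
    x = rng.normal(mean, sd, size=n)
    if clamp is None:
        return x
    lo, hi = clamp
    if not lo <= mean <= hi:
        raise ValueError(f"clamp range ({lo}, {hi}) excludes the target mean {mean}")
    for _ in range(1000):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("rejection resampling failed to converge")


def _draw_continuous_copula(
    rng: np.random.Generator,
    n: int,
    specs: list[FeatureSpec],
    group: int,
    corr: np.ndarray,
) -> np.ndarray:
    """Correlated draws: latent MVN -> per-feature affine, row-wise rejection."""
    k = len(specs)
    if corr.shape != (k, k):
        raise ValueError("correlation matrix must match the number of continuous features")
    chol = np.linalg.cholesky(corr)
    means = np.array([s.moments[group][0] for s in specs])
    sds = np.array([s.moments[group][1] for s in specs])
    los = np.array([s.clamp[0] if s.clamp else -np.inf for s in specs])
    his = np.array([s.clamp[1] if s.clamp else np.inf for s in specs])
    out = np.empty((n, k))
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            return out
        z = rng.standard_normal((need, k)) @ chol.T
        x = means + z * sds
        ok = np.all((x >= los) & (x <= his), axis=1)
        take = x[ok]
        out[filled : filled + len(take)] = take
        filled += len(take)
    raise RuntimeError("copula rejection resampling failed to converge")


def generate(schema: Sequence[FeatureSpec], config: GenerationConfig) -> CohortTable:
    """Draw a complete cohort with the configured outcome split, fully seeded."""
    rng = np.random.default_rng(config.seed)
    groups = [(1, config.n_caf), (0, config.n_nocaf)]
    cont_specs = [s for s in schema if s.kind == "continuous"]
    frames = []
    for g, n in groups:
        cols: dict[str, np.ndarray | list] = {OUTCOME: np.full(n, g, dtype=int)}
        if config.correlation is not None:
            block = _draw_continuous_copula(rng, n, cont_specs, g, np.asarray(config.correlation))
            for j, s in enumerate(cont_specs):
                cols[s.name] = block[:, j]
        for s in schema:
            if s.kind == "continuous":
                if config.correlation is None:
                    mean, sd = s.moments[g]
                    cols[s.name] = _draw_continuous(rng, n, mean, sd, s.clamp)
            else:
                idx = rng.choice(len(s.categories), size=n, p=np.asarray(s.probs[g], dtype=float))
                cats = np.asarray(s.categories)
                cols[s.name] = cats[idx]
        frames.append(pd.DataFrame(cols))
    frame = pd.concat(frames, ignore_index=True)
    order = [s.name for s in schema] + [OUTCOME]
    frame = frame[order]
    perm = rng.permutation(len(frame))
    frame = frame.iloc[perm].reset_index(drop=True)
    kinds = {s.name: s.kind for s in schema}
    return CohortTable(frame=frame, kinds=kinds)


def label_from_fesi(fesi_total: int) -> int:
    """CAF label from a FES-I total score (16-64): 1 iff score >= 28."""
    if not 16 <= fesi_total <= 64:
        raise ValueError(f"FES-I total must lie in [16, 64], got {fesi_total}")
    return int(fesi_total >= 28)


def planted_signal_dataset(
    n: int,
    n_informative: int,
    n_noise: int,
    effect_size: float,
    seed: int,
) -> CohortTable:
    """Feature-recovery test bed: Gaussian features with a planted mean shift.

    Informative features differ between classes by ``effect_size`` standard
    deviations; noise features are identically distributed in both classes.
    The class balance is 2:1 (positive:negative), mirroring the cohort.
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * 2 / 3))
    n_neg = n - n_pos
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    cols = {}
    for j in range(n_informative):
        x = rng.standard_normal(n)
        x[y == 1] += effect_size
        cols[f"signal_{j + 1}"] = x
    for j in range(n_noise):
        cols[f"noise_{j + 1}"] = rng.standard_normal(n)
    frame = pd.DataFrame(cols)
    frame[OUTCOME] = y
    perm = rng.permutation(n)
    frame = frame.iloc[perm].reset_index(drop=True)
    kinds = {c: "continuous" for c in cols}
    return CohortTable(frame=frame, kinds=kinds)
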