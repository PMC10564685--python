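"""Synthetic questionnaire data with known, planted structure.

The real survey this package was designed around (1173 university students,
17 mostly-binary predictors, six continuous wellbeing outcomes) is
confidential, so analyses are exercised on synthetic data that emulate its
documented marginal structure: each predictor is an independent Bernoulli
draw at the published prevalence, and each outcome is a linear (optionally
interaction-augmented) combination of predictors plus Gaussian noise,
clipped to the instrument's scale.  Because the generating coefficients are
known, the generator provides ground truth for importance-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeding import (
    STREAM_ITEMS,
    STREAM_OUTCOME,
    STREAM_PREDICTORS,
    child_rng,
)

logger = logging.getLogger(__name__)

#: The 17 survey predictors, in questionnaire order (demographics,
#: lifestyle/living situation, wellbeing history, pandemic-related).
PREDICTOR_NAMES: tuple[str, ...] = (
    "Gender",
    "Ethnics",
    "Education",
    "Relationship",
    "Adversity",
    "Exercise",
    "Alcohol",
    "Tobacco",
    "Relation-Impact",
    "Communication",
    "Therapy",
    "Medication",
    "Health-service",
    "Social-distancing",
    "Risk-group",
    "Living-group",
    "Contract-risk",
)

#: Published prevalence of the "positive" (coded 1) level of each
#: dichotomised predictor: female gender, white ethnicity, undergraduate,
#: single, one-or-more adversities, frequent exercise, frequent alcohol,
#: frequent tobacco, relationship impacted, frequent communication, talking
#: therapy history, medication history, health-service access, frequent
#: social distancing, high/increased risk group, cohabiting with at-risk
#: person, feels likely to contract the virus.
DEFAULT_PREVALENCES: tuple[float, ...] = (
    0.704,
    0.672,
    0.470,
    0.451,
    0.866,
    0.303,
    0.180,
    0.120,
    0.723,
    0.604,
    0.405,
    0.277,
    0.342,
    0.934,
    0.149,
    0.301,
    0.165,
)

#: Five-point frequency items eligible for the optional ordinal coding.
ORDINAL_ITEMS: tuple[str, ...] = (
    "Exercise",
    "Alcohol",
    "Tobacco",
    "Communication",
    "Social-distancing",
)

#: Outcome scales (lo, hi): totals of the respective instruments.
OUTCOME_SCALES: dict[str, tuple[float, float]] = {
    "PHQ9": (0.0, 27.0),
    "GAD7": (0.0, 21.0),
    "BRS6": (1.0, 5.0),
    "EQ5D5L": (5.0, 25.0),
    "HealthScore": (0.0, 100.0),
    "SupportNeeds": (0.0, 100.0),
}

DEFAULT_N_SUBJECTS = 1173


def _effects_from(named: dict[str, float]) -> tuple[float, ...]:
    return tuple(float(named.get(name, 0.0)) for name in PREDICTOR_NAMES)


# Per-outcome default generating models.  Effects are placed on the factors
# the published analysis ranked highest for that outcome; intercept and
# noise_sd are chosen so the latent mean and standard deviation approximate
# the published descriptive statistics (e.g. depression total 10.91 +- 6.18).
_DEFAULT_OUTCOME_MODELS: dict[str, dict] = {
    "PHQ9": dict(
        effects={"Relation-Impact": 4.0, "Exercise": -3.0, "Communication": -2.5,
                 "Therapy": 2.5, "Adversity": 2.0},
        intercept=7.7, noise_sd=5.0,
    ),
    "GAD7": dict(
        effects={"Relation-Impact": 4.0, "Communication": -2.5, "Therapy": 2.5,
                 "Adversity": 2.5, "Exercise": -1.5},
        intercept=4.8, noise_sd=5.2,
    ),
    "BRS6": dict(
        effects={"Communication": 0.15, "Ethnics": 0.15, "Adversity": -0.10,
                 "Therapy": -0.10, "Gender": -0.10},
        intercept=3.07, noise_sd=0.28,
    ),
    "EQ5D5L": dict(
        effects={"Therapy": 2.0, "Medication": 1.5, "Health-service": 1.5,
                 "Risk-group": 1.5, "Relation-Impact": 1.0},
        intercept=5.2, noise_sd=2.2,
    ),
    "HealthScore": dict(
        effects={"Exercise": 15.0, "Relation-Impact": -12.0, "Communication": 8.0,
                 "Therapy": -10.0, "Health-service": -8.0},
        intercept=75.6, noise_sd=17.0,
    ),
    "SupportNeeds": dict(
        effects={"Health-service": 20.0, "Medication": 12.0, "Adversity": 12.0,
                 "Ethnics": 10.0, "Relation-Impact": 10.0},
        intercept=-5.0, noise_sd=26.0,
    ),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset (one outcome).

    Identical specs (including ``seed``) produce bit-identical datasets.

    Parameters
    ----------
    n_subjects : int
        Number of respondents (rows).
    prevalences : sequence of float
        Per-predictor Bernoulli success probability, one entry per
        predictor, each in [0, 1].
    effects : sequence of float
        Per-predictor coefficient of the generating linear model.
    intercept : float
        Intercept of the generating model.
    noise_sd : float
        Standard deviation of the additive Gaussian noise (>= 0).
    link : {"linear", "nonlinear-interaction"}
        "linear" is additive; "nonlinear-interaction" adds the single
        pairwise product term declared in ``interaction``.
    interaction : (int, int, float), optional
        Zero-based predictor indices and coefficient of the product term;
        required when ``link="nonlinear-interaction"``.
    outcome_scale : (float, float)
        Outcome values are clipped to this closed interval.
    outcome_label : str
        Name of the outcome column.
    predictor_names : sequence of str
        Column labels; length must match ``prevalences``.
    ordinal : bool
        If True, the five-point frequency items are emitted as ordinal
        codes 1..5 instead of binary 0/1 (the dichotomised prevalence is
        split over the top two levels, its complement over the lower three).
    seed : int
        Master seed of the generator.
    """

    n_subjects: int = DEFAULT_N_SUBJECTS
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    effects: tuple[float, ...] = field(default_factory=lambda: (0.0,) * 17)
    intercept: float = 0.0
    noise_sd: float = 1.0
    link: str = "linear"
    interaction: tuple[int, int, float] | None = None
    outcome_scale: tuple[float, float] = (0.0, 27.0)
    outcome_label: str = "PHQ9"
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    ordinal: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "prevalences", tuple(float(p) for p in self.prevalences))
        object.__setattr__(self, "effects", tuple(float(e) for e in self.effects))
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        object.__setattr__(self, "outcome_scale", tuple(float(v) for v in self.outcome_scale))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive count")
        if len(self.predictor_names) != len(self.prevalences):
            raise ValueError("predictor_names and prevalences length mismatch")
        if any(not (0.0 <= p <= 1.0) for p in self.prevalences):
            raise ValueError("prevalences must all lie in [0, 1]")
        if len(self.effects) != len(self.prevalences):
            raise ValueError(
                f"effects has length {len(self.effects)}, expected {len(self.prevalences)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.link not in ("linear", "nonlinear-interaction"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "nonlinear-interaction":
            if self.interaction is None:
                raise ValueError("nonlinear-interaction link requires `interaction`")
            i, j, _ = self.interaction
            p = len(self.prevalences)
            if not (0 <= int(i) < p and 0 <= int(j) < p):
                raise ValueError("interaction indices out of range")
        lo, hi = self.outcome_scale
        if lo >= hi:
            raise ValueError("outcome_scale must satisfy lo < hi")

    @property
    def n_predictors(self) -> int:
        return len(self.prevalences)

    def with_effects(self, named_effects: dict[str, float], **overrides) -> "SyntheticSpec":
        """Copy of the spec with effects given by predictor name."""
        unknown = set(named_effects) - set(self.predictor_names)
        if unknown:
            raise KeyError(f"unknown predictors: {sorted(unknown)}")
        effects = tuple(
            float(named_effects.get(name, 0.0)) for name in self.predictor_names
        )
        return dataclasses.replace(self, effects=effects, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interaction"] = list(self.interaction) if self.interaction else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if d.get("interaction") is not None:
            d["interaction"] = tuple(d["interaction"])
        return cls(**d)


def default_spec(outcome: str = "PHQ9", n_subjects: int = DEFAULT_N_SUBJECTS,
                 seed: int = 0, **overrides) -> SyntheticSpec:
    """Default generating model for one of the six survey outcomes."""
    if outcome not in OUTCOME_SCALES:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {sorted(OUTCOME_SCALES)}")
    model = _DEFAULT_OUTCOME_MODELS[outcome]
    return SyntheticSpec(
        n_subjects=n_subjects,
        effects=_effects_from(model["effects"]),
        intercept=model["intercept"],
        noise_sd=model["noise_sd"],
        outcome_scale=OUTCOME_SCALES[outcome],
        outcome_label=outcome,
        seed=seed,
        **overrides,
    )


def generate_predictors(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the predictor matrix declared by ``spec``.

    Each column j is i.i.d. Bernoulli(prevalences[j]) coded 0/1.  With
    ``spec.ordinal`` the five-point frequency items are instead coded 1..5:
    levels 4-5 share the dichotomised prevalence equally and levels 1-3
    share its complement equally, so thresholding at >= 4 recovers the
    binary coding.  Deterministic under ``spec.seed``.
    """
    rng = child_rng(spec.seed, STREAM_PREDICTORS)
    n, p = spec.n_subjects, spec.n_predictors
    columns = {}
    for j, (name, prev) in enumerate(zip(spec.predictor_names, spec.prevalences)):
        if spec.ordinal and name in ORDINAL_ITEMS:
            probs = np.array([(1 - prev) / 3] * 3 + [prev / 2] * 2)
            columns[name] = rng.choice(np.arange(1, 6), size=n, p=probs)
        else:
            columns[name] = (rng.random(n) < prev).astype(np.int64)
    X = pd.DataFrame(columns, columns=list(spec.predictor_names))
    assert X.shape == (n, p) and not X.isna().any().any()
    return X


def generate_outcome(X: pd.DataFrame, spec: SyntheticSpec) -> pd.Series:
    """Draw the outcome vector for an existing predictor matrix.

    linear link:  y = intercept + X @ effects + Normal(0, noise_sd),
    clipped to ``spec.outcome_scale``.  The nonlinear-interaction link adds
    the declared pairwise product term.  The number of clipped values is
    logged and recorded in ``y.attrs["n_clipped"]``.
    """
    if X.shape[1] != spec.n_predictors:
        raise ValueError(
            f"predictor matrix has {X.shape[1]} columns, spec declares {spec.n_predictors}"
        )
    rng = child_rng(spec.seed, STREAM_OUTCOME)
    values = np.asarray(X, dtype=float)
    linear = spec.intercept + values @ np.asarray(spec.effects)
    if spec.link == "nonlinear-interaction":
        i, j, coef = spec.interaction
        linear = linear + coef * values[:, int(i)] * values[:, int(j)]
    y = linear + rng.normal(0.0, spec.noise_sd, size=len(X))
    lo, hi = spec.outcome_scale
    n_clipped = int(np.count_nonzero((y < lo) | (y > hi)))
    if n_clipped:
        logger.info("clipped %d/%d outcome values to [%g, %g]", n_clipped, len(y), lo, hi)
    y = np.clip(y, lo, hi)
    out = pd.Series(y, index=X.index, name=spec.outcome_label)
    out.attrs["scale"] = (lo, hi)
    out.attrs["n_clipped"] = n_clipped
    return out


def generate_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Predictors plus the one outcome column declared by ``spec``."""
    X = generate_predictors(spec)
    y = generate_outcome(X, spec)
    df = X.copy()
    df[spec.outcome_label] = y
    return df


def generate_survey(n_subjects: int = DEFAULT_N_SUBJECTS, seed: int = 0,
                    outcomes: Sequence[str] = tuple(OUTCOME_SCALES)) -> pd.DataFrame:
    """A full survey table: one predictor matrix, all requested outcomes.

    All outcomes are generated from the same predictor draw; outcome noise
    streams differ per outcome (keyed by position in ``OUTCOME_SCALES``).
    """
    base = default_spec(outcomes[0] if outcomes else "PHQ9", n_subjects=n_subjects, seed=seed)
    X = generate_predictors(base)
    df = X.copy()
    for outcome in outcomes:
        sub_seed = child_rng(seed, STREAM_OUTCOME, sorted(OUTCOME_SCALES).index(outcome))
        spec = default_spec(outcome, n_subjects=n_subjects,
                            seed=int(sub_seed.integers(2**31)))
        df[outcome] = generate_outcome(X, spec)
    return df


def generate_instrument_items(total: int, n_items: int, item_range: tuple[int, int],
                              seed: int = 0) -> np.ndarray:
    """Integer item vector of length ``n_items`` in ``item_range`` summing to ``total``.

    Any valid composition is acceptable (uniformity over compositions is
    not promised).  Items start at the scale floor and the remaining mass
    is placed one unit at a time on a random item with spare capacity, so
    re-scoring by summation round-trips exactly.
    """
    lo, hi = int(item_range[0]), int(item_range[1])
    total = int(total)
    if lo > hi:
        raise ValueError("item_range must satisfy lo <= hi")
    if not (n_items * lo <= total <= n_items * hi):
        raise ValueError(
            f"total {total} infeasible for {n_items} items in [{lo}, {hi}]"
        )
    rng = child_rng(seed, STREAM_ITEMS)
    items = np.full(n_items, lo, dtype=np.int64)
    for _ in range(total - n_items * lo):
        open_slots = np.flatnonzero(items < hi)
        items[open_slots[rng.integers(len(open_slots))]] += 1
    assert items.sum() == total
    return items


def write_dataset(df: pd.DataFrame, path: str | Path, spec: SyntheticSpec | None = None) -> Path:
    """Write a dataset as headered CSV with a JSON sidecar of its spec."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return path
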