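"""Binary growth-state observers built on support vector machines.

An observer predicts whether a seedling's growth parameter is in a "good"
(+1) or "bad" (-1) state from environmental and/or physiological inputs.
The label of sample i for growth variable g is ``sign(g_i - mean(g))``,
with a value exactly at the mean labelled good.

Three training strategies are supported:

* ``L``   — linear-kernel SVM with fixed cost C;
* ``R``   — RBF-kernel SVM ``K(x, x') = exp(-gamma ||x - x'||^2)`` with
            fixed C and gamma (default gamma = 1 / n_features);
* ``Rac`` — RBF-kernel SVM with hyperparameters chosen by cross-validated
            grid search over C in {2^-5, 2^-3, ..., 2^15} and gamma in
            {2^-15, 2^-13, ..., 2^3} on the training split only.

Features are affinely scaled to [-1, 1] column-wise using training min/max
(test values outside the training range extrapolate outside [-1, 1], which
is permitted).  The train/test split is random but stratified by trial so
every environmental condition is represented in training.  The quadratic
programme inside each SVM is delegated to scikit-learn's SVC; labeling,
scaling, splitting, the strategy layer, evaluation and strategy comparison
are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .blocks import GROWTH_NAMES, SeedlingDataset, physio_columns
from .screening import FULL_COMBINATIONS, FeatureCombination

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSamples",
    "ObserverStrategy",
    "RangeScaler",
    "ObserverModel",
    "EvaluationReport",
    "label_growth",
    "split_dataset",
    "scale_features",
    "train_observer",
    "evaluate",
    "compare_strategies",
    "select_final_model",
    "RosterEntry",
    "default_roster",
    "run_roster",
]

STRATEGY_KINDS = ("L", "R", "Rac")
#: Tie-break preference between strategies for final-model selection.
_STRATEGY_RANK = {"Rac": 0, "L": 1, "R": 2}

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))


class TrainingError(ValueError):
    """Raised when a model cannot be trained (e.g. single-class labels)."""


@dataclass
class LabeledSamples:
    """A feature matrix with +/-1 labels for one growth target."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    combination: str = ""
    target: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features disagree in sample count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names do not match feature columns")

    def subset(self, idx: np.ndarray) -> "LabeledSamples":
        return LabeledSamples(
            self.features[idx], self.labels[idx], self.feature_names,
            self.combination, self.target,
        )


@dataclass(frozen=True)
class ObserverStrategy:
    """SVM training strategy: kernel kind plus hyperparameter policy."""

    kind: str = "Rac"
    C: float = 1.0
    gamma: float | None = None        # None -> 1 / n_features (R only)
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"kind must be one of {STRATEGY_KINDS}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class RangeScaler:
    """Affine per-column map of training min/max onto [-1, 1].

    A zero-range training column maps to 0 everywhere (it carries no
    information on the training split).
    """

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, train_features: np.ndarray) -> "RangeScaler":
        train_features = np.asarray(train_features, dtype=float)
        mins = train_features.min(axis=0)
        ranges = train_features.max(axis=0) - mins
        degenerate = np.flatnonzero(ranges == 0.0)
        if degenerate.size:
            logger.warning(
                "zero-range training column(s) %s map to 0", degenerate.tolist()
            )
        return cls(mins=mins, ranges=ranges)

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        out = np.zeros_like(features)
        ok = self.ranges != 0.0
        out[:, ok] = 2.0 * (features[:, ok] - self.mins[ok]) / self.ranges[ok] - 1.0
        return out


@dataclass
class ObserverModel:
    """A trained growth-state observer with its scaling transform."""

    strategy: ObserverStrategy
    svc: SVC
    scaler: RangeScaler
    feature_names: tuple[str, ...]
    combination: str
    target: str
    chosen_params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(features))

    def predict(self, features: np.ndarray) -> np.ndarray:
        """+1 where the decision value is >= 0 (ties at the boundary are
        'good', mirroring the >= convention of the labeling rule)."""
        return np.where(self.decision_values(features) >= 0.0, 1, -1)


def label_growth(values: np.ndarray) -> np.ndarray:
    """Good/bad labels: +1 where the value is >= the mean of all values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("need at least one finite growth value")
    return np.where(values >= values.mean(), 1, -1)


def split_dataset(
    trial_ids: np.ndarray | SeedlingDataset,
    n_train: int = 48,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test split stratified by trial.

    Training slots are allocated to trials proportionally to trial size
    (largest-remainder rounding, at least one per trial when capacity
    allows), then filled by seeded shuffling within each trial.  The same
    seed always yields the same partition.
    """
    if isinstance(trial_ids, SeedlingDataset):
        trial_ids = trial_ids.trial_ids
    trial_ids = np.asarray(trial_ids)
    n = len(trial_ids)
    if not 0 < n_train < n:
        raise ValueError(f"n_train={n_train} must lie strictly between 0 and n={n}")
    rng = np.random.default_rng(seed)
    trials = list(dict.fromkeys(trial_ids.tolist()))  # first-appearance order
    members = {t: np.flatnonzero(trial_ids == t) for t in trials}

    sizes = np.array([len(members[t]) for t in trials], dtype=float)
    exact = n_train * sizes / n
    quota = np.floor(exact).astype(int)
    if n_train >= len(trials):
        quota = np.maximum(quota, 1)
    quota = np.minimum(quota, sizes.astype(int))
    # Largest-remainder adjustment to hit n_train exactly.
    while quota.sum() < n_train:
        remainders = np.where(quota < sizes, exact - quota, -np.inf)
        quota[int(np.argmax(remainders))] += 1
    while quota.sum() > n_train:
        over = np.where(quota > 0, quota - exact, -np.inf)
        quota[int(np.argmax(over))] -= 1

    train: list[int] = []
    test: list[int] = []
    for t, k in zip(trials, quota):
        idx = members[t].copy()
        rng.shuffle(idx)
        train.extend(idx[:k].tolist())
        test.extend(idx[k:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def scale_features(
    train_features: np.ndarray, test_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, RangeScaler]:
    """Scale train and test features with a transform fit on training only."""
    scaler = RangeScaler.fit(train_features)
    return scaler.transform(train_features), scaler.transform(test_features), scaler


def train_observer(
    train: LabeledSamples,
    strategy: ObserverStrategy,
    scaler: RangeScaler | None = None,
) -> ObserverModel:
    """Train one observer on (already labelled) training samples."""
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise TrainingError(
            f"target {train.target!r}: training labels contain a single class "
            f"({int(classes[0]):+d}); an observer cannot be trained"
        )
    scaler = scaler or RangeScaler.fit(train.features)
    x = scaler.transform(train.features)
    y = train.labels
    n_feat = train.features.shape[1]

    if strategy.kind == "L":
        svc = SVC(kernel="linear", C=strategy.C)
        svc.fit(x, y)
        chosen = {"C": strategy.C}
    elif strategy.kind == "R":
        gamma = strategy.gamma if strategy.gamma is not None else 1.0 / n_feat
        svc = SVC(kernel="rbf", C=strategy.C, gamma=gamma)
        svc.fit(x, y)
        chosen = {"C": strategy.C, "gamma": gamma}
    else:  # Rac
        min_class = int(np.bincount((y == 1).astype(int)).min())
        folds = max(2, min(strategy.cv_folds, min_class))
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(strategy.c_grid), "gamma": list(strategy.gamma_grid)},
            cv=StratifiedKFold(n_splits=folds, shuffle=False),
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(x, y)
        svc = search.best_estimator_
        chosen = {k: float(v) for k, v in search.best_params_.items()}
        chosen["cv_folds"] = folds

    return ObserverModel(
        strategy=strategy, svc=svc, scaler=scaler,
        feature_names=train.feature_names, combination=train.combination,
        target=train.target, chosen_params=chosen,
    )


def evaluate(model: ObserverModel, test: LabeledSamples) -> float:
    """Fraction of test samples predicted correctly."""
    if len(test.labels) == 0:
        raise ValueError("test set is empty")
    if tuple(test.feature_names) != tuple(model.feature_names):
        raise ValueError(
            f"feature mismatch: model expects {list(model.feature_names)}, "
            f"got {list(test.feature_names)}"
        )
    return float(np.mean(model.predict(test.features) == test.labels))


@dataclass
class ModelEvaluation:
    """One trained model with its test success rate and grouping keys."""

    strategy: str
    feature_class: str          # "e", "p", or "e+p"
    target: str                 # growth column, e.g. "g1_d9"
    target_name: str            # Plant_Height / Leaf_Area / Fresh_Weight / Dry_Weight
    combination: str
    success_rate: float
    n_features: int
    model: ObserverModel | None = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "feature_class": self.feature_class,
            "target": self.target,
            "target_name": self.target_name,
            "combination": self.combination,
            "success_rate": self.success_rate,
            "n_features": self.n_features,
        }


@dataclass
class EvaluationReport:
    """Per-model success rates for a batch of trained observers."""

    evaluations: list[ModelEvaluation] = field(default_factory=list)

    def rates(self, **filters: str) -> list[float]:
        out = []
        for ev in self.evaluations:
            if all(getattr(ev, k) == v for k, v in filters.items()):
                out.append(ev.success_rate)
        return out

    def to_dict(self) -> dict:
        return {"evaluations": [ev.to_dict() for ev in self.evaluations]}


def compare_strategies(report: EvaluationReport) -> dict:
    """Min/avg/max success rate per (strategy, feature class, target).

    Mirrors the 3 strategies x 3 feature classes comparison: for each
    growth parameter there are up to 9 groups; groups without any evaluated
    model are omitted with a warning.
    """
    targets = sorted({ev.target_name for ev in report.evaluations})
    strategies = [s for s in STRATEGY_KINDS
                  if any(ev.strategy == s for ev in report.evaluations)]
    summary: dict[str, dict[str, dict]] = {}
    for tgt in targets:
        summary[tgt] = {}
        for strat in strategies:
            for fclass in ("e", "p", "e+p"):
                rates = report.rates(
                    strategy=strat, feature_class=fclass, target_name=tgt
                )
                key = f"{strat}({fclass})"
                if not rates:
                    warnings.warn(
                        f"no models in group {key} for target {tgt}; omitted",
                        stacklevel=2,
                    )
                    continue
                summary[tgt][key] = {
                    "min": float(np.min(rates)),
                    "avg": float(np.mean(rates)),
                    "max": float(np.max(rates)),
                    "n_models": len(rates),
                }
    return summary


def select_final_model(
    evaluations: list[ModelEvaluation], target: str
) -> ModelEvaluation:
    """Best observer for a target: highest test success rate, ties broken
    by fewer input features, then by strategy preference Rac > L > R."""
    candidates = [ev for ev in evaluations if ev.target == target]
    if not candidates:
        raise ValueError(f"no evaluated model for target {target!r}")
    return min(
        candidates,
        key=lambda ev: (-ev.success_rate, ev.n_features,
                        _STRATEGY_RANK.get(ev.strategy, 9)),
    )


# --------------------------------------------------------------------------
# The model roster: which feature set predicts which growth block.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RosterEntry:
    """One observer family: a feature recipe and a target growth block.

    ``env`` and ``physio`` name feature combinations (or None); the physio
    combination is read from the physiological block ``physio_block``.  The
    entry expands into one model per growth variable of ``target_block``
    (height and leaf-area increments for G1/G2; those plus fresh and dry
    weight for G3, where the single day-9 weight measurements live).
    """

    name: str
    feature_class: str          # "e", "p", or "e+p"
    target_block: str           # "G1" | "G2" | "G3"
    env: str | None = None      # e.g. "E_8D", "E_6D"
    physio: str | None = None   # e.g. "P_10D", "P_8D_6_9"
    physio_block: str | None = None   # "P1".."P4"


def default_roster() -> tuple[RosterEntry, ...]:
    """The 20 observer families of the reference modeling comparison:
    6 environmental, 8 physiological and 6 combined."""
    return (
        # environment only
        RosterEntry("E_6D->G1", "e", "G1", env="E_6D"),
        RosterEntry("E_6D->G2", "e", "G2", env="E_6D"),
        RosterEntry("E_6D->G3", "e", "G3", env="E_6D"),
        RosterEntry("E_8D->G1", "e", "G1", env="E_8D"),
        RosterEntry("E_8D->G2", "e", "G2", env="E_8D"),
        RosterEntry("E_8D->G3", "e", "G3", env="E_8D"),
        # physiology only
        RosterEntry("P2->G1", "p", "G1", physio="P_10D", physio_block="P2"),
        RosterEntry("P3->G2", "p", "G2", physio="P_10D", physio_block="P3"),
        RosterEntry("P4->G3", "p", "G3", physio="P_10D", physio_block="P4"),
        RosterEntry("P1->G3", "p", "G3", physio="P_10D", physio_block="P1"),
        RosterEntry("P2->G3", "p", "G3", physio="P_10D", physio_block="P2"),
        RosterEntry("P3->G3", "p", "G3", physio="P_10D", physio_block="P3"),
        RosterEntry("P3_8D->G2", "p", "G2", physio="P_8D_6_9", physio_block="P3"),
        RosterEntry("P4_9D->G3", "p", "G3", physio="P_9D_9", physio_block="P4"),
        # environment + physiology
        RosterEntry("E_8D+P2->G1", "e+p", "G1", env="E_8D",
                    physio="P_10D", physio_block="P2"),
        RosterEntry("E_8D+P3->G2", "e+p", "G2", env="E_8D",
                    physio="P_10D", physio_block="P3"),
        RosterEntry("E_8D+P4->G3", "e+p", "G3", env="E_8D",
                    physio="P_10D", physio_block="P4"),
        RosterEntry("E_6D+P3_8D->G2", "e+p", "G2", env="E_6D",
                    physio="P_8D_6_9", physio_block="P3"),
        RosterEntry("E_6D+P3_8D_9_10->G3", "e+p", "G3", env="E_6D",
                    physio="P_8D_9_10", physio_block="P3"),
        RosterEntry("E_6D+P4_9D->G3", "e+p", "G3", env="E_6D",
                    physio="P_9D_9", physio_block="P4"),
    )


def _target_columns(block: str) -> list[str]:
    day = {"G1": 3, "G2": 6, "G3": 9}[block]
    cols = [f"g1_d{day}", f"g2_d{day}"]
    if block == "G3":
        cols += ["g3", "g4"]
    return cols


def _default_combinations() -> dict[str, FeatureCombination]:
    """Full blocks plus the four simplified presets derived from the
    packaged reference screening verdicts."""
    from .reference import screening_results
    from .screening import COMBINATION_PRESETS, derive_preset

    combos = dict(FULL_COMBINATIONS)
    results = screening_results()
    for name in COMBINATION_PRESETS:
        combos[name] = derive_preset(name, results)
    return combos


def entry_feature_columns(
    entry: RosterEntry,
    combinations: Mapping[str, FeatureCombination] | None = None,
) -> list[str]:
    """Dataset columns realising a roster entry's feature recipe.

    Combination names resolve against ``combinations`` first, then the
    defaults (full blocks and the reference-derived simplified presets).
    """
    combos = _default_combinations()
    if combinations:
        combos.update(combinations)
    cols: list[str] = []
    if entry.env is not None:
        cols += list(combos[entry.env].parameter_ids)
    if entry.physio is not None:
        if entry.physio_block is None:
            raise ValueError(f"entry {entry.name!r}: physio combination without block")
        stage_cols = dict(zip(
            (f"p{i}" for i in range(1, 11)), physio_columns(entry.physio_block)
        ))
        cols += [stage_cols[p] for p in combos[entry.physio].parameter_ids]
    if not cols:
        raise ValueError(f"entry {entry.name!r} selects no features")
    return cols


def run_roster(
    dataset: SeedlingDataset,
    strategies: tuple[str | ObserverStrategy, ...] = ("L", "R", "Rac"),
    seed: int = 0,
    entries: tuple[RosterEntry, ...] | None = None,
    combinations: Mapping[str, FeatureCombination] | None = None,
    n_train: int = 48,
) -> EvaluationReport:
    """Label, split, scale, train and evaluate a roster of observers.

    One train/test split (stratified by trial, seeded) is shared by every
    model so success rates are comparable across strategies and feature
    sets.  Labels are assigned from the mean over all samples before
    splitting.  Targets whose training labels collapse to one class are
    skipped with a warning.
    """
    entries = entries or default_roster()
    train_idx, test_idx = split_dataset(dataset.trial_ids, n_train=n_train, seed=seed)
    report = EvaluationReport()
    for entry in entries:
        feat_cols = entry_feature_columns(entry, combinations)
        features = dataset.frame[feat_cols].to_numpy(dtype=float)
        for tcol in _target_columns(entry.target_block):
            labels = label_growth(dataset.frame[tcol].to_numpy(dtype=float))
            samples = LabeledSamples(
                features, labels, tuple(feat_cols), entry.name, tcol
            )
            train, test = samples.subset(train_idx), samples.subset(test_idx)
            for strat in strategies:
                if isinstance(strat, str):
                    strat = ObserverStrategy(kind=strat)
                try:
                    model = train_observer(train, strat)
                except TrainingError as exc:
                    warnings.warn(str(exc), stacklevel=2)
                    continue
                rate = evaluate(model, test)
                report.evaluations.append(ModelEvaluation(
                    strategy=strat.kind, feature_class=entry.feature_class,
                    target=tcol, target_name=GROWTH_NAMES[tcol.split("_")[0]],
                    combination=entry.name, success_rate=rate,
                    n_features=len(feat_cols), model=model,
                ))
    return report
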