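"""Candidate selection and iterative backward feature pruning.

One pruning run ("IT" step) works on a fixed random 80/20 train/test
split.  At each complexity level a full dual-objective search is executed
on the current feature subset; the Pareto front is collapsed to a single
candidate with the one-standard-error rule (simplest model — lowest
support-vector ratio — whose CV MAE is within one standard error of the
best front member); the candidate is refit, its features ranked by
permutation importance on a seeded carve-out of the training split, and
the least important feature is eliminated.  The loop repeats down to
``min_features``, yielding one candidate per descriptor count.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.svm import NuSVR

from ._seed import derive_seed
from .config import RunConfig
from .doo import (HyperParams, SplitSpec, TrialResult, gamma_base, make_split,
                  pareto_front, run_doo, standardize)

__all__ = [
    "CandidateModel",
    "PruningTrace",
    "select_1se",
    "permutation_importance",
    "dooit_run",
]


@dataclass(frozen=True)
class CandidateModel:
    """The model selected at one pruning level of one run."""

    feature_names: tuple[str, ...]
    params: HyperParams
    cv_mae: float
    cv_mae_se: float
    sv_ratio: float
    train_mae: float
    test_mae: float
    train_r2: float
    test_r2: float
    importances: dict[str, float]
    removed_feature: str | None = None  # feature dropped after this level

    def __post_init__(self) -> None:
        if set(self.importances) != set(self.feature_names):
            raise ValueError("importances must cover exactly the feature names")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "features": list(self.feature_names),
            "params": {"nu": self.params.nu, "C": self.params.C,
                       "log10_gamma_scale": self.params.log10_gamma_scale},
            "cv_mae": self.cv_mae,
            "cv_mae_se": self.cv_mae_se,
            "sv_ratio": self.sv_ratio,
            "train_mae": self.train_mae,
            "test_mae": self.test_mae,
            "train_r2": self.train_r2,
            "test_r2": self.test_r2,
            "importances": self.importances,
            "removed_feature": self.removed_feature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateModel":
        return cls(
            feature_names=tuple(d["features"]),
            params=HyperParams(**d["params"]),
            cv_mae=d["cv_mae"], cv_mae_se=d["cv_mae_se"],
            sv_ratio=d["sv_ratio"], train_mae=d["train_mae"],
            test_mae=d["test_mae"], train_r2=d["train_r2"],
            test_r2=d["test_r2"], importances=dict(d["importances"]),
            removed_feature=d.get("removed_feature"),
        )


@dataclass(frozen=True)
class PruningTrace:
    """Candidates of one run, from the full feature set down to min_features."""

    run_id: int
    split_seed: int
    candidates: tuple[CandidateModel, ...]

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.candidates, self.candidates[1:]):
            if prev.n_features - nxt.n_features != 1:
                raise ValueError("consecutive candidates must differ by one feature")
            gone = set(prev.feature_names) - set(nxt.feature_names)
            if gone != {prev.removed_feature}:
                raise ValueError(
                    "removed feature must be the one missing from the next level")

    def candidate_at(self, n_features: int) -> CandidateModel | None:
        for c in self.candidates:
            if c.n_features == n_features:
                return c
        return None

    def to_dict(self) -> dict:
        return {"run_id": self.run_id, "split_seed": self.split_seed,
                "levels": [c.to_dict() for c in self.candidates]}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True,
                       ensure_ascii=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PruningTrace":
        return cls(run_id=d["run_id"], split_seed=d["split_seed"],
                   candidates=tuple(CandidateModel.from_dict(l)
                                    for l in d["levels"]))

    @classmethod
    def read_json(cls, path: str | Path) -> "PruningTrace":
        return cls.from_dict(json.loads(Path(path).read_text()))


def select_1se(front: Sequence[TrialResult]) -> TrialResult:
    """One-standard-error rule on a Pareto front.

    The best front member minimises CV MAE; its standard error is the
    sample SD of its per-fold MAEs divided by sqrt(k).  Among members whose
    CV MAE does not exceed best + SE, the one with the lowest SV ratio is
    returned (ties: lower CV MAE, then lower trial id).
    """
    members = [t for t in front if t.status == "ok"]
    if not members:
        raise ValueError("select_1se needs a non-empty front")
    best = min(members, key=lambda t: (t.cv_mae, t.trial_id))
    se = one_se(best)
    eligible = [t for t in members if t.cv_mae <= best.cv_mae + se]
    return min(eligible, key=lambda t: (t.sv_ratio, t.cv_mae, t.trial_id))


def one_se(trial: TrialResult) -> float:
    """Standard error of a trial's mean fold MAE (sample SD / sqrt(k))."""
    k = len(trial.fold_maes)
    if k < 2:
        return 0.0
    return float(np.std(trial.fold_maes, ddof=1) / math.sqrt(k))


def permutation_importance(
    predictor,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean MAE increase when one feature column is shuffled.

    importance_j = mean over repeats of (MAE with column j permuted −
    baseline MAE).  A feature the predictor ignores scores exactly zero.
    """
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if X_val.shape[0] < 2:
        raise ValueError("permutation importance needs at least two validation rows")
    res = _sk_permutation_importance(
        predictor, X_val, y_val, scoring="neg_mean_absolute_error",
        n_repeats=n_repeats, random_state=seed)
    return res.importances_mean


class _FittedCandidate(RegressorMixin, BaseEstimator):
    """A scaler + nuSVR pair fit on given rows of a feature matrix."""

    def __init__(self, X: np.ndarray, y: np.ndarray, params: HyperParams,
                 gamma_base_value: float, cfg: RunConfig):
        self.params = params
        (self._Xs, _, self._means, self._sds, self._kept) = standardize(X)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            self._svr = NuSVR(nu=params.nu, C=params.C,
                              gamma=params.gamma(gamma_base_value),
                              tol=cfg.svr_tol, max_iter=cfg.svr_max_iter)
            self._svr.fit(self._Xs, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._svr.predict((X[:, self._kept] - self._means) / self._sds)

    # sklearn's permutation_importance probes the estimator for fit status
    def fit(self, X, y):  # pragma: no cover - never refit through sklearn
        raise RuntimeError("refit through _FittedCandidate is not supported")

    def __sklearn_is_fitted__(self) -> bool:
        return True


def _mae(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(a - b)))


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def dooit_run(
    frame: pd.DataFrame,
    feature_names: Sequence[str],
    target: str,
    split_seed: int,
    config: RunConfig | None = None,
    run_id: int = 0,
    n_trials: int | None = None,
) -> PruningTrace:
    """One full DOO-IT run on a fresh 80/20 split.

    Per level: dual-objective search -> Pareto front -> 1-SE candidate ->
    refit on the full training split for train/test metrics -> permutation
    importance on a seeded 20% carve-out of the training split -> drop the
    least important feature.  The held-out test rows are only ever used for
    the reported test metrics, never for selection.
    """
    cfg = config or RunConfig()
    n_trials = cfg.n_trials if n_trials is None else n_trials
    features = list(feature_names)
    if len(features) <= cfg.min_features - 1:
        raise ValueError("need more features than min_features to prune")

    split = make_split(len(frame), split_seed, cfg.train_fraction)
    y_all = frame[target].to_numpy(dtype=float)
    levels: list[CandidateModel] = []
    level_idx = 0
    while len(features) >= cfg.min_features:
        try:
            candidate = _run_level(frame, features, y_all, split, cfg,
                                   split_seed, level_idx, n_trials)
        except Exception as exc:
            raise RuntimeError(
                f"run {run_id}: failure at pruning iteration {level_idx} "
                f"({len(features)} features)") from exc
        if len(features) > cfg.min_features:
            # eliminate the least important feature (first index on ties)
            imps = np.array([candidate.importances[f] for f in features])
            removed = features[int(np.argmin(imps))]
            candidate = dataclasses.replace(candidate, removed_feature=removed)
            features = [f for f in features if f != removed]
        else:
            features = []
        levels.append(candidate)
        level_idx += 1
    return PruningTrace(run_id=run_id, split_seed=split_seed,
                        candidates=tuple(levels))


def _run_level(
    frame: pd.DataFrame,
    features: list[str],
    y_all: np.ndarray,
    split: SplitSpec,
    cfg: RunConfig,
    split_seed: int,
    level_idx: int,
    n_trials: int,
) -> CandidateModel:
    X_all = frame[features].to_numpy(dtype=float)
    X_train, y_train = X_all[split.train_indices], y_all[split.train_indices]
    X_test, y_test = X_all[split.test_indices], y_all[split.test_indices]

    doo_seed = derive_seed(split_seed, 101, level_idx)
    trials = run_doo(X_train, y_train, n_trials=n_trials, seed=doo_seed,
                     config=cfg)
    front = pareto_front(trials)
    chosen = select_1se(front)

    X_std, *_ = standardize(X_train)
    gb = gamma_base(X_std, seed=doo_seed, max_rows=cfg.gamma_subsample)

    # train/test metrics from a refit on the full training split
    full_fit = _FittedCandidate(X_train, y_train, chosen.params, gb, cfg)
    train_pred = full_fit.predict(X_train)
    test_pred = full_fit.predict(X_test)

    # importance from a fit on the training remainder, evaluated on a
    # seeded carve-out; the test split stays untouched
    carve_rng = np.random.default_rng(derive_seed(split_seed, 202, level_idx))
    n_tr = X_train.shape[0]
    n_val = max(2, int(round(n_tr * cfg.importance_fraction)))
    perm = carve_rng.permutation(n_tr)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    imp_fit = _FittedCandidate(X_train[fit_idx], y_train[fit_idx],
                               chosen.params, gb, cfg)
    imps = permutation_importance(
        imp_fit, X_train[val_idx], y_train[val_idx],
        n_repeats=cfg.n_permutation_repeats,
        seed=derive_seed(split_seed, 303, level_idx))

    return CandidateModel(
        feature_names=tuple(features),
        params=chosen.params,
        cv_mae=chosen.cv_mae,
        cv_mae_se=one_se(chosen),
        sv_ratio=chosen.sv_ratio,
        train_mae=_mae(train_pred, y_train),
        test_mae=_mae(test_pred, y_test),
        train_r2=_r2(y_train, train_pred),
        test_r2=_r2(y_test, test_pred),
        importances={f: float(v) for f, v in zip(features, imps)},
    )
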