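"""Dual-objective nuSVR hyperparameter search.

For a fixed feature subset, each trial draws a hyperparameter triple
(nu, C, log10_gamma_scale), evaluates it by k-fold cross-validation on the
training split, and records two competing objectives: the mean absolute
error (accuracy) and the mean support-vector ratio (model complexity —
support vectors per fold-training sample, which nu lower-bounds in the
nu-SVR formulation).  The non-dominated trials form the Pareto front from
which downstream selection picks a candidate.

The RBF kernel width is anchored at ``gamma_base``, the inverse median
pairwise squared Euclidean distance of the (standardized) training
features — the classic median heuristic — and the sampler searches only a
logarithmic scaling factor around that anchor.  The sampler is a seeded
random search over the configured box (C log-uniform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import KFold
from sklearn.svm import NuSVR

from .config import RunConfig

__all__ = [
    "HyperParams",
    "TrialResult",
    "SplitSpec",
    "make_split",
    "standardize",
    "gamma_base",
    "evaluate_trial",
    "run_doo",
    "pareto_front",
]


@dataclass(frozen=True)
class HyperParams:
    """One nuSVR hyperparameter triple.

    ``gamma`` is realised as ``gamma_base * 10**log10_gamma_scale`` with
    ``gamma_base`` bound at evaluation time.
    """

    nu: float
    C: float
    log10_gamma_scale: float

    def __post_init__(self) -> None:
        if not (0.0 < self.nu <= 1.0):
            raise ValueError(f"nu must lie in (0, 1], got {self.nu}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")

    def gamma(self, gamma_base_value: float) -> float:
        return gamma_base_value * 10.0 ** self.log10_gamma_scale


@dataclass(frozen=True)
class TrialResult:
    """Cross-validated objectives of one hyperparameter trial."""

    trial_id: int
    params: HyperParams
    fold_maes: np.ndarray
    fold_sv_ratios: np.ndarray
    cv_mae: float
    sv_ratio: float
    status: str = "ok"  # "ok" | "failed"

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "nu": self.params.nu,
            "C": self.params.C,
            "log10_gamma_scale": self.params.log10_gamma_scale,
            "fold_maes": [float(v) for v in self.fold_maes],
            "fold_sv_ratios": [float(v) for v in self.fold_sv_ratios],
            "cv_mae": float(self.cv_mae),
            "sv_ratio": float(self.sv_ratio),
            "status": self.status,
        }


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible train/test partition of record indices."""

    seed: int
    train_fraction: float
    train_indices: np.ndarray
    test_indices: np.ndarray


def make_split(n_records: int, seed: int, train_fraction: float = 0.8) -> SplitSpec:
    """Random train/test split; size of train = round(n * fraction)."""
    if n_records < 10:
        raise ValueError(f"need at least 10 records to split, got {n_records}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_records)
    n_train = int(round(n_records * train_fraction))
    return SplitSpec(
        seed=seed,
        train_fraction=train_fraction,
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
    )


def standardize(
    train: np.ndarray, other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean unit-variance scaling fitted on ``train`` only.

    Constant training columns carry no information and break the scaling;
    they are dropped with a warning (an all-constant matrix is an error).
    Returns ``(train_scaled, other_scaled, means, sds, kept_idx)`` where the
    means/sds refer to the kept columns and the identical affine map was
    applied to ``other``.
    """
    train = np.asarray(train, dtype=float)
    means = train.mean(axis=0)
    sds = train.std(axis=0)
    kept = np.flatnonzero(sds > 0)
    if kept.size == 0:
        raise ValueError("all feature columns are constant on the training data")
    if kept.size < train.shape[1]:
        dropped = sorted(set(range(train.shape[1])) - set(kept.tolist()))
        warnings.warn(f"dropping constant training column(s) {dropped}")
    means, sds = means[kept], sds[kept]
    train_s = (train[:, kept] - means) / sds
    other_s = None
    if other is not None:
        other = np.asarray(other, dtype=float)
        other_s = (other[:, kept] - means) / sds
    return train_s, other_s, means, sds, kept


def gamma_base(
    train: np.ndarray, seed: int = 0, max_rows: int = 2000
) -> float:
    """Median-heuristic RBF bandwidth: 1 / median pairwise squared distance.

    For more than ``max_rows`` rows a seeded subsample bounds the O(n²)
    distance computation.
    """
    X = np.asarray(train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("gamma_base needs at least two rows")
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_rows, replace=False)]
    med = float(np.median(pdist(X, metric="sqeuclidean")))
    if med <= 0:
        raise ValueError("median pairwise squared distance is zero "
                         "(duplicate-dominated data)")
    return 1.0 / med


def evaluate_trial(
    X: np.ndarray,
    y: np.ndarray,
    params: HyperParams,
    gamma_base_value: float,
    trial_id: int = 0,
    folds: int = 5,
    seed: int = 0,
    standardization: Literal["fold", "global"] = "fold",
    svr_tol: float = 1e-3,
    svr_max_iter: int = -1,
) -> TrialResult:
    """Score one hyperparameter triple by k-fold cross-validation.

    In "fold" mode the feature scaling is refit on each fold-training
    portion (no information from the held fold leaks into the scaler); in
    "global" mode ``X`` is assumed already scaled once on the whole
    training split.  A solver failure marks the trial ``failed`` instead of
    raising, so a search never crashes on a pathological triple.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    maes = np.empty(folds)
    svs = np.empty(folds)
    gamma = params.gamma(gamma_base_value)
    try:
        for f, (tr, te) in enumerate(kf.split(X)):
            Xtr, Xte = X[tr], X[te]
            if standardization == "fold":
                Xtr, Xte, *_ = standardize(Xtr, Xte)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NuSVR(nu=params.nu, C=params.C, gamma=gamma,
                              tol=svr_tol, max_iter=svr_max_iter)
                model.fit(Xtr, y[tr])
            maes[f] = float(np.mean(np.abs(model.predict(Xte) - y[te])))
            svs[f] = len(model.support_) / len(tr)
    except Exception:
        return TrialResult(trial_id=trial_id, params=params,
                           fold_maes=np.full(folds, np.nan),
                           fold_sv_ratios=np.full(folds, np.nan),
                           cv_mae=np.nan, sv_ratio=np.nan, status="failed")
    return TrialResult(trial_id=trial_id, params=params, fold_maes=maes,
                       fold_sv_ratios=svs, cv_mae=float(maes.mean()),
                       sv_ratio=float(svs.mean()))


def run_doo(
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 2000,
    seed: int = 0,
    config: RunConfig | None = None,
) -> list[TrialResult]:
    """Dual-objective random search minimising (cv_mae, sv_ratio).

    Draws ``n_trials`` triples from the configured box (nu and the gamma
    scale uniform, C log-uniform), evaluates each by cross-validation and
    returns every completed trial.  Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    if cfg.standardization == "global":
        X_eval, *_ = standardize(X)
    else:
        X_eval = X
    # The median-heuristic anchor is always computed on standardized
    # features so the gamma scale search is comparable across modes.
    X_std, *_ = standardize(X)
    gb = gamma_base(X_std, seed=seed, max_rows=cfg.gamma_subsample)

    rng = np.random.default_rng(seed)
    lo_c, hi_c = np.log10(cfg.c_bounds[0]), np.log10(cfg.c_bounds[1])
    trials: list[TrialResult] = []
    for t in range(n_trials):
        params = HyperParams(
            nu=float(rng.uniform(*cfg.nu_bounds)),
            C=float(10.0 ** rng.uniform(lo_c, hi_c)),
            log10_gamma_scale=float(rng.uniform(*cfg.log10_gamma_scale_bounds)),
        )
        trials.append(evaluate_trial(
            X_eval, y, params, gb, trial_id=t, folds=cfg.folds, seed=seed,
            standardization=cfg.standardization,
            svr_tol=cfg.svr_tol, svr_max_iter=cfg.svr_max_iter))
    if all(t.status != "ok" for t in trials):
        raise RuntimeError("all trials failed")
    return trials


def pareto_front(trials: Sequence[TrialResult]) -> list[TrialResult]:
    """Non-dominated subset under joint minimisation of (cv_mae, sv_ratio).

    A trial is dominated when another trial is no worse in both objectives
    and strictly better in at least one; trials tied on both objectives are
    all retained.  Failed trials never enter the front.
    """
    ok = [t for t in trials if t.status == "ok"]
    if not ok:
        raise ValueError("pareto_front needs at least one successful trial")
    order = sorted(ok, key=lambda t: (t.cv_mae, t.sv_ratio))
    front: list[TrialResult] = []
    best_prev_sv = np.inf  # min sv_ratio among strictly lower cv_mae
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j].cv_mae == order[i].cv_mae:
            j += 1
        group = order[i:j]
        group_min_sv = min(t.sv_ratio for t in group)
        if group_min_sv < best_prev_sv:
            front.extend(t for t in group if t.sv_ratio == group_min_sv)
        best_prev_sv = min(best_prev_sv, group_min_sv)
        i = j
    return front
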