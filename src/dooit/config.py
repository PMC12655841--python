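"""Run configuration for the DOO-IT pipeline.

A single :class:`RunConfig` carries every tunable of the workflow: search
bounds of the nuSVR hyperparameters, cross-validation layout, pruning
depth, stability threshold and the composite-score weights.  Defaults are
the protocol defaults (2000 trials, 5-fold CV, 10 permutation repeats,
50 independent runs, >=30% frequency threshold, 50/30/20 weights).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one DOO-IT campaign.

    Parameters
    ----------
    feature_set : which assembled descriptor set to model ("set1", "set2"
        or "custom" for a user-supplied feature list).
    n_runs : independent 80/20 split repetitions feeding the stability
        analysis.
    n_trials : hyperparameter trials per dual-objective optimisation.
    folds : cross-validation folds inside each trial.
    min_features : pruning stops once this many descriptors remain.
    n_permutation_repeats : shuffles per feature in permutation importance.
    freq_threshold : minimum per-descriptor-count frequency across runs for
        a count to be architecturally admissible.
    composite_weights : (accuracy, r2, generalization) weights of the
        composite score; must sum to 1.
    master_seed : root of every derived seed.
    standardization : "fold" refits the scaler inside every CV fold
        (leakage-free, the default); "global" scales once on the whole
        training split, the behaviour used when mirroring the published
        protocol.
    train_fraction : training share of each random split.
    nu_bounds, c_bounds, log10_gamma_scale_bounds : search box of the
        sampler; C is sampled log-uniformly.
    importance_fraction : share of the training split carved out (seeded)
        as the validation set for permutation importance.
    tie_delta : composite-score margin treated as a near-tie and broken by
        descriptor stability.
    svr_tol, svr_max_iter : numerical controls passed to the nuSVR solver.
    gamma_subsample : row cap (seeded subsample) for the median pairwise
        squared distance behind gamma_base.
    """

    feature_set: Literal["set1", "set2", "custom"] = "set1"
    n_runs: int = 50
    n_trials: int = 2000
    folds: int = 5
    min_features: int = 3
    n_permutation_repeats: int = 10
    freq_threshold: float = 0.30
    composite_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    master_seed: int = 0
    standardization: Literal["fold", "global"] = "fold"
    train_fraction: float = 0.8
    nu_bounds: tuple[float, float] = (0.05, 0.95)
    c_bounds: tuple[float, float] = (1e-2, 1e3)
    log10_gamma_scale_bounds: tuple[float, float] = (-2.0, 2.0)
    importance_fraction: float = 0.2
    tie_delta: float = 0.01
    svr_tol: float = 1e-3
    svr_max_iter: int = -1
    gamma_subsample: int = 2000
    # metadata: units of the inputs, declared once and carried through
    log_base: str = "decadic"
    energy_units: str = "as-supplied"

    def __post_init__(self) -> None:
        if abs(sum(self.composite_weights) - 1.0) > 1e-9:
            raise ValueError("composite_weights must sum to 1")
        for name in ("n_runs", "n_trials", "folds", "min_features",
                     "n_permutation_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.freq_threshold <= 1.0):
            raise ValueError("freq_threshold must lie in (0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.standardization not in ("fold", "global"):
            raise ValueError("standardization must be 'fold' or 'global'")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("composite_weights", "nu_bounds", "c_bounds",
                    "log10_gamma_scale_bounds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
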