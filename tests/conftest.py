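"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dooit.doo import HyperParams, TrialResult
from dooit.synthetic import SyntheticSpec, generate


def make_trial(trial_id: int, cv_mae: float, sv_ratio: float,
               fold_maes=None, status: str = "ok") -> TrialResult:
    """Construct a TrialResult with prescribed objectives."""
    k = 5
    folds = np.asarray(fold_maes if fold_maes is not None
                       else np.full(k, cv_mae), dtype=float)
    return TrialResult(
        trial_id=trial_id,
        params=HyperParams(nu=0.3, C=1.0, log10_gamma_scale=0.0),
        fold_maes=folds,
        fold_sv_ratios=np.full(len(folds), sv_ratio),
        cv_mae=float(cv_mae),
        sv_ratio=float(sv_ratio),
        status=status,
    )


def brute_force_front(trials):
    """O(n^2) non-domination check, independent of the implementation."""
    ok = [t for t in trials if t.status == "ok"]
    front = []
    for t in ok:
        dominated = any(
            s is not t
            and s.cv_mae <= t.cv_mae and s.sv_ratio <= t.sv_ratio
            and (s.cv_mae < t.cv_mae or s.sv_ratio < t.sv_ratio)
            for s in ok
        )
        if not dominated:
            front.append(t)
    return front


@pytest.fixture(scope="session")
def small_table():
    """A 150-record, 6-feature synthetic table with 2 informative features."""
    spec = SyntheticSpec(
        n_records=150, n_features=6, informative_indices=(0, 3),
        effect_sizes=(1.0, 0.6), rho=0.5, seed=11, cosmo_proxy_corr=0.9)
    table, truth = generate(spec)
    return table, truth


@pytest.fixture(scope="session")
def xy_small(small_table):
    table, _ = small_table
    features = [c for c in table.frame.columns if c != "log_x"]
    X = table.frame[features].to_numpy(float)
    y = table.frame["log_x"].to_numpy(float)
    return X, y
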