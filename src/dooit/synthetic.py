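"""Synthetic descriptor/solubility data with known ground truth.

The generator emulates the statistical shape of a COSMO-RS descriptor
table: a block-correlated Gaussian feature matrix (blocks of three mimic
the solute / solvent / relative triplication of the energetic
descriptors, which is what makes pruning hard in practice), a response
that is a sparse — optionally mildly non-linear — function of a known
feature subset plus Gaussian noise, and a noisy computed-solubility proxy
column correlated with the response.  Everything is reproducible from the
spec's seed, and the true generating model is returned alongside the
table so recovery can be scored exactly.

σ-potential curves for pipeline tests are drawn as sums of up to three
Gaussian bumps on the standard 61-point charge-density grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import (SIGMA_GRID_POINTS, SIGMA_MAX, SIGMA_MIN,
                          DescriptorTable, SigmaPotential)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "generate_sigma_curves",
    "noise_sd_for_r2",
]

#: Intercept of the synthetic response, placing it on a realistic decadic
#: log mole-fraction solubility scale (values mostly in [-6, 0]).
RESPONSE_INTERCEPT = -3.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror the study scale: 1020 records and 16 features of which
    the last stands in for the computed-solubility column.  Features have
    unit variance; within a block of ``block_size`` consecutive features
    the pairwise correlation is ``rho``; blocks are independent.
    """

    n_records: int = 1020
    n_features: int = 16
    informative_indices: tuple[int, ...] = (0, 3, 6, 9)
    effect_sizes: tuple[float, ...] = (1.0, 0.8, 0.6, 0.5)
    rho: float = 0.5
    block_size: int = 3
    noise_sd: float | None = None  # None -> solved for target_r2
    target_r2: float = 0.95
    nonlinear: bool = False
    cosmo_proxy_corr: float | None = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_features < 1:
            raise ValueError("n_records and n_features must be positive")
        if len(self.informative_indices) > self.n_features:
            raise ValueError("more informative indices than features")
        if any(not (0 <= i < self.n_features) for i in self.informative_indices):
            raise ValueError("informative index out of range")
        if len(set(self.informative_indices)) != len(self.informative_indices):
            raise ValueError("informative indices must be distinct")
        if len(self.effect_sizes) != len(self.informative_indices):
            raise ValueError("one effect size per informative index")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cosmo_proxy_corr is not None and not (
                -1.0 <= self.cosmo_proxy_corr <= 1.0):
            raise ValueError("cosmo_proxy_corr must lie in [-1, 1]")

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = [f"x{i:02d}" for i in range(self.n_features)]
        if self.cosmo_proxy_corr is not None:
            names[-1] = "log_x_cosmo"
        return tuple(names)

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return noise_sd_for_r2(self)


@dataclass(frozen=True)
class GroundTruth:
    """The generating model behind one synthetic dataset."""

    informative_names: tuple[str, ...]
    informative_indices: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    noise_sd: float
    nonlinear: bool
    expected_r2: float

    def to_dict(self) -> dict:
        return {
            "informative_names": list(self.informative_names),
            "informative_indices": list(self.informative_indices),
            "effect_sizes": list(self.effect_sizes),
            "noise_sd": self.noise_sd,
            "nonlinear": self.nonlinear,
            "expected_r2": self.expected_r2,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _signal_variance(spec: SyntheticSpec) -> float:
    """Variance of the linear signal under the block covariance."""
    var = 0.0
    idx = spec.informative_indices
    eff = spec.effect_sizes
    for a in range(len(idx)):
        for b in range(len(idx)):
            same_block = idx[a] // spec.block_size == idx[b] // spec.block_size
            corr = 1.0 if idx[a] == idx[b] else (spec.rho if same_block else 0.0)
            var += eff[a] * eff[b] * corr
    return var


def noise_sd_for_r2(spec: SyntheticSpec) -> float:
    """Noise SD giving the requested population R² for the linear signal."""
    if not (0.0 < spec.target_r2 < 1.0):
        raise ValueError("target_r2 must lie in (0, 1)")
    var = _signal_variance(spec)
    return float(np.sqrt(var * (1.0 - spec.target_r2) / spec.target_r2))


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one dataset; returns the table and its generating model.

    The response is ``intercept + Σ effect_i · x_i (+ optional quadratic
    and interaction terms on the first informative features) + N(0,
    noise_sd)``.  When ``cosmo_proxy_corr`` is set, the last feature
    column is replaced by a standardized proxy with that population
    correlation to the noiseless response, named ``log_x_cosmo``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_records, spec.n_features

    # block-correlated standard Gaussian features via the one-factor
    # equicorrelation construction within each block
    X = np.empty((n, p))
    sq_rho, sq_rem = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)
    for start in range(0, p, spec.block_size):
        width = min(spec.block_size, p - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        X[:, start:start + width] = sq_rho * shared + sq_rem * own

    idx = list(spec.informative_indices)
    eff = np.asarray(spec.effect_sizes)
    signal = X[:, idx] @ eff if idx else np.zeros(n)
    if spec.nonlinear and idx:
        # mild curvature: centred quadratic on the first informative
        # feature and, when present, an interaction of the first two
        signal = signal + 0.2 * (X[:, idx[0]] ** 2 - 1.0)
        if len(idx) > 1:
            signal = signal + 0.3 * X[:, idx[0]] * X[:, idx[1]]
    noise_sd = spec.resolved_noise_sd()
    y = RESPONSE_INTERCEPT + signal + rng.normal(0.0, noise_sd, size=n)

    names = list(spec.feature_names)
    if spec.cosmo_proxy_corr is not None:
        c = spec.cosmo_proxy_corr
        z = (signal - signal.mean()) / signal.std() if signal.std() > 0 \
            else np.zeros(n)
        X[:, -1] = c * z + np.sqrt(max(0.0, 1.0 - c * c)) * rng.standard_normal(n)

    frame = pd.DataFrame(X, columns=names)
    frame["log_x"] = y
    table = DescriptorTable(frame=frame,
                            set_tags={c: "set1" for c in names})
    sig_var = _signal_variance(spec)
    truth = GroundTruth(
        informative_names=tuple(names[i] for i in idx),
        informative_indices=tuple(idx),
        effect_sizes=tuple(float(e) for e in eff),
        noise_sd=noise_sd,
        nonlinear=spec.nonlinear,
        expected_r2=sig_var / (sig_var + noise_sd ** 2)
        if sig_var + noise_sd ** 2 > 0 else float("nan"),
    )
    return table, truth


def generate_sigma_curves(n_species: int, seed: int = 0) -> list[SigmaPotential]:
    """Smooth random σ-potential curves on the standard 61-point grid.

    Each curve is a sum of one to three Gaussian bumps with random centre,
    width and signed amplitude — enough structure to exercise binning and
    mixture weighting without claiming physical realism.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.linspace(SIGMA_MIN, SIGMA_MAX, SIGMA_GRID_POINTS)
    curves = []
    for i in range(n_species):
        mu = np.zeros(SIGMA_GRID_POINTS)
        for _ in range(rng.integers(1, 4)):
            centre = rng.uniform(SIGMA_MIN, SIGMA_MAX)
            width = rng.uniform(0.005, 0.02)
            amp = rng.uniform(-5.0, 5.0)
            mu = mu + amp * np.exp(-((grid - centre) ** 2) / (2 * width ** 2))
        curves.append(SigmaPotential(species_id=f"species_{i:03d}",
                                     sigma_grid=grid.copy(), mu_values=mu))
    return curves
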