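"""Model/Results surface over the DOO-IT pipeline.

`DooIt` is constructed from a feature table (a plain DataFrame or an
assembled :class:`~dooit.descriptors.DescriptorTable`); ``fit()`` executes
the configured number of independent pruning runs, aggregates them and
returns a :class:`DooItResults` carrying the stability report, the
composite-scored final model, a fitted predictor for it, and a
``summary()`` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seed import derive_seed
from .config import RunConfig
from .descriptors import DescriptorTable
from .doo import gamma_base, make_split, standardize
from .selection import CandidateModel, PruningTrace, _FittedCandidate, dooit_run
from .stability import (FinalSelection, RunSummary, StabilityReport,
                        aggregate_runs, final_selection)

__all__ = ["DooIt", "DooItResults"]


class DooIt:
    """Dual-objective nuSVR model selection on a descriptor table.

    Parameters
    ----------
    data : DataFrame holding the feature columns and the target column.
    features : names of the candidate descriptor columns.
    target : name of the response column (decadic log mole-fraction
        solubility in the intended application).
    config : pipeline configuration; defaults to :class:`RunConfig`.
    """

    def __init__(self, data: pd.DataFrame, features: Sequence[str],
                 target: str = "log_x", config: RunConfig | None = None):
        self.config = config or RunConfig()
        missing = [c for c in list(features) + [target]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if data[list(features) + [target]].isna().any().any():
            raise ValueError("data contains missing values")
        self.data = data.reset_index(drop=True)
        self.features = list(features)
        self.target = target

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, features: Sequence[str],
                       target: str = "log_x",
                       config: RunConfig | None = None) -> "DooIt":
        return cls(data, features, target=target, config=config)

    @classmethod
    def from_descriptor_table(cls, table: DescriptorTable,
                              feature_set: str | None = None,
                              config: RunConfig | None = None) -> "DooIt":
        cfg = config or RunConfig()
        fs = feature_set or cfg.feature_set
        if fs == "custom":
            cols = [c for c in table.frame.columns if c in table.set_tags]
        else:
            cols = table.feature_columns(fs)
        return cls(table.frame, cols, target=table.target, config=cfg)

    def fit(self, n_runs: int | None = None, n_trials: int | None = None,
            seed: int | None = None) -> "DooItResults":
        """Run the full campaign: prune, aggregate, select.

        ``seed`` overrides the config master seed; per-run split seeds are
        derived from it so runs are independent yet reproducible.
        """
        cfg = self.config
        n_runs = cfg.n_runs if n_runs is None else n_runs
        n_trials = cfg.n_trials if n_trials is None else n_trials
        master = cfg.master_seed if seed is None else seed
        summaries = []
        for r in range(n_runs):
            split_seed = derive_seed(master, 1, r)
            trace = dooit_run(self.data, self.features, self.target,
                              split_seed=split_seed, config=cfg,
                              run_id=r, n_trials=n_trials)
            summaries.append(RunSummary(run_id=r, split_seed=split_seed,
                                        trace=trace))
        report = aggregate_runs(summaries)
        selection = final_selection(report, summaries, cfg)
        return DooItResults(model=self, summaries=tuple(summaries),
                            report=report, selection=selection,
                            master_seed=master)


@dataclass(frozen=True)
class DooItResults:
    """Fitted campaign: traces, stability report and the deployed model."""

    model: DooIt
    summaries: tuple[RunSummary, ...]
    report: StabilityReport
    selection: FinalSelection
    master_seed: int

    @property
    def final_model(self) -> CandidateModel:
        return self.selection.candidate

    @property
    def traces(self) -> tuple[PruningTrace, ...]:
        return tuple(s.trace for s in self.summaries)

    def basin_table(self) -> pd.DataFrame:
        return self.report.basin_table()

    def _fitted_final(self) -> _FittedCandidate:
        """Refit the winning candidate on its own training split."""
        cfg = self.model.config
        cand = self.final_model
        split = make_split(len(self.model.data), self.selection.split_seed,
                           cfg.train_fraction)
        X = self.model.data[list(cand.feature_names)].to_numpy(dtype=float)
        y = self.model.data[self.model.target].to_numpy(dtype=float)
        Xtr, ytr = X[split.train_indices], y[split.train_indices]
        X_std, *_ = standardize(Xtr)
        gb = gamma_base(X_std, seed=self.selection.split_seed,
                        max_rows=cfg.gamma_subsample)
        return _FittedCandidate(Xtr, ytr, cand.params, gb, cfg)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predict the response for new records with the final model."""
        cand = self.final_model
        fitted = self._fitted_final()
        return fitted.predict(data[list(cand.feature_names)].to_numpy(dtype=float))

    def summary(self) -> str:
        """Human-readable basin table and final-model card."""
        cand = self.final_model
        score = self.selection.score
        buf = StringIO()
        w = buf.write
        w("DOO-IT model selection results\n")
        w("==============================\n")
        w(f"runs: {len(self.summaries)}    master seed: {self.master_seed}    "
          f"records: {len(self.model.data)}\n")
        w(f"candidate descriptor counts (stable: frequency >= "
          f"{self.model.config.freq_threshold:.0%}):\n\n")
        table = self.basin_table()
        table = table.assign(selected=table["n_features"].isin(
            self.selection.selected_counts).map({True: "*", False: ""}))
        w(table.to_string(index=False,
                          float_format=lambda v: f"{v:.4f}"))
        w("\n\nFinal model\n-----------\n")
        w(f"descriptors ({cand.n_features}): "
          + ", ".join(cand.feature_names) + "\n")
        w(f"hyperparameters: nu={cand.params.nu:.4f}  C={cand.params.C:.4f}  "
          f"log10_gamma_scale={cand.params.log10_gamma_scale:.4f}\n")
        w(f"cv_mae={cand.cv_mae:.4f} (+/- {cand.cv_mae_se:.4f} SE)  "
          f"sv_ratio={cand.sv_ratio:.4f}\n")
        w(f"train_mae={cand.train_mae:.4f}  test_mae={cand.test_mae:.4f}  "
          f"train_r2={cand.train_r2:.4f}  test_r2={cand.test_r2:.4f}\n")
        w(f"composite score: {score.total:.4f} "
          f"(accuracy {score.accuracy_component:.3f}, "
          f"r2 {score.r2_component:.3f}, "
          f"generalization {score.generalization_component:.3f})\n")
        w(f"provenance: run {self.selection.run_id}, "
          f"split seed {self.selection.split_seed}, "
          f"descriptor stability {self.selection.descriptor_stability:.3f}\n")
        return buf.getvalue()

    def save(self, out_dir: str | Path) -> None:
        """Write traces, stability report, final model and basin CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs = out / "runs"
        runs.mkdir(exist_ok=True)
        for s in self.summaries:
            s.trace.write_json(runs / f"run_{s.run_id:03d}.json")
        self.report.write_json(out / "stability_report.json")
        self.selection.write_json(out / "final_model.json")
        self.basin_table().to_csv(out / "basin_table.csv", index=False)
        (out / "summary.txt").write_text(self.summary())
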