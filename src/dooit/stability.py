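"""Cross-run stability analysis and final model selection.

Many independent pruning runs (fresh 80/20 splits) each produce one
candidate per descriptor count.  Aggregating them reveals "basins" —
descriptor counts that recur across runs with consistently low test error.
Architectural selection keeps counts that (a) appear in at least a
threshold fraction of runs (default 30%) and (b) have a mean test MAE
within one standard error of the best count.  Finalists at those counts
are ranked by a composite score — 0.5 · accuracy + 0.3 · R² +
0.2 · generalization (train/test gap) — each component min–max normalised
within the finalist cohort; composite near-ties are broken by descriptor
stability (how consistently the candidate's features recur across runs).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .selection import CandidateModel, PruningTrace

__all__ = [
    "RunSummary",
    "CountStats",
    "StabilityReport",
    "CompositeScore",
    "FinalSelection",
    "aggregate_runs",
    "architectural_selection",
    "composite_score",
    "final_selection",
]


@dataclass(frozen=True)
class RunSummary:
    """One completed DOO-IT run: its split seed and pruning trace."""

    run_id: int
    split_seed: int
    trace: PruningTrace


@dataclass(frozen=True)
class CountStats:
    """Aggregate statistics for one descriptor count across runs."""

    n_features: int
    frequency: float          # fraction of runs producing this count
    n_runs_with: int
    mean_test_mae: float
    sd_test_mae: float        # sample SD; 0 when only one run
    mean_train_mae: float
    descriptor_frequency: dict[str, float]  # among runs at this count

    @property
    def se_test_mae(self) -> float:
        return self.sd_test_mae / math.sqrt(self.n_runs_with)


@dataclass(frozen=True)
class StabilityReport:
    """Per-descriptor-count aggregation over all runs."""

    n_runs: int
    per_count: dict[int, CountStats]

    def basin_table(self) -> pd.DataFrame:
        """Tidy (count, frequency, mean/sd test MAE, mean train MAE) table."""
        rows = [{
            "n_features": c.n_features,
            "frequency": c.frequency,
            "n_runs_with": c.n_runs_with,
            "mean_test_mae": c.mean_test_mae,
            "sd_test_mae": c.sd_test_mae,
            "mean_train_mae": c.mean_train_mae,
        } for c in sorted(self.per_count.values(), key=lambda c: c.n_features)]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "per_count": {str(k): {
                "n_features": c.n_features,
                "frequency": c.frequency,
                "n_runs_with": c.n_runs_with,
                "mean_test_mae": c.mean_test_mae,
                "sd_test_mae": c.sd_test_mae,
                "mean_train_mae": c.mean_train_mae,
                "descriptor_frequency": c.descriptor_frequency,
            } for k, c in sorted(self.per_count.items())},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True, ensure_ascii=False))


@dataclass(frozen=True)
class CompositeScore:
    """50/30/20 weighted score of a finalist within its cohort."""

    accuracy_component: float
    r2_component: float
    generalization_component: float
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)

    @property
    def total(self) -> float:
        w = self.weights
        return (w[0] * self.accuracy_component
                + w[1] * self.r2_component
                + w[2] * self.generalization_component)

    def to_dict(self) -> dict:
        return {"accuracy_component": self.accuracy_component,
                "r2_component": self.r2_component,
                "generalization_component": self.generalization_component,
                "weights": list(self.weights),
                "total": self.total}


@dataclass(frozen=True)
class FinalSelection:
    """The deployed model with its provenance and score breakdown."""

    candidate: CandidateModel
    score: CompositeScore
    run_id: int
    split_seed: int
    n_features: int
    descriptor_stability: float
    cohort_size: int
    selected_counts: tuple[int, ...]

    def to_dict(self) -> dict:
        d = self.candidate.to_dict()
        d["composite"] = self.score.to_dict()
        d["provenance"] = {"run_id": self.run_id, "split_seed": self.split_seed,
                           "trace_level_n_features": self.n_features,
                           "selected_counts": list(self.selected_counts),
                           "cohort_size": self.cohort_size,
                           "descriptor_stability": self.descriptor_stability}
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True, ensure_ascii=False))


def aggregate_runs(summaries: Sequence[RunSummary]) -> StabilityReport:
    """Aggregate pruning traces into per-descriptor-count statistics.

    A count missing from a trace lowers that count's frequency (the
    denominator is always the total number of runs) but contributes
    nothing to its error statistics.
    """
    if len(summaries) < 2:
        raise ValueError("stability analysis needs at least two runs")
    # canonical run order makes the aggregation exactly permutation-invariant
    summaries = sorted(summaries, key=lambda s: s.run_id)
    n_runs = len(summaries)
    counts = sorted({c.n_features for s in summaries
                     for c in s.trace.candidates})
    per_count: dict[int, CountStats] = {}
    for k in counts:
        cands = [s.trace.candidate_at(k) for s in summaries]
        cands = [c for c in cands if c is not None]
        test = np.array([c.test_mae for c in cands])
        train = np.array([c.train_mae for c in cands])
        feat_counts: dict[str, int] = {}
        for c in cands:
            for f in c.feature_names:
                feat_counts[f] = feat_counts.get(f, 0) + 1
        per_count[k] = CountStats(
            n_features=k,
            frequency=len(cands) / n_runs,
            n_runs_with=len(cands),
            mean_test_mae=float(test.mean()),
            sd_test_mae=float(np.std(test, ddof=1)) if len(cands) > 1 else 0.0,
            mean_train_mae=float(train.mean()),
            descriptor_frequency={f: n / len(cands)
                                  for f, n in sorted(feat_counts.items())},
        )
    return StabilityReport(n_runs=n_runs, per_count=per_count)


def architectural_selection(
    report: StabilityReport, freq_threshold: float = 0.30
) -> set[int]:
    """Descriptor counts that are both stable and near-optimal.

    Keeps counts with frequency >= ``freq_threshold`` whose mean test MAE
    lies within one standard error (at the minimising count) of the
    minimum mean test MAE.  An empty result falls back, with a warning, to
    the count minimising mean test MAE.
    """
    stats = report.per_count
    best = min(stats.values(), key=lambda c: c.mean_test_mae)
    threshold = best.mean_test_mae + best.se_test_mae
    selected = {c.n_features for c in stats.values()
                if c.frequency >= freq_threshold
                and c.mean_test_mae <= threshold}
    if not selected:
        warnings.warn(
            "no descriptor count passed the stability/accuracy rule; "
            f"falling back to the minimum-MAE count {best.n_features}")
        selected = {best.n_features}
    return selected


def composite_score(
    candidate: CandidateModel,
    cohort: Sequence[CandidateModel],
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
) -> CompositeScore:
    """Score a finalist within its cohort.

    Three raw metrics — test MAE (lower better), test R² (higher better)
    and the absolute train/test MAE gap (lower better) — are min–max
    normalised over the cohort so each component lies in [0, 1]; a
    degenerate spread (or a single-member cohort) maps to 1.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one candidate")

    def higher_better(value: float, values: np.ndarray) -> float:
        lo, hi = float(values.min()), float(values.max())
        return 1.0 if hi == lo else (value - lo) / (hi - lo)

    def lower_better(value: float, values: np.ndarray) -> float:
        lo, hi = float(values.min()), float(values.max())
        return 1.0 if hi == lo else (hi - value) / (hi - lo)

    maes = np.array([c.test_mae for c in cohort])
    r2s = np.array([c.test_r2 for c in cohort])
    gaps = np.array([abs(c.test_mae - c.train_mae) for c in cohort])
    return CompositeScore(
        accuracy_component=lower_better(candidate.test_mae, maes),
        r2_component=higher_better(candidate.test_r2, r2s),
        generalization_component=lower_better(
            abs(candidate.test_mae - candidate.train_mae), gaps),
        weights=weights,
    )


def _descriptor_stability(candidate: CandidateModel,
                          stats: CountStats) -> float:
    """Mean cross-run occurrence frequency of the candidate's features."""
    return float(np.mean([stats.descriptor_frequency.get(f, 0.0)
                          for f in candidate.feature_names]))


def final_selection(
    report: StabilityReport,
    summaries: Sequence[RunSummary],
    config: RunConfig | None = None,
) -> FinalSelection:
    """Pick the deployed model from the architecturally admissible counts.

    All candidates at admissible counts form the finalist cohort; the
    highest composite score wins, except that scores within ``tie_delta``
    of the best are treated as tied and resolved by descriptor stability
    (then score, then run id, for full determinism).
    """
    cfg = config or RunConfig()
    counts = architectural_selection(report, cfg.freq_threshold)
    finalists: list[tuple[RunSummary, CandidateModel]] = []
    for s in summaries:
        for k in counts:
            c = s.trace.candidate_at(k)
            if c is not None:
                finalists.append((s, c))
    if not finalists:
        raise RuntimeError("no finalist candidates at the selected counts")
    cohort = [c for _, c in finalists]
    scores = [composite_score(c, cohort, cfg.composite_weights)
              for c in cohort]
    stabilities = [_descriptor_stability(c, report.per_count[c.n_features])
                   for c in cohort]
    best_total = max(s.total for s in scores)
    near = [i for i, s in enumerate(scores)
            if best_total - s.total < cfg.tie_delta]
    winner = max(near, key=lambda i: (stabilities[i], scores[i].total,
                                      -finalists[i][0].run_id))
    summary, candidate = finalists[winner]
    return FinalSelection(
        candidate=candidate,
        score=scores[winner],
        run_id=summary.run_id,
        split_seed=summary.split_seed,
        n_features=candidate.n_features,
        descriptor_stability=stabilities[winner],
        cohort_size=len(cohort),
        selected_counts=tuple(sorted(counts)),
    )
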