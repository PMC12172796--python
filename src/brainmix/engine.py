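"""The three resampling designs and the bagged source x target prediction grid.

Design A (``split_permutations``): re-draw the 50-50 train/test split each
iteration, fit one model per pipeline version, and evaluate all four
cross-version cells (v5->v5, v5->v7, v7->v7, v7->v5), on both the train and
the test side.  Varies the split to probe the influence of individual
differences.

Design B (``version_shuffle``): hold one split fixed (the *initial
iteration*); per iteration, re-draw the 50:50 version assignment within train
and within test, fit a mix-trained model, and fill the full 3x3 grid of
{mix, v5, v7} sources x {mix, v5, v7} targets.  The two single-version models
are fitted once on the fixed split, so single->single cells carry a single
iteration.

Design C (``joint_permutations``): as B but the split itself is also re-drawn
each iteration (both sources of variation vary together).

Seed hierarchy: one master seed spawns per-iteration split, assignment and
model seeds, so any sub-experiment replays independently and a DesignResult is
bit-reproducible from its stored seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import json
import numpy as np
import pandas as pd

from . import stats as bstats
from .cohort import SplitPlan, assemble_design_matrix, assign_versions, make_split
from .models import FittedModel, ModelSpec, fit_model, predict_ages
from .synthdata import MultiVersionDataset

__all__ = [
    "DesignResult",
    "run_split_permutations",
    "run_version_shuffle",
    "run_joint_permutations",
    "bag_predictions",
    "write_design_result",
]

SOURCES = ("mix", "v5", "v7")


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass
class DesignResult:
    """All records, per-iteration summaries, and replay seeds of one design run."""

    design: str
    records: pd.DataFrame  # participant_id, iteration, train_source, test_target,
    # true_age, predicted_age (test side only)
    summaries: pd.DataFrame  # iteration, train_source, test_target, side + metrics
    seeds: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD of every metric over iterations, per (source, target, side)."""
        metrics = ["R", "R2_adj", "R2_adj_corrected", "MAE", "RMSE", "AIC", "BIC"]
        grouped = self.summaries.groupby(
            ["train_source", "test_target", "side"], sort=True
        )
        agg = grouped[metrics].agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        agg["n_iterations"] = grouped.size()
        return agg.reset_index()

    def formatted_table(self, decimals: int = 2) -> pd.DataFrame:
        """Aggregate with 'mean ± SD' strings, shaped like a report table."""
        agg = self.aggregate()
        out = agg[["train_source", "test_target", "side", "n_iterations"]].copy()
        for m in ["R", "R2_adj", "R2_adj_corrected", "MAE", "RMSE", "AIC", "BIC"]:
            mean, sd = agg[f"{m}_mean"], agg[f"{m}_std"]
            out[m] = [
                f"{mu:.{decimals}f}" if not np.isfinite(s) else f"{mu:.{decimals}f} ± {s:.{decimals}f}"
                for mu, s in zip(mean, sd.fillna(np.inf))
            ]
        return out


class _Collector:
    def __init__(self, dataset: MultiVersionDataset, k: int):
        self.dataset = dataset
        self.k = k
        self.demo = dataset.demographics.set_index("participant_id")
        self.records: list[pd.DataFrame] = []
        self.summaries: list[dict] = []

    def evaluate(
        self,
        model: FittedModel,
        X: pd.DataFrame,
        iteration: int,
        source: str,
        target: str,
        side: str,
        keep_records: bool,
    ) -> None:
        ids = X.index.to_numpy()
        y = self.demo.loc[ids, "age"].to_numpy()
        cov = self.demo.loc[ids, ["sex", "site"]]
        pred = predict_ages(model, X)
        summary = bstats.compute_metrics(y, pred, covariates=cov, k=self.k)
        row = {"iteration": iteration, "train_source": source,
               "test_target": target, "side": side}
        row.update(summary.as_dict())
        self.summaries.append(row)
        if keep_records:
            self.records.append(
                pd.DataFrame(
                    {"participant_id": ids, "iteration": iteration,
                     "train_source": source, "test_target": target,
                     "true_age": y, "predicted_age": pred}
                )
            )

    def result(self, design: str, seeds: dict) -> DesignResult:
        records = (
            pd.concat(self.records, ignore_index=True)
            if self.records
            else pd.DataFrame(
                columns=["participant_id", "iteration", "train_source",
                         "test_target", "true_age", "predicted_age"]
            )
        )
        return DesignResult(
            design=design, records=records,
            summaries=pd.DataFrame(self.summaries), seeds=seeds,
        )


def _single_version_matrices(
    dataset: MultiVersionDataset, plan: SplitPlan, version: str
):
    plan_v = assign_versions(plan, f"single_{version}")
    X_train, y_train, _ = assemble_design_matrix(dataset, plan_v, "train")
    X_test, _, _ = assemble_design_matrix(dataset, plan_v, "test")
    return X_train, y_train, X_test


def run_split_permutations(
    dataset: MultiVersionDataset,
    spec: ModelSpec,
    i: int = 100,
    seed: int = 0,
    k: Optional[int] = None,
) -> DesignResult:
    """Design A: vary the 50-50 split, evaluate the 2x2 cross-version grid.

    Per iteration both single-version models are refitted on the new split and
    evaluated on both versions' test rows; "train performance" of a
    cross-version cell is the source model evaluated on the train-side rows of
    the target version.
    """
    if i < 1:
        raise ValueError("need at least one iteration")
    k = k or len(dataset.feature_names)
    coll = _Collector(dataset, k)
    ids = dataset.participant_ids
    iter_seeds = _spawn_seeds(seed, i)
    for t in range(1, i + 1):
        sub = _spawn_seeds(iter_seeds[t - 1], 3)
        try:
            plan = make_split(ids, seed=sub[0], iteration_id=t)
            mats = {v: _single_version_matrices(dataset, plan, v) for v in ("v5", "v7")}
            fitted = {
                v: fit_model(replace(spec, seed=sub[1 + j]),
                             mats[v][0], mats[v][1])
                for j, v in enumerate(("v5", "v7"))
            }
            for source in ("v5", "v7"):
                for target in ("v5", "v7"):
                    coll.evaluate(fitted[source], mats[target][2], t, source, target,
                                  "test", keep_records=True)
                    coll.evaluate(fitted[source], mats[target][0], t, source, target,
                                  "train", keep_records=False)
        except Exception as exc:
            raise RuntimeError(f"design A failed at iteration {t}") from exc
    return coll.result("A_splits", {"master": seed, "iterations": iter_seeds})


def run_version_shuffle(
    dataset: MultiVersionDataset,
    spec: ModelSpec,
    i: int = 100,
    fixed_split_seed: int = 0,
    seed: int = 1,
    k: Optional[int] = None,
    composition_mode: str = "shuffled_50_50",
) -> DesignResult:
    """Design B: fixed split, re-drawn version composition per iteration.

    Fills the full 3x3 source x target grid: single->single cells are computed
    once (iteration 0) from the two models fitted on the fixed split;
    mix-involved cells are aggregated over the i compositions.
    ``composition_mode`` defaults to the 50:50 shuffle; forcing it to a single
    version is a boundary/sensitivity setting.
    """
    if i < 1:
        raise ValueError("need at least one iteration")
    k = k or len(dataset.feature_names)
    coll = _Collector(dataset, k)
    ids = dataset.participant_ids
    plan = make_split(ids, seed=fixed_split_seed, iteration_id=0)
    single_seeds = _spawn_seeds(seed, 2)
    mats = {v: _single_version_matrices(dataset, plan, v) for v in ("v5", "v7")}
    singles = {
        v: fit_model(replace(spec, seed=single_seeds[j]),
                     mats[v][0], mats[v][1])
        for j, v in enumerate(("v5", "v7"))
    }
    for source in ("v5", "v7"):
        for target in ("v5", "v7"):
            coll.evaluate(singles[source], mats[target][2], 0, source, target,
                          "test", keep_records=True)
    iter_seeds = _spawn_seeds(seed + 1, i)
    for t in range(1, i + 1):
        sub = _spawn_seeds(iter_seeds[t - 1], 2)
        try:
            plan_t = assign_versions(plan, composition_mode, seed=sub[0])
            X_mix_train, y_train, _ = assemble_design_matrix(dataset, plan_t, "train")
            X_mix_test, _, _ = assemble_design_matrix(dataset, plan_t, "test")
            mix = fit_model(
                replace(spec, seed=sub[1]),
                X_mix_train, y_train,
            )
            coll.evaluate(mix, X_mix_test, t, "mix", "mix", "test", keep_records=True)
            coll.evaluate(mix, X_mix_train, t, "mix", "mix", "train", keep_records=False)
            for target in ("v5", "v7"):
                coll.evaluate(mix, mats[target][2], t, "mix", target, "test",
                              keep_records=True)
            for source in ("v5", "v7"):
                coll.evaluate(singles[source], X_mix_test, t, source, "mix", "test",
                              keep_records=True)
        except Exception as exc:
            raise RuntimeError(f"design B failed at iteration {t}") from exc
    return coll.result(
        "B_shuffle",
        {"master": seed, "fixed_split": fixed_split_seed, "iterations": iter_seeds},
    )


def run_joint_permutations(
    dataset: MultiVersionDataset,
    spec: ModelSpec,
    i: int = 100,
    seed: int = 0,
    k: Optional[int] = None,
) -> DesignResult:
    """Design C: both the split and the version composition re-drawn each
    iteration; single-version models are refitted per split so all nine cells
    aggregate over i."""
    if i < 1:
        raise ValueError("need at least one iteration")
    k = k or len(dataset.feature_names)
    coll = _Collector(dataset, k)
    ids = dataset.participant_ids
    iter_seeds = _spawn_seeds(seed, i)
    for t in range(1, i + 1):
        sub = _spawn_seeds(iter_seeds[t - 1], 5)
        try:
            plan = make_split(ids, seed=sub[0], iteration_id=t)
            plan_t = assign_versions(plan, "shuffled_50_50", seed=sub[1])
            mats = {v: _single_version_matrices(dataset, plan, v) for v in ("v5", "v7")}
            fitted = {
                v: fit_model(replace(spec, seed=sub[2 + j]),
                             mats[v][0], mats[v][1])
                for j, v in enumerate(("v5", "v7"))
            }
            X_mix_train, y_train, _ = assemble_design_matrix(dataset, plan_t, "train")
            X_mix_test, _, _ = assemble_design_matrix(dataset, plan_t, "test")
            fitted["mix"] = fit_model(
                replace(spec, seed=sub[4]),
                X_mix_train, y_train,
            )
            targets = {"v5": mats["v5"][2], "v7": mats["v7"][2], "mix": X_mix_test}
            for source in SOURCES:
                for target in SOURCES:
                    coll.evaluate(fitted[source], targets[target], t, source, target,
                                  "test", keep_records=True)
            coll.evaluate(fitted["mix"], X_mix_train, t, "mix", "mix", "train",
                          keep_records=False)
        except Exception as exc:
            raise RuntimeError(f"design C failed at iteration {t}") from exc
    return coll.result("C_joint", {"master": seed, "iterations": iter_seeds})


def bag_predictions(
    records: pd.DataFrame, group_by: tuple[str, str] = ("train_source", "test_target")
) -> pd.DataFrame:
    """Average each participant's predictions over iterations, per grid cell.

    Returns one row per (source, target, participant) with the bagged
    prediction (arithmetic mean over the iterations in which the participant
    was on the test side), the true age, and the iteration count.  Participants
    never tested in a cell are simply absent.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    keys = [*group_by, "participant_id"]
    grouped = records.groupby(keys, sort=True)
    out = grouped.agg(
        true_age=("true_age", "first"),
        predicted_age=("predicted_age", "mean"),
        n_iterations=("predicted_age", "size"),
    ).reset_index()
    return out


def write_design_result(result: DesignResult, directory: str | Path) -> None:
    """Tidy CSVs: per-record predictions, per-iteration metrics, aggregate table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = result.design
    result.records.to_csv(directory / f"{prefix}_records.csv", index=False)
    result.summaries.to_csv(directory / f"{prefix}_summaries.csv", index=False)
    result.aggregate().to_csv(directory / f"{prefix}_aggregate.csv", index=False)
    result.formatted_table().to_csv(directory / f"{prefix}_table.csv", index=False)
    (directory / f"{prefix}_seeds.json").write_text(json.dumps(result.seeds))
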