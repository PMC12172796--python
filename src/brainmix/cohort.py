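"""Quality control, train/test splits, and version-shuffled composition.

The shuffling unit is the participant row: in a shuffled composition each
participant contributes all of their features from exactly one pipeline
version, with a 50:50 version balance enforced separately within the training
and the test set.  A column-wise (per-feature) mixing mode is exposed behind a
flag for sensitivity analysis, but row-wise is the default and the mode used
throughout the analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthdata import MultiVersionDataset, VERSIONS

__all__ = [
    "SplitPlan",
    "remove_outliers",
    "make_split",
    "assign_versions",
    "assemble_design_matrix",
]

logger = logging.getLogger(__name__)

MODES = ("single_v5", "single_v7", "shuffled_50_50")


@dataclass
class SplitPlan:
    """A train/test partition plus per-participant version assignment."""

    iteration_id: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    version_assignment: dict = field(default_factory=dict)  # participant -> version tag

    def __post_init__(self) -> None:
        self.train_ids = np.asarray(self.train_ids)
        self.test_ids = np.asarray(self.test_ids)
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test sets overlap")

    def ids(self, side: str) -> np.ndarray:
        if side == "train":
            return self.train_ids
        if side == "test":
            return self.test_ids
        raise ValueError(f"unknown side {side!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "iteration_id": self.iteration_id,
            "train_ids": [int(i) for i in self.train_ids],
            "test_ids": [int(i) for i in self.test_ids],
            "version_assignment": {str(k): v for k, v in self.version_assignment.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            iteration_id=payload["iteration_id"],
            train_ids=np.array(payload["train_ids"]),
            test_ids=np.array(payload["test_ids"]),
            version_assignment={int(k): v for k, v in payload["version_assignment"].items()},
        )


def remove_outliers(
    dataset: MultiVersionDataset, threshold: float = 5.0
) -> tuple[MultiVersionDataset, np.ndarray]:
    """Drop participants with any feature beyond ``threshold`` SD of its column mean.

    The rule is a single pass: column means and SDs are computed once on the
    full sample (per version), and a participant is excluded if *any* feature
    in *any* version satisfies ``|value - mean| > threshold * SD``.  Both
    version matrices drop the same rows so alignment is preserved.  Columns
    with zero SD cannot define a z-score and are skipped with a warning.
    """
    if dataset.n_participants == 0:
        raise ValueError("dataset is empty")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    flagged = np.zeros(dataset.n_participants, dtype=bool)
    for v, mat in dataset.features_by_version.items():
        values = mat.to_numpy()
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "%d zero-variance column(s) in %s skipped by the outlier rule", zero.sum(), v
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(values - mu[None, :]) / sd[None, :]
        z[:, zero] = 0.0
        flagged |= (z > threshold).any(axis=1)
    excluded = dataset.participant_ids[flagged]
    keep = ~flagged
    filtered = MultiVersionDataset(
        demographics=dataset.demographics.loc[keep].reset_index(drop=True),
        features_by_version={
            v: mat.loc[keep] for v, mat in dataset.features_by_version.items()
        },
        feature_names=list(dataset.feature_names),
    )
    return filtered, excluded


def make_split(ids: Sequence, fraction: float = 0.5, seed: int = 0, iteration_id: int = 0) -> SplitPlan:
    """Uniform random train/test partition (default equal halves).

    With an odd number of participants the training side receives the extra
    one.  Deterministic given ``seed``.
    """
    ids = np.asarray(ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 participants to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.ceil(fraction * len(ids)))
    return SplitPlan(
        iteration_id=iteration_id,
        train_ids=np.sort(ids[perm[:n_train]]),
        test_ids=np.sort(ids[perm[n_train:]]),
    )


def _balanced_assignment(ids: np.ndarray, rng: np.random.Generator) -> dict:
    """Assign an exact random half of ids to v5, the rest to v7 (train gets the
    extra v5 when odd)."""
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    assignment = {}
    for rank, idx in enumerate(perm):
        assignment[ids[idx].item() if hasattr(ids[idx], "item") else ids[idx]] = (
            "v5" if rank < half else "v7"
        )
    return assignment


def assign_versions(plan: SplitPlan, mode: str, seed: int = 0) -> SplitPlan:
    """Attach a per-participant version assignment to a split plan.

    ``shuffled_50_50`` draws, independently within train and within test, a
    uniform random half of participants to contribute their v5 row and the
    other half their v7 row; ``single_v5``/``single_v7`` assign constantly.
    Returns a new plan; the input is not modified.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if plan.train_ids.size == 0 or plan.test_ids.size == 0:
        raise ValueError("plan has empty train or test set")
    assignment: dict = {}
    if mode == "shuffled_50_50":
        rng = np.random.default_rng(seed)
        assignment.update(_balanced_assignment(plan.train_ids, rng))
        assignment.update(_balanced_assignment(plan.test_ids, rng))
    else:
        tag = "v5" if mode == "single_v5" else "v7"
        for pid in np.concatenate([plan.train_ids, plan.test_ids]):
            assignment[pid.item() if hasattr(pid, "item") else pid] = tag
    return SplitPlan(
        iteration_id=plan.iteration_id,
        train_ids=plan.train_ids.copy(),
        test_ids=plan.test_ids.copy(),
        version_assignment=assignment,
    )


def assemble_design_matrix(
    dataset: MultiVersionDataset, plan: SplitPlan, side: str
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Build (features, ages, covariates) for one side of a plan.

    Row i takes participant i's feature row from the version the plan assigns
    to them; covariates are the aligned (sex, site) columns.  Column order is
    the dataset's canonical feature order for every assembly.
    """
    ids = plan.ids(side)
    missing = [pid for pid in ids if pid not in plan.version_assignment]
    if missing:
        raise ValueError(f"plan has no version assignment for {len(missing)} {side} ids")
    demo = dataset.demographics.set_index("participant_id")
    absent = [pid for pid in ids if pid not in demo.index]
    if absent:
        raise KeyError(f"participants missing from dataset: {absent[:5]}...")
    tags = np.array([plan.version_assignment[pid] for pid in ids])
    unknown_tags = set(tags) - set(dataset.features_by_version)
    if unknown_tags:
        raise KeyError(f"assignments reference unknown version(s) {sorted(unknown_tags)}")
    X = pd.DataFrame(
        np.empty((len(ids), len(dataset.feature_names))),
        index=pd.Index(ids, name="participant_id"),
        columns=dataset.feature_columns,
    )
    for tag in dataset.features_by_version:
        mask = tags == tag
        if mask.any():
            X.loc[mask] = dataset.features_by_version[tag].loc[ids[mask]].to_numpy()
    y = demo.loc[ids, "age"]
    covariates = demo.loc[ids, ["sex", "site"]]
    return X, y, covariates
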