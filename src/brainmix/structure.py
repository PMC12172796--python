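"""Feature-structure analyses: agreement, age associations, importance, PCA.

Four views of the paired feature tables that explain *why* version-shuffled
training behaves as it does: per-feature cross-version agreement (overall and
by age decade), per-feature age correlations, permutation feature importance
of a fitted model, and the principal-component composition of each version's
feature matrix sorted into thickness / area / volume loading mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import r2_score

from .models import FittedModel
from .synthdata import MultiVersionDataset, feature_name

__all__ = [
    "ImportanceRanking",
    "PCASummary",
    "cross_version_correlations",
    "age_correlations",
    "permutation_importance",
    "pca_by_feature_type",
    "importance_by_measure",
    "write_structure_tables",
]

#: Default age-decade bin edges; bins are closed-open with the last bin
#: absorbing the upper bound: [49, 60), [60, 70), [70, 83].
DEFAULT_AGE_BINS = (49.0, 60.0, 70.0, 83.0)


@dataclass
class ImportanceRanking:
    """Permutation feature importances, ranked."""

    entries: list[tuple[str, float, int]]  # (feature_name, importance, rank)
    n_repeats: int
    metric: str = "r2_drop"

    def __post_init__(self) -> None:
        ranks = [rank for _, _, rank in self.entries]
        if sorted(ranks) != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be a permutation of 1..p")

    def top(self, k: int) -> list[str]:
        ordered = sorted(self.entries, key=lambda e: e[2])
        return [name for name, _, _ in ordered[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["feature", "importance", "rank"]
        ).sort_values("rank", ignore_index=True)


@dataclass
class PCASummary:
    """Variance-explained profile and loading composition for one version."""

    version: str
    variance_explained: np.ndarray  # proportions, non-increasing, in [0, 1]
    composition: pd.DataFrame  # component x measure share of squared loadings

    def __post_init__(self) -> None:
        v = np.asarray(self.variance_explained, dtype=float)
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("variance proportions must lie in [0, 1]")
        if (np.diff(v) > 1e-10).any():
            raise ValueError("variance proportions must be non-increasing")
        sums = self.composition.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("composition proportions must sum to 1 per component")

    def to_frame(self) -> pd.DataFrame:
        out = self.composition.copy()
        out.insert(0, "variance_explained", np.asarray(self.variance_explained))
        out.insert(0, "component", np.arange(1, len(out) + 1))
        out.insert(0, "version", self.version)
        return out.reset_index(drop=True)


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = []
    for k in range(len(edges) - 1):
        close = "]" if k == len(edges) - 2 else ")"
        labels.append(f"[{edges[k]:g},{edges[k + 1]:g}{close}")
    return labels


def _column_corrs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two matrices (NaN where degenerate)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    return r


def cross_version_correlations(
    dataset: MultiVersionDataset,
    age_bins: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-feature Pearson r between the v5 and v7 columns.

    Returns a tidy frame with one row per (feature, age_bin); the ``overall``
    rows use every participant, the remaining rows stratify by the closed-open
    age bins (the last bin also absorbs its upper edge).  Bins with fewer than
    3 participants are kept with ``r`` = NaN and ``insufficient_n`` = True.
    Pearson r is invariant to affine rescaling of either version.
    """
    v5 = dataset.features_by_version["v5"].to_numpy(dtype=float)
    v7 = dataset.features_by_version["v7"].to_numpy(dtype=float)
    names = dataset.feature_columns
    age = dataset.demographics["age"].to_numpy()

    blocks = [("overall", np.ones(len(age), dtype=bool))]
    if age_bins is not None:
        edges = list(age_bins)
        if len(edges) < 2 or (np.diff(edges) <= 0).any():
            raise ValueError("age_bins must be at least two strictly increasing edges")
        for k, label in enumerate(_bin_labels(edges)):
            lo, hi = edges[k], edges[k + 1]
            mask = (age >= lo) & ((age <= hi) if k == len(edges) - 2 else (age < hi))
            blocks.append((label, mask))

    rows = []
    for label, mask in blocks:
        n = int(mask.sum())
        if n < 3:
            r = np.full(len(names), np.nan)
        else:
            r = _column_corrs(v5[mask], v7[mask])
        rows.append(
            pd.DataFrame(
                {"feature": names, "age_bin": label, "n": n, "r": r,
                 "insufficient_n": n < 3}
            )
        )
    return pd.concat(rows, ignore_index=True)


def age_correlations(
    dataset: MultiVersionDataset,
    version: str,
    ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Pearson r between each feature column of one version and age.

    ``ids`` restricts the computation to a participant subset (e.g. the
    training side of a split).  Zero-variance features are flagged and get
    ``r`` = NaN.
    """
    if version not in dataset.features_by_version:
        raise KeyError(f"unknown version {version!r}")
    mat = dataset.features_by_version[version]
    demo = dataset.demographics.set_index("participant_id")
    if ids is not None:
        ids = np.asarray(ids)
        missing = [pid for pid in ids if pid not in demo.index]
        if missing:
            raise KeyError(f"participants missing from dataset: {missing[:5]}")
        mat = mat.loc[ids]
        age = demo.loc[ids, "age"].to_numpy()
    else:
        age = demo["age"].to_numpy()
    if len(mat) < 3:
        raise ValueError("need at least 3 participants for correlations")
    values = mat.to_numpy(dtype=float)
    r = _column_corrs(values, np.repeat(age[:, None], values.shape[1], axis=1))
    zero_var = values.std(axis=0) == 0
    return pd.DataFrame(
        {"feature": dataset.feature_columns, "r": r, "zero_variance": zero_var}
    )


def permutation_importance(
    model: FittedModel,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceRanking:
    """Permutation feature importance as the mean R² drop per feature.

    For each feature, the column is permuted ``n_repeats`` times and the
    importance is the mean of (baseline R² − permuted R²).  Ranks are by
    descending importance with ties broken by feature-name lexicographic
    order, so the ranking is deterministic given the seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(y, dtype=float)
    values = X.to_numpy(dtype=float)
    baseline = r2_score(y, model.predict(X))
    rng = np.random.default_rng(seed)
    names = [str(c) for c in X.columns]
    importance = np.zeros(len(names))
    work = values.copy()
    for j in range(values.shape[1]):
        drops = np.empty(n_repeats)
        for rep in range(n_repeats):
            work[:, j] = values[rng.permutation(len(values)), j]
            pred = model.predict(pd.DataFrame(work, columns=X.columns))
            drops[rep] = baseline - r2_score(y, pred)
        work[:, j] = values[:, j]
        importance[j] = drops.mean()
    order = sorted(range(len(names)), key=lambda j: (-importance[j], names[j]))
    entries = [
        (names[j], float(importance[j]), rank + 1) for rank, j in enumerate(order)
    ]
    return ImportanceRanking(entries=entries, n_repeats=n_repeats)


def pca_by_feature_type(
    dataset: MultiVersionDataset, n_components: int = 10
) -> dict[str, PCASummary]:
    """PCA of each version's z-scored feature matrix plus loading composition.

    Composition is the share of squared loadings per measure type
    (thickness / area / volume) within each retained component.  Features are
    z-scored first so mixed units (area's scale) do not dominate.
    """
    measures = np.array([m for _, _, m in dataset.feature_names])
    out: dict[str, PCASummary] = {}
    for v, mat in dataset.features_by_version.items():
        values = mat.to_numpy(dtype=float)
        n, p = values.shape
        sd = values.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = [dataset.feature_columns[j] for j in np.flatnonzero(sd == 0)[:5]]
            raise ValueError(f"degenerate (zero-variance) features in {v}: {bad}")
        z = (values - values.mean(axis=0)) / sd
        k = min(n_components, p, n - 1)
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(z)
        sq = pca.components_**2  # k x p
        comp = pd.DataFrame(
            {m: sq[:, measures == m].sum(axis=1) for m in dict.fromkeys(measures)}
        )
        comp = comp.div(comp.sum(axis=1), axis=0)
        out[v] = PCASummary(
            version=v,
            variance_explained=pca.explained_variance_ratio_.copy(),
            composition=comp,
        )
    return out


def importance_by_measure(
    ranking: ImportanceRanking, dataset: MultiVersionDataset
) -> pd.DataFrame:
    """Exploratory: point-biserial r between importance and measure membership.

    For each measure type, the Pearson correlation between the per-feature
    importance vector and the 0/1 indicator that a feature belongs to that
    measure.  This is one concrete reading of "importance correlates with
    feature type"; the computation behind the published region-level numbers
    is ambiguous, so this routine documents its own definition and makes no
    equivalence claim.
    """
    frame = ranking.to_frame().set_index("feature")
    measures = {feature_name(*t): t[2] for t in dataset.feature_names}
    missing = [f for f in frame.index if f not in measures]
    if missing:
        raise KeyError(f"features absent from dataset: {missing[:5]}")
    imp = frame["importance"].to_numpy()
    rows = []
    for m in dict.fromkeys(measures.values()):
        ind = np.array([float(measures[f] == m) for f in frame.index])
        if ind.std() == 0 or imp.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(imp, ind)[0, 1])
        rows.append({"measure": m, "r": r, "n_features": int(ind.sum())})
    return pd.DataFrame(rows)


def write_structure_tables(
    outdir: str | Path,
    correlations: Optional[pd.DataFrame] = None,
    age_corrs: Optional[dict[str, pd.DataFrame]] = None,
    rankings: Optional[dict[str, ImportanceRanking]] = None,
    pca: Optional[dict[str, PCASummary]] = None,
) -> list[Path]:
    """Write whichever structure tables were computed as tidy CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    if correlations is not None:
        _write(correlations, "cross_version_correlations.csv")
    if age_corrs:
        stacked = pd.concat(
            [df.assign(version=v) for v, df in sorted(age_corrs.items())],
            ignore_index=True,
        )
        _write(stacked, "age_correlations.csv")
    if rankings:
        stacked = pd.concat(
            [r.to_frame().assign(version=v) for v, r in sorted(rankings.items())],
            ignore_index=True,
        )
        _write(stacked, "importance_rankings.csv")
    if pca:
        stacked = pd.concat(
            [s.to_frame() for _, s in sorted(pca.items())], ignore_index=True
        )
        _write(stacked, "pca_summary.csv")
    return written
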