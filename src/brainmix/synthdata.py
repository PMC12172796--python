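"""Synthetic paired two-version cortical feature cohorts.

The generator emulates the statistical structure of a middle-aged-to-older
cohort whose T1-weighted scans were processed with two releases of a cortical
reconstruction pipeline, yielding one Desikan-Killiany feature table per
release ("v5", "v7"): 34 regions x 2 hemispheres x {thickness, area, volume}
= 204 features by default.

Generative model (linear-Gaussian latent factors, per participant i and
feature j):

    core_v[i, j] = alpha_v[j] * z_age[i] + b[j] * m[type(j), i] + c_v[j] * eps[i, j]
    x_v[i, j]    = gain_v[j] * ( lambda[j] * core_v[i, j]
                                 + sqrt(1 - lambda[j]^2) * nu_v[i, j]
                                 + sex/site shifts )            + offset_v[j]

with z_age the standardised age, m measure-type anatomy factors shared across
all features of one measure, eps idiosyncratic anatomy shared by both
versions, and nu_v independent version-specific noise.  alpha_v is calibrated
so the mean feature-age correlation per version hits its target (default
-0.17 for v5, -0.15 for v7), and lambda so the per-feature cross-version
Pearson correlation hits its target (default mean 0.88, with entorhinal /
temporal-pole / frontal-pole area+volume forced below 0.69).  Features are
emitted on an approximately standardised scale; real-world units are not
simulated, since every downstream statistic is scale-equivariant or
standardises internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DK_REGIONS",
    "GeneratorConfig",
    "MultiVersionDataset",
    "GroundTruth",
    "generate_cohort",
    "inject_outliers",
    "write_dataset",
    "read_dataset",
]

#: The 34 cortical regions of the Desikan-Killiany parcellation (per hemisphere).
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "insula", "frontalpole",
)

VERSIONS = ("v5", "v7")
MEASURES = ("thickness", "area", "volume")

# Relative strength of the age association by measure type: cortical thinning
# dominates aging signal in this age range, volumes shrink moderately, surface
# area is nearly age-stable.
_MEASURE_SLOPE = {"thickness": -1.0, "volume": -0.6, "area": -0.25}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the reference cohort conditions: ages 49.33-82.84 y
    (mean 64.84, SD 7.27), 52.53 % female, three scanning sites with weights
    (0.5538, 0.3499, 0.0962), 204 features, mean cross-version agreement 0.88
    with low-agreement poles, and mean feature-age correlations -0.17 (v5)
    and -0.15 (v7).
    """

    n_participants: int = 1000
    age_range: tuple[float, float] = (49.33, 82.84)
    age_mean: float = 64.84
    age_sd: float = 7.27
    sex_fraction_female: float = 0.5253
    site_weights: tuple[float, float, float] = (0.5538, 0.3499, 0.0962)
    n_regions: int = 34
    measures: tuple[str, ...] = MEASURES
    target_cross_version_r: float = 0.88
    low_agreement_regions: tuple[str, ...] = ("entorhinal", "temporalpole", "frontalpole")
    low_agreement_target_r: float = 0.60
    thickness_agreement_r: float = 0.95
    mean_age_corr_v5: float = -0.17
    mean_age_corr_v7: float = -0.15
    sex_effect_size: float = 0.2
    site_effect_size: float = 0.0
    version_offset: float = 0.65
    version_gain_sd: float = 0.05
    version_age_bias_years: float = 0.0
    version_age_noise_years: float = 0.0
    version_slope_jitter: float = 0.1
    measure_factor_var: float = 0.10
    slope_jitter: float = 0.3
    strong_regions: tuple[str, ...] = (
        "superiorfrontal", "inferiorparietal", "precentral",
        "superiortemporal", "rostralmiddlefrontal",
    )
    strong_region_multiplier: float = 2.2
    age_slope_pattern: Optional[np.ndarray] = None
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_regions <= 0 or not self.measures:
            raise ValueError("feature count would be zero")
        if self.n_regions > len(DK_REGIONS):
            raise ValueError(
                f"n_regions must be <= {len(DK_REGIONS)} (Desikan-Killiany regions)"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range lower bound must be below upper bound")
        total = sum(self.site_weights)
        if abs(total - 1.0) > 5e-4:
            raise ValueError("site_weights must sum to 1")
        if abs(total - 1.0) > 1e-9:
            # printed percentages (e.g. 55.38/34.99/9.62) round to 99.99 %
            object.__setattr__(
                self, "site_weights", tuple(w / total for w in self.site_weights)
            )
        for w in (*self.site_weights, self.sex_fraction_female):
            if not 0.0 <= w <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        for r in (self.mean_age_corr_v5, self.mean_age_corr_v7):
            if not -1.0 < r < 1.0:
                raise ValueError("mean age-correlation targets must lie in (-1, 1)")
        for r in (self.target_cross_version_r, self.low_agreement_target_r):
            if not 0.0 < r <= 1.0:
                raise ValueError("cross-version correlation targets must lie in (0, 1]")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")

    @property
    def regions(self) -> tuple[str, ...]:
        return DK_REGIONS[: self.n_regions]

    @property
    def n_features(self) -> int:
        return self.n_regions * 2 * len(self.measures)


def feature_name(hemi: str, region: str, measure: str) -> str:
    return f"{hemi}_{region}_{measure}"


def _feature_table(config: GeneratorConfig) -> pd.DataFrame:
    rows = [
        {"hemi": h, "region": r, "measure": m, "name": feature_name(h, r, m)}
        for m in config.measures
        for h in ("lh", "rh")
        for r in config.regions
    ]
    return pd.DataFrame(rows)


@dataclass
class MultiVersionDataset:
    """A cohort with one row-aligned feature matrix per pipeline version."""

    demographics: pd.DataFrame  # participant_id, age, sex, site
    features_by_version: dict[str, pd.DataFrame]
    feature_names: list[tuple[str, str, str]]  # (hemi, region, measure)

    def __post_init__(self) -> None:
        names = [feature_name(*t) for t in self.feature_names]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        ids = self.demographics["participant_id"].to_numpy()
        for tag, mat in self.features_by_version.items():
            if list(mat.columns) != names:
                raise ValueError(f"column order of {tag} does not match feature_names")
            if not np.array_equal(mat.index.to_numpy(), ids):
                raise ValueError(f"row order of {tag} does not match demographics")
            if mat.isna().any().any():
                raise ValueError(f"missing values in {tag}")

    @property
    def n_participants(self) -> int:
        return len(self.demographics)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.demographics["participant_id"].to_numpy()

    @property
    def feature_columns(self) -> list[str]:
        return [feature_name(*t) for t in self.feature_names]

    def copy(self) -> "MultiVersionDataset":
        return MultiVersionDataset(
            demographics=self.demographics.copy(),
            features_by_version={k: v.copy() for k, v in self.features_by_version.items()},
            feature_names=list(self.feature_names),
        )


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort, for parameter-recovery tests."""

    feature_names: list[str]
    cross_version_target: np.ndarray  # per-feature target Pearson r between versions
    age_corr: dict[str, np.ndarray]  # per-version planted feature-age correlation
    z_loading: dict[str, np.ndarray]  # loading on the standardised-age factor
    measure_loading: dict[str, np.ndarray]  # loading on the measure-type anatomy factor
    shared_loading: dict[str, np.ndarray]  # loading on idiosyncratic shared anatomy
    version_noise_sd: dict[str, np.ndarray]  # version-specific noise SD per feature
    gain: dict[str, np.ndarray]
    offset: dict[str, np.ndarray]
    sex_effect: np.ndarray  # additive shift for female relative to male, per feature
    site_shifts: np.ndarray  # per-site additive shift (applied to all features)
    importance_order: list[str]  # features ranked by |planted age correlation|, desc
    measure_of_feature: np.ndarray  # measure-type index per feature
    displaced_cells: list[tuple[str, object, str]] = field(default_factory=list)
    # (version, participant_id, feature name) of every injected outlier cell

    def population_r2(self, version: str) -> float:
        """Population R^2 of age on this version's features.

        Computed from the planted factor loadings: R^2 = s' Sigma^-1 s with
        Sigma the feature covariance and s the feature-age covariances (both on
        the standardised scale; gains and offsets cancel).
        """
        a = self.z_loading[version]
        p = len(a)
        n_types = int(self.measure_of_feature.max()) + 1
        L = np.zeros((p, 1 + n_types))
        L[:, 0] = a
        for t in range(n_types):
            mask = self.measure_of_feature == t
            L[mask, 1 + t] = self.measure_loading[version][mask]
        psi = self.shared_loading[version] ** 2 + self.version_noise_sd[version] ** 2
        sigma = L @ L.T + np.diag(psi)
        return float(a @ np.linalg.solve(sigma, a))


def _calibrate_loadings(config: GeneratorConfig, rng: np.random.Generator):
    """Solve for per-feature loadings hitting the correlation targets.

    Returns (alpha, c) per version, plus b, lambda and the per-feature
    cross-version targets.  Uses a short fixed-point iteration: lambda depends
    on the core cross-correlation, which depends on alpha, which depends on
    lambda through the mean-age-correlation normalisation.
    """
    table = _feature_table(config)
    p = len(table)
    low = (
        table["region"].isin(config.low_agreement_regions)
        & table["measure"].isin(("area", "volume"))
    ).to_numpy()
    n_low = int(low.sum())
    r_target = np.full(p, config.target_cross_version_r)
    # Per-feature agreement is heterogeneous: thickness features (which carry
    # most of the age signal) agree strongly across pipeline releases, the
    # poles' area/volume agree poorly, and the remaining area/volume features
    # absorb whatever value keeps the overall mean on target.
    is_th = (table["measure"] == "thickness").to_numpy() & ~low
    n_th = int(is_th.sum())
    n_rem = p - n_low - n_th
    if n_low or n_th:
        budget = (
            p * config.target_cross_version_r
            - n_th * config.thickness_agreement_r
            - n_low * config.low_agreement_target_r
        )
        if n_rem:
            r_rem = budget / n_rem
            if not 0.0 < r_rem <= 1.0:
                raise ValueError("cross-version targets are infeasible for this feature set")
            r_target[:] = r_rem
        elif abs(budget) > 1e-9:
            raise ValueError("cross-version targets are infeasible for this feature set")
        r_target[is_th] = config.thickness_agreement_r
        r_target[low] = config.low_agreement_target_r

    if config.age_slope_pattern is not None:
        pattern = np.asarray(config.age_slope_pattern, dtype=float)
        if pattern.shape != (p,):
            raise ValueError(f"age_slope_pattern must have length {p}")
    else:
        base = table["measure"].map(_MEASURE_SLOPE).to_numpy(dtype=float)
        mult = np.where(
            table["region"].isin(config.strong_regions),
            config.strong_region_multiplier, 1.0,
        )
        jitter = 1.0 + rng.uniform(-config.slope_jitter, config.slope_jitter, size=p)
        pattern = base * mult * jitter

    b = np.sqrt(config.measure_factor_var) * np.ones(p)
    # v5 is the shared latent anatomy itself; v7 is an affine re-expression of
    # it plus independent version noise sized to hit the cross-version target.
    lam = {"v5": np.ones(p), "v7": np.sqrt(np.clip(r_target, 0.0, 1.0))}
    targets = {"v5": config.mean_age_corr_v5, "v7": config.mean_age_corr_v7}
    # per-feature, per-version perturbation of the age slope: pipeline releases
    # do not rescale every region's age sensitivity by one common factor
    delta = {v: config.version_slope_jitter * rng.standard_normal(p) for v in VERSIONS}
    shrink = np.ones(p)  # locally damps the jitter where it would make the
    # cross-version correlation target infeasible for a feature
    alpha: dict[str, np.ndarray] = {}
    c: dict[str, np.ndarray] = {}
    for attempt in range(40):
        for v in VERSIONS:
            pattern_v = pattern * (1.0 + shrink * delta[v])
            denom = float(np.mean(lam[v] * pattern_v))
            if denom == 0.0:
                raise ValueError("age_slope_pattern has zero mean loading; cannot calibrate")
            kappa = targets[v] / denom
            alpha[v] = kappa * pattern_v
            resid = 1.0 - alpha[v] ** 2 - b**2
            if np.any(resid < 0):
                raise ValueError(
                    "calibrated age loadings exceed unit variance; weaken the "
                    "age-correlation targets or the slope pattern"
                )
            c[v] = np.sqrt(resid)
        rho_core = alpha["v5"] * alpha["v7"] + b**2 + c["v5"] * c["v7"]
        lam7 = r_target / rho_core
        infeasible = lam7 > 1.0 + 1e-12
        if not infeasible.any():
            lam = {"v5": np.ones(p), "v7": np.clip(lam7, 0.0, 1.0)}
            if attempt >= 7:  # loadings and shrink factors have stabilised
                break
        else:
            shrink[infeasible] *= 0.5
    else:
        raise ValueError("cross-version targets are infeasible given the age targets")
    return table, alpha, b, c, lam, r_target


def generate_cohort(config: GeneratorConfig) -> tuple[MultiVersionDataset, GroundTruth]:
    """Generate a paired two-version cohort plus its planted ground truth.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # Demographics -------------------------------------------------------
    lo, hi = config.age_range
    a, bnd = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = sps.truncnorm.rvs(
        a, bnd, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < config.sex_fraction_female, "F", "M")
    site = rng.choice([1, 2, 3], size=n, p=config.site_weights)
    ids = np.arange(1, n + 1)
    demographics = pd.DataFrame(
        {"participant_id": ids, "age": age, "sex": sex, "site": site}
    )

    # Loadings -----------------------------------------------------------
    table, alpha, b, c, lam, r_target = _calibrate_loadings(config, rng)
    p = len(table)
    names = table["name"].tolist()
    measure_idx = table["measure"].map({m: i for i, m in enumerate(config.measures)})
    measure_idx = measure_idx.to_numpy()

    # Latent factors -----------------------------------------------------
    z_age = (age - age.mean()) / age.std(ddof=0)
    m_fac = rng.standard_normal((len(config.measures), n))  # measure-type anatomy
    eps = rng.standard_normal((n, p))  # idiosyncratic shared anatomy

    sex_eff = np.where(table["measure"].isin(("area", "volume")), -config.sex_effect_size, 0.0)
    d_sex = (sex == "F").astype(float) - 0.5
    site_shift_by_site = config.site_effect_size * np.array([-0.5, 0.0, 0.5])
    d_site = site_shift_by_site[site - 1]

    # v7 is an affine re-expression of the shared anatomy: per-feature gain near 1
    # and a per-feature systematic offset of either sign (SD = version_offset)
    gain = {"v5": np.ones(p), "v7": 1.0 + config.version_gain_sd * rng.standard_normal(p)}
    offset = {"v5": np.zeros(p), "v7": config.version_offset * rng.standard_normal(p)}
    # Apparent-age perturbation of the v7 reconstruction: participant i's v7
    # features are shifted along the age-slope direction by the equivalent of
    # eta_i ~ N(version_age_bias_years, version_age_noise_years^2) years of
    # aging, emulating the documented effect that the same person's brain age
    # differs systematically (bias) and idiosyncratically (noise) between
    # pipeline releases.
    eta = config.version_age_bias_years + config.version_age_noise_years * rng.standard_normal(n)
    age_direction = lam["v7"] * alpha["v7"] * gain["v7"] / config.age_sd

    features: dict[str, pd.DataFrame] = {}
    for v in VERSIONS:
        core = (
            z_age[:, None] * alpha[v][None, :]
            + m_fac[measure_idx, :].T * b[None, :]
            + eps * c[v][None, :]
        )
        nu = rng.standard_normal((n, p))
        x = lam[v][None, :] * core + np.sqrt(1.0 - lam[v] ** 2)[None, :] * nu
        x = x + d_sex[:, None] * sex_eff[None, :] + d_site[:, None]
        x = gain[v][None, :] * x + offset[v][None, :]
        if v == "v7":
            x = x + eta[:, None] * age_direction[None, :]
        features[v] = pd.DataFrame(x, index=pd.Index(ids, name="participant_id"), columns=names)

    planted_corr = {v: lam[v] * alpha[v] for v in VERSIONS}
    order = np.argsort(-np.abs(planted_corr["v5"]), kind="stable")
    truth = GroundTruth(
        feature_names=names,
        cross_version_target=r_target,
        age_corr=planted_corr,
        z_loading={v: lam[v] * alpha[v] for v in VERSIONS},
        measure_loading={v: lam[v] * b for v in VERSIONS},
        shared_loading={v: lam[v] * c[v] for v in VERSIONS},
        version_noise_sd={v: np.sqrt(1.0 - lam[v] ** 2) for v in VERSIONS},
        gain=gain,
        offset=offset,
        sex_effect=sex_eff,
        site_shifts=site_shift_by_site,
        importance_order=[names[i] for i in order],
        measure_of_feature=measure_idx,
    )
    dataset = MultiVersionDataset(
        demographics=demographics,
        features_by_version=features,
        feature_names=list(zip(table["hemi"], table["region"], table["measure"])),
    )
    if config.outlier_fraction > 0:
        dataset, displaced = inject_outliers(
            dataset,
            fraction=config.outlier_fraction,
            magnitude=config.outlier_magnitude,
            seed=int(rng.integers(2**31 - 1)),
        )
        truth.displaced_cells = displaced
    return dataset, truth


def inject_outliers(
    dataset: MultiVersionDataset,
    fraction: float,
    magnitude: float = 6.0,
    seed: int = 0,
) -> tuple[MultiVersionDataset, list[tuple[str, object, str]]]:
    """Displace a random fraction of participant x feature x version cells.

    Each selected cell is moved to ``column mean +/- magnitude * column SD``
    (mean and SD of the pre-injection column, random sign), planting outliers
    that a z-score rule at any threshold below ``magnitude`` should catch.
    Returns the modified dataset and the list of displaced cells as
    ``(version, participant_id, feature)`` tuples.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    out = dataset.copy()
    if fraction == 0.0:
        return out, []
    rng = np.random.default_rng(seed)
    displaced: list[tuple[str, object, str]] = []
    ids = dataset.participant_ids
    for v in sorted(out.features_by_version):
        mat = out.features_by_version[v]
        values = mat.to_numpy()
        n, p = values.shape
        mask = rng.random((n, p)) < fraction
        if not mask.any():
            continue
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        signs = rng.choice([-1.0, 1.0], size=(n, p))
        targets = mu[None, :] + signs * magnitude * sd[None, :]
        values[mask] = targets[mask]
        out.features_by_version[v] = pd.DataFrame(
            values, index=mat.index, columns=mat.columns
        )
        rows, cols = np.nonzero(mask)
        displaced.extend((v, ids[r], mat.columns[cc]) for r, cc in zip(rows, cols))
    return out, displaced


# ---------------------------------------------------------------------------
# Plain-text persistence


def write_dataset(
    dataset: MultiVersionDataset,
    directory: str | Path,
    truth: Optional[GroundTruth] = None,
) -> None:
    """Write demographics/feature tables as CSV, ground truth as a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.demographics.to_csv(directory / "demographics.csv", index=False)
    for v, mat in dataset.features_by_version.items():
        mat.to_csv(directory / f"features_{v}.csv")
    if truth is not None:
        payload = {
            "feature_names": truth.feature_names,
            "cross_version_target": truth.cross_version_target.tolist(),
            "age_corr": {v: arr.tolist() for v, arr in truth.age_corr.items()},
            "sex_effect": truth.sex_effect.tolist(),
            "site_shifts": truth.site_shifts.tolist(),
            "importance_order": truth.importance_order,
            "displaced_cells": [
                [v, int(pid), name] for v, pid, name in truth.displaced_cells
            ],
        }
        (directory / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def read_dataset(directory: str | Path) -> MultiVersionDataset:
    """Read a dataset previously written by :func:`write_dataset`.

    Also accepts externally produced tables of the same shape: one
    ``demographics.csv`` and one wide ``features_<tag>.csv`` per version with
    columns named ``<hemi>_<region>_<measure>``.
    """
    directory = Path(directory)
    demographics = pd.read_csv(directory / "demographics.csv")
    features: dict[str, pd.DataFrame] = {}
    names: Optional[list[str]] = None
    for path in sorted(directory.glob("features_*.csv")):
        tag = path.stem.split("_", 1)[1]
        mat = pd.read_csv(path, index_col="participant_id")
        features[tag] = mat
        names = list(mat.columns)
    if not features or names is None:
        raise FileNotFoundError(f"no features_*.csv found in {directory}")
    feature_names = [tuple(c.split("_", 2)) for c in names]
    return MultiVersionDataset(
        demographics=demographics,
        features_by_version=features,
        feature_names=feature_names,  # type: ignore[arg-type]
    )
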