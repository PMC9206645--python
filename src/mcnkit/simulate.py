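"""Synthetic two-timepoint cohorts with planted covariance structure.

The generator emulates the statistical skeleton the analysis assumes: each
group's per-ROI weekly growth rates are multivariate normal with a
block-structured correlation matrix (within- and between-network targets),
covariate effects add shared variance across ROIs, volumes are constructed
from baseline and rate, and invasive-procedure counts are drawn so the
designated high-stress group scores higher on the standardized stress
scale. Scales follow the target population: birth gestational age
~ N(26.64, 0.99) truncated to [24, 28) weeks, scans near 30 and 41 weeks
post-menstrual age.

Arbitrary block targets need not be jointly positive semi-definite; the
implied matrix is repaired by eigenvalue clipping and re-standardization to
unit diagonal, and any repair that moves a target noticeably is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .atlas import NETWORKS, NetworkAtlas
from .errors import ConfigError
from .io import COVARIATE_COLUMNS, CovariateTable, LongitudinalVolumes, write_cohort

logger = logging.getLogger(__name__)

#: repairs that move any block target by more than this are logged loudly
REPAIR_TOLERANCE = 0.05


def _pair_key(a: str, b: str) -> frozenset:
    if a == b:
        raise ConfigError("between-network key must join two distinct networks")
    return frozenset({a, b})


def build_block_correlation(
    atlas: NetworkAtlas, rho_within: dict, rho_between: dict
) -> np.ndarray:
    """Block-constant correlation matrix from per-block targets, PSD-repaired.

    ``rho_within`` maps network -> target correlation among its ROIs;
    ``rho_between`` maps a network pair (any 2-tuple order, or frozenset)
    -> cross-block target. All targets must lie in (-1, 1). If the implied
    matrix is not positive semi-definite it is repaired by eigenvalue
    clipping followed by re-standardization to unit diagonal; the maximum
    deviation from the targets is logged.
    """
    nets = atlas.networks_present()
    between = {_pair_key(*k) if not isinstance(k, frozenset) else k: v for k, v in rho_between.items()}
    for label, val in list(rho_within.items()) + [(tuple(sorted(k)), v) for k, v in between.items()]:
        if not -1 < val < 1:
            raise ConfigError(f"correlation target for {label} must be in (-1, 1), got {val}")
    n = atlas.n_rois
    R = np.zeros((n, n))
    net = atlas.network
    for i in range(n):
        for j in range(n):
            if i == j:
                R[i, j] = 1.0
            elif net[i] == net[j]:
                R[i, j] = rho_within.get(net[i], 0.0)
            else:
                R[i, j] = between.get(_pair_key(net[i], net[j]), 0.0)
    repaired = nearest_psd_correlation(R)
    dev = np.abs(repaired - R).max()
    if dev > 0:
        level = logging.WARNING if dev > REPAIR_TOLERANCE else logging.INFO
        logger.log(level, "PSD repair moved block targets by up to %.4f", dev)
    return repaired


def nearest_psd_correlation(R: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped, unit-diagonal PSD repair of a symmetric matrix."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R
    w = np.clip(w, floor, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def _default_within() -> dict:
    return {n: (0.40, 0.40) for n in NETWORKS}


def _default_between() -> dict:
    return {
        frozenset({"SN", "DMN"}): (0.20, 0.20),
        frozenset({"SN", "ECN"}): (0.20, 0.20),
        frozenset({"DMN", "ECN"}): (0.20, 0.20),
    }


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults give a null (no group effect) cohort.

    Correlation targets are (low-group, high-group) pairs per block.
    ``covariate_effects`` maps covariate name -> coefficient applied to the
    z-scored covariate, added uniformly to every ROI's rate (confounding
    that the residualization step should remove). ``procedures_per_day``
    sets the Poisson intensity of invasive procedures for the two groups.
    """

    n_per_group: int = 90
    atlas: NetworkAtlas | None = None
    rho_within: dict = field(default_factory=_default_within)
    rho_between: dict = field(default_factory=_default_between)
    covariate_effects: dict = field(
        default_factory=lambda: {"gestational_age_weeks": 0.003, "gender": 0.002}
    )
    rate_mean: float = 0.05  # fractional growth per week
    rate_noise_sd: float = 0.012
    baseline_volume_mean: float = 2500.0  # mm^3
    baseline_volume_sd: float = 400.0
    procedures_per_day: tuple = (1.5, 3.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 4:
            raise ConfigError(f"n_per_group must be >= 4, got {self.n_per_group}")
        if self.atlas is None:
            self.atlas = NetworkAtlas.default()
        self.rho_between = {
            (_pair_key(*k) if not isinstance(k, frozenset) else k): tuple(v)
            for k, v in self.rho_between.items()
        }
        self.rho_within = {k: tuple(v) for k, v in self.rho_within.items()}
        for src in (self.rho_within, self.rho_between):
            for key, pair in src.items():
                if len(pair) != 2 or not all(-1 < r < 1 for r in pair):
                    raise ConfigError(f"targets for {key} must be two correlations in (-1, 1)")
        unknown = set(self.covariate_effects) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown covariate(s) in covariate_effects: {sorted(unknown)}")
        if self.rate_noise_sd <= 0 or self.baseline_volume_mean <= 0:
            raise ConfigError("rate_noise_sd and baseline_volume_mean must be positive")

    def group_targets(self, group: str) -> tuple[dict, dict]:
        g = {"low": 0, "high": 1}[group]
        return (
            {k: v[g] for k, v in self.rho_within.items()},
            {k: v[g] for k, v in self.rho_between.items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "rho_between" in raw:
            raw["rho_between"] = {
                frozenset(k.split("_")) if isinstance(k, str) else frozenset(k): v
                for k, v in raw["rho_between"].items()
            }
        if "atlas" in raw and raw["atlas"] is not None:
            raw["atlas"] = NetworkAtlas.from_csv(raw["atlas"])
        if "procedures_per_day" in raw:
            raw["procedures_per_day"] = tuple(raw["procedures_per_day"])
        return cls(**raw)


def null_config(n_per_group: int = 45, seed: int | None = None, **kw) -> SimulationConfig:
    """Identical correlation structure in both groups (type-I calibration)."""
    return SimulationConfig(n_per_group=n_per_group, seed=seed, **kw)


def stress_effect_config(n_per_group: int = 90, seed: int | None = None, **kw) -> SimulationConfig:
    """Planted stress effect: higher SN, lower DMN and lower SN-DMN coupling
    in the high-stress group (+0.3 within-SN, -0.3 within-DMN, -0.2 SN-DMN)."""
    return SimulationConfig(
        n_per_group=n_per_group,
        seed=seed,
        rho_within={"SN": (0.30, 0.60), "DMN": (0.60, 0.30), "ECN": (0.40, 0.40)},
        rho_between={
            frozenset({"SN", "DMN"}): (0.35, 0.15),
            frozenset({"SN", "ECN"}): (0.15, 0.15),
            frozenset({"DMN", "ECN"}): (0.15, 0.15),
        },
        **kw,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    volumes: LongitudinalVolumes
    covariates: CovariateTable
    stress: pd.DataFrame  # subject_id-indexed: procedure_count, nicu_days
    true_labels: pd.Series  # subject_id -> low | high
    true_correlations: dict  # group -> PSD correlation matrix actually used
    config: SimulationConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(
            self.volumes, self.covariates, outdir / "volumes.csv", outdir / "covariates.csv"
        )
        self.stress.reset_index().to_csv(outdir / "stress.csv", index=False)
        truth = {
            "true_labels": self.true_labels.to_dict(),
            "true_correlations": {g: m.tolist() for g, m in self.true_correlations.items()},
            "seed": self.config.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; reproducible from the seed.

    ``seed`` overrides ``config.seed`` when given. Subjects of the low group
    come first, but all downstream grouping is score- or label-based, never
    positional.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    atlas = config.atlas
    n_g = config.n_per_group
    n = 2 * n_g
    k = atlas.n_rois
    groups = np.array(["low"] * n_g + ["high"] * n_g)
    sids = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="subject_id")

    # clinical covariates at the target population's scales
    gender = rng.binomial(1, 0.433, n).astype(float)  # 1 = female
    ga = truncnorm.rvs(
        (24.0 - 26.64) / 0.99, (28.0 - 26.64) / 0.99, loc=26.64, scale=0.99,
        size=n, random_state=rng,
    )
    age1 = np.maximum(rng.normal(30.0, 0.97, n), ga + 0.5)
    age2 = np.maximum(rng.normal(41.0, 0.90, n), age1 + 4.0)
    ivh = rng.binomial(1, 0.33, n).astype(float)
    surgeries = rng.poisson(0.5, n).astype(float)
    prenatal = rng.binomial(1, 0.91, n).astype(float)
    postnatal = rng.binomial(1, 0.30, n).astype(float)
    morphine = np.round(rng.exponential(3.14, n), 1)

    # group-wise correlated latent rates
    factors = {}
    truths = {}
    for g in ("low", "high"):
        within, between = config.group_targets(g)
        R = build_block_correlation(atlas, within, between)
        w, V = np.linalg.eigh(R)
        factors[g] = V * np.sqrt(np.clip(w, 0, None))
        truths[g] = R
    latent = np.empty((n, k))
    for g in ("low", "high"):
        mask = groups == g
        latent[mask] = rng.standard_normal((int(mask.sum()), k)) @ factors[g].T

    cov_values = {
        "gender": gender,
        "gestational_age_weeks": ga,
        "age_scan1_weeks": age1,
        "age_scan2_weeks": age2,
        "ivh": ivh,
        "surgeries": surgeries,
        "prenatal_steroids": prenatal,
        "postnatal_steroids": postnatal,
        "morphine_days": morphine,
    }
    confound = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        if name == "total_brain_volume_mm3":
            continue  # derived below; cannot drive rates
        confound += beta * _zscore(cov_values[name])
    rates = config.rate_mean + config.rate_noise_sd * latent + confound[:, None]

    # volumes from baseline and rate; v2 = v1 * (1 + rate * dt)
    v1 = np.maximum(
        rng.normal(config.baseline_volume_mean, config.baseline_volume_sd, (n, k)), 50.0
    )
    dt = (age2 - age1)[:, None]
    v2 = np.maximum(v1 * (1.0 + rates * dt), 1.0)
    tbv = np.maximum(1.25 * v1.sum(axis=1) + rng.normal(0.0, 2000.0, n), 1000.0)

    vol_df = pd.DataFrame(
        {"age_scan1_weeks": age1, "age_scan2_weeks": age2}, index=sids
    )
    for j, roi in enumerate(atlas.rois):
        vol_df[f"{roi}_t1"] = v1[:, j]
    for j, roi in enumerate(atlas.rois):
        vol_df[f"{roi}_t2"] = v2[:, j]
    cov_df = pd.DataFrame(
        {
            "gender": gender,
            "total_brain_volume_mm3": tbv,
            "gestational_age_weeks": ga,
            "age_scan1_weeks": age1,
            "age_scan2_weeks": age2,
            "ivh": ivh,
            "surgeries": surgeries,
            "prenatal_steroids": prenatal,
            "postnatal_steroids": postnatal,
            "morphine_days": morphine,
        },
        index=sids,
    )

    # invasive procedures: Poisson intensity per NICU day, higher in the
    # high-stress group, so standardized scores separate the groups
    nicu_days = np.maximum(np.round((age1 - ga) * 7.0), 3.0)
    rate_day = np.where(groups == "high", config.procedures_per_day[1], config.procedures_per_day[0])
    procedures = rng.poisson(rate_day * nicu_days).astype(float)
    stress_df = pd.DataFrame(
        {"procedure_count": procedures, "nicu_days": nicu_days}, index=sids
    )

    return SyntheticCohort(
        volumes=LongitudinalVolumes(data=vol_df, atlas=atlas),
        covariates=CovariateTable(data=cov_df),
        stress=stress_df,
        true_labels=pd.Series(groups, index=sids, name="group"),
        true_correlations=truths,
        config=config,
    )
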