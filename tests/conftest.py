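import numpy as np
import pandas as pd
import pytest

from mcnkit import (
    CovariateTable,
    LongitudinalVolumes,
    NetworkAtlas,
    assign_groups,
    compute_stress_scores,
    prepare_rates,
    simulate_cohort,
)
from mcnkit.errors import ValidationError
from mcnkit.io import COVARIATE_COLUMNS, write_cohort


@pytest.fixture(scope="session")
def atlas():
    return NetworkAtlas.default()


def make_toy_atlas(regions_per_network: dict[str, int]) -> NetworkAtlas:
    """Small non-strict atlas, e.g. {'SN': 2, 'DMN': 2} -> 4 ROIs."""
    rois, hemis, nets = [], [], []
    for net, k in regions_per_network.items():
        for i in range(k):
            rois.append(f"{net.lower()}_roi{i}")
            hemis.append("left" if i % 2 == 0 else "right")
            nets.append(net)
    return NetworkAtlas(rois=tuple(rois), hemisphere=tuple(hemis), network=tuple(nets), strict=False)


@pytest.fixture
def toy_atlas4():
    return make_toy_atlas({"SN": 2, "DMN": 2})


@pytest.fixture
def toy_atlas6():
    return make_toy_atlas({"SN": 2, "DMN": 2, "ECN": 2})


def make_cohort_frames(atlas: NetworkAtlas, n: int = 3, seed: int = 0):
    """Hand-sized valid volumes/covariates frames for I/O tests."""
    rng = np.random.default_rng(seed)
    sids = [f"P{i:03d}" for i in range(1, n + 1)]
    age1 = rng.normal(30, 0.5, n)
    age2 = age1 + rng.uniform(9, 12, n)
    vols = pd.DataFrame({"subject_id": sids, "age_scan1_weeks": age1, "age_scan2_weeks": age2})
    for roi in atlas.rois:
        vols[f"{roi}_t1"] = rng.uniform(1000, 3000, n)
    for roi in atlas.rois:
        vols[f"{roi}_t2"] = vols[f"{roi}_t1"] * (1 + rng.uniform(0.02, 0.08, n) * (age2 - age1))
    covs = pd.DataFrame({"subject_id": sids})
    for col in COVARIATE_COLUMNS:
        covs[col] = rng.uniform(0, 2, n)
    covs["age_scan1_weeks"] = age1
    covs["age_scan2_weeks"] = age2
    return vols, covs


def pipeline_pvalues(config, seed, K=0.20, n_perm=200, scheme="median"):
    """One full replicate: simulate -> score -> split -> rates -> permutation.

    Cohorts with a degenerate design matrix (e.g. a quasi-constant binary
    covariate, where a leverage of one makes external studentization
    undefined) are redrawn from a derived seed.
    """
    import mcnkit

    for trial in range(5):
        try:
            co = simulate_cohort(config, seed=(seed + trial * 1000003) % 2**31)
            scores = compute_stress_scores(
                co.stress["procedure_count"], co.stress["nicu_days"], subject_ids=co.stress.index
            )
            labels = assign_groups(scores, scheme)
            rates = prepare_rates(co.volumes, co.covariates)
            return mcnkit.permutation_test(
                rates, labels, K_values=[K], n_perm=n_perm, seed=seed + 1
            ).set_index("block")
        except ValidationError:
            continue
    raise RuntimeError("could not draw a non-degenerate cohort in 5 attempts")
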