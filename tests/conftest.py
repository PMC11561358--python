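import warnings

import numpy as np
import pytest

from sibscore.synthdata import SimConfig, simulate_study

COVARIATES = ["age", "sex", "chip"] + [f"PC{i}" for i in range(1, 9)]


def make_config(**overrides) -> SimConfig:
    """Study conditions with unit phenotype variance and noiseless GWAS
    weights, so recovery targets are the configured betas themselves."""
    base = dict(
        n_families=400, sibs_per_family=2, n_variants=120, block_size=6,
        beta_direct=0.2, beta_nurture=0.3, var_shared_env=0.15,
        gwas_se=1e-3, frac_ambiguous=0.0, frac_low_maf=0.0, frac_low_info=0.0,
        seed=101,
    )
    base.update(overrides)
    cfg = SimConfig(**base)
    cfg.var_noise = cfg.noise_for_unit_variance()
    return cfg


@pytest.fixture(scope="session")
def small_study():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(make_config())


@pytest.fixture(scope="session")
def recovery_study():
    """2,000 families under the direct + nurture conditions."""
    return simulate_study(make_config(n_families=2000, n_variants=200,
                                      block_size=5, seed=202))


@pytest.fixture(scope="session")
def recovery_data(recovery_study):
    """Phenotypes merged with the pipeline PGS for the recovery study."""
    from sibscore.pgs import run_pgs_pipeline

    study = recovery_study
    result, _, _ = run_pgs_pipeline(study.sumstats, study.offspring,
                                    reference=study.founders)
    data = study.pheno.merge(
        result.to_frame().rename(columns={"IID": "individual_id"}),
        on="individual_id")
    return data


@pytest.fixture(scope="session")
def stratified_study():
    """Two subpopulations with a subpopulation-linked environment."""
    return simulate_study(make_config(
        n_families=2000, n_variants=200, block_size=5, n_subpops=2,
        freq_divergence=0.1, subpop_env_effect=0.5, beta_nurture=0.0,
        var_shared_env=0.05, seed=77))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
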