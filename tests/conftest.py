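import pytest

import hostmet as hm
from hostmet.config import HOSTS
from hostmet.energetics import attach_metrics, growth_cost


def small_replicates(n3=6, n4=10, npu=4):
    reps = {}
    for h in HOSTS:
        reps[("instar3", h)] = n3
        reps[("instar4", h)] = n4
        reps[("pupa", h)] = npu
    return reps


@pytest.fixture()
def small_config():
    """Reduced-size study for fast structural tests."""
    return hm.SimulationConfig(
        replicates=small_replicates(), n_families=5, batch_size=4
    )


@pytest.fixture()
def noiseless_config():
    """Small study with every noise source switched off."""
    cfg = hm.SimulationConfig(
        replicates=small_replicates(), n_families=5, batch_size=4,
        family_sd=0.0, residual_sd=0.0,
    )
    cfg.trace.noise_sd_ppm = 0.0
    cfg.trace.drift_ppm_per_s = 0.0
    return cfg


@pytest.fixture(scope="session")
def default_study():
    """One full-size default study (the acceptance-scale dataset)."""
    return hm.generate_study(hm.SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def default_vco2(default_study):
    proc = hm.TraceProcessor().fit(default_study.sessions)
    return proc.transform(default_study.sessions)


@pytest.fixture(scope="session")
def default_metrics(default_study, default_vco2):
    return attach_metrics(default_study.cohort, default_vco2)


@pytest.fixture(scope="session")
def cohort_level_metrics():
    """Factory: 4th-instar metrics straight from latent rates.

    Skips trace synthesis (shown elsewhere to be an exact round trip) so
    replicated simulations stay fast.
    """

    def _make(config, seed):
        cohort = hm.generate_cohort(config, seed)
        d = cohort[cohort["stage"] == "instar4"].copy()
        d["vco2_ml_min"] = d["true_vco2_ml_min"]
        d["growth_cost_ml_per_g"] = growth_cost(
            d["dev_time_days"], d["mass_g"], d["vco2_ml_min"]
        )
        return d

    return _make
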