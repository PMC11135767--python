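import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

import germdose as gd  # noqa: E402

SMALL_GENES = {
    "MullerA": 80, "MullerAD": 80, "MullerC": 80, "neoY": 40,
    "MullerB": 150, "MullerE": 150, "MullerF": 15,
}


@pytest.fixture(scope="session")
def small_config():
    return gd.SimConfig(
        seed=7,
        n_genes_per_chrom=dict(SMALL_GENES),
        n_cells_per_type={s: 40 for s in gd.DEFAULT_STAGES},
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return gd.make_annotation(small_config)


@pytest.fixture(scope="session")
def small_sc(small_config, small_annotation):
    ann, _ = small_annotation
    return gd.simulate_sc_counts(small_config, ann, "DC_SHUTDOWN")


@pytest.fixture(scope="session")
def flat_config():
    """All baselines equal (logsd 0): exact analytic ratios hold."""
    return gd.SimConfig(
        seed=3,
        n_genes_per_chrom={"MullerA": 60, "neoY": 30, "MullerB": 100,
                           "MullerE": 100, "MullerF": 20},
        n_cells_per_type={s: 20 for s in gd.DEFAULT_STAGES},
        baseline_logmean=1.0,
        baseline_logsd=0.0,
        y_degeneration_logitsd=0.0,
    )
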