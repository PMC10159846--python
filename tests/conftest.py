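import pytest

from viratlas import pipeline, synthetic


@pytest.fixture(scope="session")
def cohort90():
    """Default study cohort: 3 orders x 2 families x 3 genera x 5 vOTUs.

    Runs the full pipeline once per session (alignment dominates the cost);
    downstream tests share the artifacts.
    """
    return pipeline.run_cohort(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 24-genome cohort for structural checks."""
    cfg = synthetic.SyntheticConfig(
        n_orders=2, families_per_order=2, genera_per_family=2, votus_per_genus=3,
        seed=11,
    )
    return pipeline.run_cohort(config=cfg)
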