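import numpy as np
import pytest

from randsig import SurvivalCohort, SyntheticSpec, generate_cohort, generate_network


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced-scale synthetic study used by several suites."""
    return SyntheticSpec(
        n_genes=120,
        n_samples=80,
        n_driver_genes=12,
        template_sizes=(6, 10, 15),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    cohort, drivers = generate_cohort(small_spec)
    network = generate_network(small_spec, drivers)
    return cohort, drivers, network


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose outcome is independent of expression (hazard_effect = 0)."""
    spec = SyntheticSpec(n_genes=100, n_samples=120, n_driver_genes=10,
                         hazard_effect=0.0, template_sizes=(5, 8, 12), seed=7)
    cohort, _ = generate_cohort(spec)
    return cohort


@pytest.fixture()
def tiny_cohort():
    """Hand-sized cohort: 4 genes x 8 samples with simple survival."""
    rng = np.random.default_rng(5)
    return SurvivalCohort(
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=[f"s{i}" for i in range(1, 9)],
        expression=rng.uniform(0.5, 4.0, size=(4, 8)),
        time=np.array([5.0, 8, 3, 9, 2, 7, 4, 6]),
        event=np.array([1, 0, 1, 1, 1, 0, 1, 1]),
    )
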