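import pytest

from cnge import (
    SimulationConfig,
    Locus,
    build_paired_data,
    eccc_table,
    estimate_copy_number,
    generate_cohort,
    segment_cohort,
)


def mini_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale-but-fast synthetic study used across the unit tests."""
    params = dict(
        n_samples=40,
        n_markers=600,
        n_probesets=240,
        n_chromosomes=3,
        chrom_length_bp=30_000_000,
        n_reference=30,
        amplicon_loci=[
            Locus("1", 5_000_001, 10_000_000, 6.0, 0.25),
            Locus("2", 10_000_001, 15_000_000, 6.0, 0.20),
        ],
        loss_loci=[Locus("3", 5_000_001, 15_000_000, 1.2, 0.6)],
        dosage_gene_fraction=0.15,
        n_cohorts_meta=3,
        duplicate_pairs=1,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(mini_config())


@pytest.fixture(scope="session")
def profiles(cohort):
    cnm = estimate_copy_number(
        cohort.tumor_intensities, cohort.reference_intensities, cohort.markers
    )
    return segment_cohort(cnm, seed=0)


@pytest.fixture(scope="session")
def paired(cohort, profiles):
    return build_paired_data(cohort.expression, cohort.annotation, profiles)


@pytest.fixture(scope="session")
def records(paired):
    return eccc_table(paired)
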