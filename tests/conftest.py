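import pytest

import starcall as sc


@pytest.fixture(scope="session")
def current_table():
    return sc.load_bundled_definitions("current")


@pytest.fixture(scope="session")
def prior_table():
    return sc.load_bundled_definitions("prior")


@pytest.fixture(scope="session")
def reference():
    return sc.build_reference(seed=1)


@pytest.fixture(scope="session")
def gene_model():
    return sc.GeneModel.bundled()


@pytest.fixture(scope="session")
def annotation():
    return sc.AnnotationTable.bundled()


@pytest.fixture(scope="session")
def study_cohort(current_table):
    """The full study-shaped cohort: 202 samples, 404 haplotypes."""
    return sc.make_cohort(
        current_table, sc.study_composition(), sc.novel_variant_placements(), seed=1
    )


def call_from_reads(dip, ref, table, *, depth=100, error_rate=0.0, seed=0, qc=None):
    """Simulate -> QC -> detect -> phase for one sample (test helper)."""
    from starcall.reads import (
        QCParams,
        build_observation_matrix,
        detect_candidate_sites,
        filter_reads,
        phase_sample,
    )

    reads = sc.simulate_reads(
        dip, ref, table, depth=depth, error_rate=error_rate, seed=seed
    )
    retained, _ = filter_reads(reads, qc or QCParams())
    sites = detect_candidate_sites(retained, ref)
    return phase_sample(build_observation_matrix(retained, ref, sites, dip.sample_id))
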