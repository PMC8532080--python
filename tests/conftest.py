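import pytest

from xburden import CohortSpec, apply_qc, generate_all


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down study conditions used by most tests."""
    return CohortSpec(
        n_cases=120,
        n_controls=40,
        n_genes=8,
        variants_per_gene_rate=25,
        n_common_variants=60,
        planted_gene="GENE0001",
        planted_case_carriers=6,
        planted_control_carriers=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_all(small_spec)


@pytest.fixture(scope="session")
def small_filtered(small_spec, small_cohort):
    samples, sites, gm = small_cohort
    sites_f, gm_f, report = apply_qc(samples, sites, gm)
    return samples, sites_f, gm_f, report
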