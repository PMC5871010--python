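import pytest

from sbaexome.intervals import GenomicIntervals
from sbaexome.synthetic import CohortConfig, generate_cohort, generate_population_resource
from sbaexome.variants import PooledEvidence, PopulationResource, TargetRegions, VariantCall

# desk-scale study conditions: default rates, reduced problem size
TINY = dict(
    n_samples=6,
    msi_fraction=1 / 3,
    germline_het_snps_per_sample=1500,
    n_population_loci=8000,
    target_mb=3.0,
    karyotype_scale=1000,
    n_ms_loci=600,
    n_inhouse=200,
    n_artifact_loci=30,
)


def make_call(
    chrom="1",
    pos=1500,
    ref="A",
    alt="C",
    depth=40,
    alt_depth=20,
    sample_id="S1",
    **kw,
) -> VariantCall:
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        depth=depth, alt_depth=alt_depth, **kw,
    )


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    return CohortConfig(seed=11, **TINY)


@pytest.fixture(scope="session")
def tiny_resource(tiny_config):
    return generate_population_resource(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_resource):
    """(calls_by_sample, pool, targets, ms_loci, truth) at desk scale."""
    return generate_cohort(tiny_config, tiny_resource)


@pytest.fixture()
def empty_resource():
    return PopulationResource(
        snv_af={},
        indel_sites=GenomicIntervals(),
        finnish_keys=set(),
        finnish_indel_sites=GenomicIntervals(),
        inhouse_keys=set(),
    )


@pytest.fixture()
def empty_pool():
    return PooledEvidence(snv_pool_reads={}, indel_window_support={})


@pytest.fixture()
def toy_targets():
    return TargetRegions(GenomicIntervals([("1", 1000, 2000)]), total_mb=0.001)
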