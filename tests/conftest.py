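import numpy as np
import pytest

from raveburden import (
    AnalysisConfig,
    AnnotatedVariant,
    CohortData,
    FunctionalClass,
    Group,
    Sample,
    SimConfig,
    SiteQuality,
    simulate_study,
)

PASSING_QUALITY = SiteQuality(
    dp=60, qual=800.0, qd=15.0, fs=2.0, haplotype_score=1.0, mq=55.0,
    mq_rank_sum=0.1, read_pos_rank_sum=-0.2,
)


def make_cohort(n_cases, n_controls, variant_specs):
    """Construct a small in-memory cohort.

    ``variant_specs`` is a list of (AnnotatedVariant kwargs, case-carrier
    indices, control-carrier indices).  All sites carry passing quality.
    """
    samples = [
        Sample(sample_id=f"CASE{i:04d}", group=Group.CASE) for i in range(n_cases)
    ] + [
        Sample(sample_id=f"CTRL{i:04d}", group=Group.CONTROL)
        for i in range(n_controls)
    ]
    variants, cols = [], []
    for k, (kwargs, case_idx, control_idx) in enumerate(variant_specs):
        defaults = dict(
            chrom="chr1", pos=1000 + k, ref="A", alt="T", gene=f"GENE{k}",
            functional_class=FunctionalClass.NONSYNONYMOUS,
        )
        defaults.update(kwargs)
        variants.append(AnnotatedVariant(**defaults))
        col = np.zeros(n_cases + n_controls, dtype=np.int8)
        for i in case_idx:
            col[i] = 1
        for i in control_idx:
            col[n_cases + i] = 1
        cols.append(col)
    geno = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((n_cases + n_controls, 0), dtype=np.int8)
    )
    return CohortData(
        samples=samples,
        variants=variants,
        genotypes=geno,
        site_quality=[PASSING_QUALITY] * len(variants),
    )


@pytest.fixture(scope="session")
def default_study():
    """One full-sized simulated study shared across the suite."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()
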