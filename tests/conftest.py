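import numpy as np
import pytest

import atacohort as a


@pytest.fixture(scope="session")
def small_spec():
    """Reduced cohort: quick to generate, still carries every planted layer."""
    return a.CohortSpec(
        n_samples=10,
        n_patients=6,
        genome=(("chr1", 8_000_000), ("chr2", 6_000_000)),
        n_core_regions=120,
        n_variable_regions=60,
        n_sample_specific_regions_per_sample=3,
        n_signature_regions=10,
        n_diffvar_regions=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return a.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (40 samples / 25 patients / 2,000 regions)."""
    return a.generate_cohort(a.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    consensus = a.merge_peak_sets(default_cohort.peak_sets)
    matrix = a.quantify_regions(consensus, default_cohort.fragments)
    a.add_normalized_layer(matrix)
    return matrix


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    return a.ighv_labels(default_cohort.sample_sheet)


@pytest.fixture(scope="session")
def default_patients(default_cohort):
    return default_cohort.sample_sheet.set_index("sample_id")["patient_id"]


def random_regions(rng, n, chroms=("chr1", "chr2"), span=300, width_max=40):
    """Small random interval sets for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span - 2))
        end = start + int(rng.integers(1, width_max))
        out.append(a.GenomicRegion(chrom, start, min(end, span)))
    return out
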