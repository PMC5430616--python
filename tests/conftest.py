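import numpy as np
import pytest

from admixscan import CohortSpec, GenotypeMatrix, SnpRecord, make_study


@pytest.fixture
def tiny_gm():
    """Hand-written 3-sample x 2-SNP matrix with one missing genotype."""
    snps = [
        SnpRecord("rsA", "1", 100, "A", "G"),
        SnpRecord("rsB", "1", 500, "C", "T"),
    ]
    dosage = np.array([[0.0, 2.0], [1.0, 2.0], [2.0, np.nan]])
    return GenotypeMatrix(["s1", "s2", "s3"], snps, dosage)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study reused across module tests."""
    spec = CohortSpec(n_snps=800, n_admixed=150, n_proxy_pool=40, seed=42)
    return make_study(spec)


@pytest.fixture(scope="session")
def small_supervised_fit(small_study):
    from admixscan import fit_supervised

    study = small_study
    comb = study.combined()
    assign = {
        s: lab for lab, pool in study.proxy_pools.items() for s in list(pool.samples)[:30]
    }
    used = list(study.cohort.samples) + list(assign)
    return study, fit_supervised(comb.subset_samples(used), assign, seed=1, n_restarts=1)
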