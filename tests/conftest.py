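import numpy as np
import pytest

from habitatrisk import phantoms


@pytest.fixture(scope="session")
def us_phantom():
    """Standard 4-class speckled ultrasound phantom."""
    return phantoms.gen_us_phantom(4, (256, 256), 0.2, seed=1)


@pytest.fixture(scope="session")
def us_phantom_clean():
    """Noiseless 2-class phantom: the zero-noise recovery limit."""
    return phantoms.gen_us_phantom(2, (128, 128), 0.0, seed=0)


@pytest.fixture(scope="session")
def ct_cohort_small():
    """Four 5-class CT lesions with low HU noise."""
    return phantoms.gen_ct_phantom_cohort(4, 5, (40, 40, 40), 5.0, seed=7)


@pytest.fixture(scope="session")
def ct_habitats(ct_cohort_small):
    """Supervoxels + cohort-consistent 5-habitat maps for the small cohort."""
    from habitatrisk import habitat_ct

    maps, profs = [], []
    for i in range(ct_cohort_small.n_patients):
        sv, p = habitat_ct.supervoxel_oversegment(
            ct_cohort_small.annotated(i), n_supervoxels=120, seed=0)
        maps.append(sv)
        profs.append(p)
    palette, habmaps = habitat_ct.two_stage_cluster(maps, profs, k_final=5,
                                                    seed=0)
    return maps, profs, palette, habmaps


@pytest.fixture(scope="session")
def clinical_cohort():
    return phantoms.gen_clinical_cohort(3000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
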