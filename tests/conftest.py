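import numpy as np
import pytest

from sexdecode import glm, mvpa, synthdata
from sexdecode.pipeline import movie_paradigm


@pytest.fixture(scope="session")
def short_movie_design():
    """100-volume movie design (sexual + control regressors), no jitter noise
    in the annotation so forward-model checks are exact."""
    design, tracks = movie_paradigm(100, 2.6, seed=0, jitter_sd=0.0)
    return design


@pytest.fixture(scope="session")
def full_mask_8():
    prob = synthdata.generate_tissue_probability((8, 8, 8))
    return mvpa.mask_from_probability(prob)


def make_cohort_maps(
    design,
    d=2.0,
    seed=0,
    n=10,
    grid=(8, 8, 8),
    corner=(2, 2, 2),
    region=(3, 3, 3),
    subject_sd=0.5,
    noise_sd=1.5,
    amp=None,
):
    """Simulate one cohort and return (sexual beta maps, labels).

    ``amp`` overrides the symmetric +/- d*sd/2 amplitude pair.
    """
    am, af = (d * subject_sd / 2, -d * subject_sd / 2) if amp is None else amp
    spec = synthdata.CohortSpec(
        n_male=n,
        n_female=n,
        grid_shape=grid,
        tr_seconds=2.6,
        n_volumes=design.n_timepoints,
        effect_regions=(
            synthdata.EffectRegion(
                "sexual_response",
                synthdata.region_block(corner, region),
                amp_male=am,
                amp_female=af,
                subject_sd=subject_sd,
                regressor="sexual",
            ),
        ),
        noise_sd=noise_sd,
        noise_ar1=0.3,
        seed=seed,
    )
    cohort = synthdata.generate_cohort(spec, design)
    maps = [glm.fit_glm(s, design).volume("sexual") for s in cohort]
    return maps, [s.sex for s in cohort]
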