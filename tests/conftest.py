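import numpy as np
import pytest

from mrsmeta.datasets import Metabolite, Normalization, Region, StudyDataset


def make_dataset(
    study_id="s01",
    region=Region.MPFC,
    metabolite=Metabolite.NAA,
    n_pt=20,
    n_con=20,
    mean_pt=10.0,
    sd_pt=1.5,
    mean_con=10.0,
    sd_con=1.5,
    normalization=Normalization.WATER,
    field_T=3.0,
    te_ms=30.0,
    **extra,
):
    return StudyDataset(
        study_id=study_id,
        region=region,
        metabolite=metabolite,
        n_pt=n_pt,
        n_con=n_con,
        mean_pt=mean_pt,
        sd_pt=sd_pt,
        mean_con=mean_con,
        sd_con=sd_con,
        normalization=normalization,
        field_T=field_T,
        te_ms=te_ms,
        **extra,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
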