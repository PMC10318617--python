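import numpy as np
import pytest

from phylodem.demography import DemographyModel, MigrationBand, SampleConfig


@pytest.fixture
def two_tip_model() -> DemographyModel:
    """Minimal valid demography: tips A, B under root R."""
    return DemographyModel(
        names={"A": "A", "B": "B", "R": "R"},
        parent={"A": "R", "B": "R"},
        theta={"A": 0.002, "B": 0.002, "R": 0.002},
        tau={"R": 0.001},
        bands=[],
    )


@pytest.fixture
def single_pop_model() -> DemographyModel:
    return DemographyModel(
        names={"A": "A"}, parent={}, theta={"A": 0.002}, tau={}, bands=[]
    )


@pytest.fixture
def im_model() -> DemographyModel:
    """Two-population isolation-with-migration model with one directed band."""
    return DemographyModel(
        names={"A": "A", "B": "B", "R": "R"},
        parent={"A": "R", "B": "R"},
        theta={"A": 0.002, "B": 0.001, "R": 0.003},
        tau={"R": 0.002},
        bands=[MigrationBand(source="A", target="B", rate=200.0, pair_id="A~B")],
    )


@pytest.fixture
def small_dataset(two_tip_model):
    from phylodem.coalsim import simulate_dataset

    return simulate_dataset(
        two_tip_model,
        SampleConfig({"A": 2, "B": 2}),
        n_loci=60,
        locus_length=400,
        missingness_rate=0.0,
        seed=11,
    )


def make_dataset(hap_matrices, populations, lengths=None, missing=None):
    """Hand-build a MultilocusDataset from per-locus haplotype matrices.

    ``populations`` lists one population per diploid individual; haplotypes
    2i and 2i+1 belong to individual i.
    """
    from phylodem.coalsim import Individual, Locus, MultilocusDataset

    n_ind = len(populations)
    loci = []
    for k, h in enumerate(hap_matrices):
        h = np.asarray(h, dtype=np.uint8)
        assert h.shape[0] == 2 * n_ind
        length = (lengths or {}).get(k, max(h.shape[1], 1)) if isinstance(lengths, dict) \
            else (lengths[k] if lengths else max(h.shape[1], 1))
        loci.append(
            Locus(length=length, haplotypes=h,
                  positions=np.arange(1, h.shape[1] + 1))
        )
    individuals = [
        Individual(id=f"{pop}_{i}", population=pop, haplotypes=(2 * i, 2 * i + 1))
        for i, pop in enumerate(populations)
    ]
    if missing is None:
        missing = np.zeros((n_ind, len(loci)), dtype=bool)
    return MultilocusDataset(loci=loci, individuals=individuals,
                             missing=np.asarray(missing, dtype=bool))
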