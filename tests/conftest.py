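import numpy as np
import pytest
from hypothesis import settings

from beanpop import IndividualInfo, LocusInfo, SNPDataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

_BASES = "ACGT"


def make_dataset(codes, populations, chromosomes=None, positions=None) -> SNPDataset:
    """Build an SNPDataset from a codes matrix (-1 = missing) and pop labels."""
    codes = np.asarray(codes, dtype=np.int8)
    n_ind, n_loc = codes.shape
    assert len(populations) == n_ind
    individuals = [
        IndividualInfo(id=f"ind{i}", population=populations[i]) for i in range(n_ind)
    ]
    loci = [
        LocusInfo(
            id=f"L{j}-{_BASES[j % 4]}/{_BASES[(j + 1) % 4]}",
            chromosome=str(chromosomes[j]) if chromosomes is not None else "1",
            position=int(positions[j]) if positions is not None else j * 1000 + 1,
            ref_allele=_BASES[j % 4],
            alt_allele=_BASES[(j + 1) % 4],
        )
        for j in range(n_loc)
    ]
    return SNPDataset(genotypes=codes, individuals=individuals, loci=loci)


@pytest.fixture
def tiny_ds() -> SNPDataset:
    """6 individuals in 2 pops, 4 loci, with one missing call."""
    codes = [
        [0, 0, 1, 2],
        [0, 1, 1, 2],
        [0, 0, 2, 2],
        [2, 0, 0, 2],
        [2, 1, 0, 2],
        [2, -1, 0, 2],
    ]
    return make_dataset(codes, ["A", "A", "A", "B", "B", "B"])
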