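import numpy as np
import pytest

from proppd.motif import AMINO_ACIDS
from proppd.scan import ProteinAnnotation
from proppd.simulate import SelectionDesign, SynthProteomeSpec


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_protein(
    protein_id: str,
    sequence: str,
    disorder=0.9,
    **kwargs,
) -> ProteinAnnotation:
    scores = np.full(len(sequence), disorder) if np.isscalar(disorder) else disorder
    return ProteinAnnotation(protein_id, sequence, scores, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    return SynthProteomeSpec(n_proteins=40, seed=101)


@pytest.fixture
def small_design():
    return SelectionDesign(seed=202, background_depth=2000, replicates_per_bait=2)
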