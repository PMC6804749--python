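import numpy as np
import pytest

from panplastome.matrix import AlignedMatrix
from panplastome.pan import build_all_pans, mask_ambiguous_columns
from panplastome.synth import emulate_study_shape, study_hierarchy

PRESET_SEED = 7


@pytest.fixture(scope="session")
def preset():
    """The study-shape synthetic dataset: (matrix, loci, truth)."""
    return emulate_study_shape(PRESET_SEED)


@pytest.fixture(scope="session")
def preset_pans(preset):
    m, _, _ = preset
    pans = build_all_pans(m)
    masked, kept = mask_ambiguous_columns(pans)
    return pans, masked, kept


@pytest.fixture(scope="session")
def hier():
    return study_hierarchy()


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     alphabet: str = "ACGT-") -> AlignedMatrix:
    chars = np.array(list(alphabet))
    seqs = ["".join(rng.choice(chars, L)) for _ in range(n)]
    return AlignedMatrix([f"s{i}" for i in range(n)], seqs)
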