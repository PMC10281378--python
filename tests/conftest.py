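import numpy as np
import pytest

from cas9kit.seq_io import IupacPattern, SeqRecord
from cas9kit.synthetic_data import PamLibrarySpec, load_preset

ADAPTER = "ACGCAGTGTAGCTTCG"
FLANKS = ("GCTTAGCTGGTCAACGTACT", "CCAGTTGACTGATCGGAACT")


@pytest.fixture(scope="session")
def eh():
    return load_preset("eh")


@pytest.fixture(scope="session")
def invivo_spec(eh):
    return PamLibrarySpec(IupacPattern(eh["invivo_pattern"]), eh["anchor"])


@pytest.fixture(scope="session")
def invitro_spec(eh):
    return PamLibrarySpec(IupacPattern(eh["invitro_pattern"]), eh["anchor"])


def random_record(rng: np.random.Generator, n: int, name: str = "seq"
                  ) -> SeqRecord:
    return SeqRecord(name, "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]))
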