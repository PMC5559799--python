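import numpy as np
import pytest

from asmeval import AssemblySet, Contig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def random_assembly(rng: np.random.Generator, n_contigs: int,
                    len_range=(50, 2000), label="rand") -> AssemblySet:
    return AssemblySet(
        label,
        (
            Contig(f"{label}_c{i}", random_dna(rng, int(rng.integers(*len_range))))
            for i in range(n_contigs)
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
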