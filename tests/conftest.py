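import numpy as np
import pytest

from pgscunk.io import Assembly, GraphNode, PangenomeGraph

BASES = np.array(list("ACGT"))


def random_seq(rng, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def make_assembly(name: str, *seqs: str) -> Assembly:
    return Assembly(name=name, contigs=[(f"c{i+1}", s) for i, s in enumerate(seqs)])


def make_graph(*seqs: str) -> PangenomeGraph:
    return PangenomeGraph(
        nodes=[GraphNode(id=f"n{i+1}", sequence=s) for i, s in enumerate(seqs)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
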