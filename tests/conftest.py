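import numpy as np
import pandas as pd
import pytest

from metabias import IncidenceMatrix, SequenceRecord, UltrametricTree


@pytest.fixture
def toy_tree() -> UltrametricTree:
    """Three-tip ultrametric tree with hand-computable descriptors."""
    return UltrametricTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20180814)


def make_incidence(cells, units=None, sites=None) -> IncidenceMatrix:
    cells = np.asarray(cells)
    units = units or [f"u{i}" for i in range(cells.shape[0])]
    sites = sites or [f"s{j}" for j in range(cells.shape[1])]
    return IncidenceMatrix(pd.DataFrame(cells, index=units, columns=sites))


def make_records(seqs, **common) -> list[SequenceRecord]:
    return [SequenceRecord(id=f"r{i}", seq=s, **common) for i, s in enumerate(seqs)]
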