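"""Shared fixtures: synthetic families at two scales.

The full-scale family mirrors the *E. coli* rRNA operon architecture
(7 copies, 1542 + 2904 column gene regions at ~99.6% identity, biallelic
186/92 bp spacer).  The toy family is small enough for the exhaustive
parsimony oracle (<= 4 copies, short regions, dense heterologous sites).
"""

import numpy as np
import pytest

from rrnconv.alignment import OperonAlignment
from rrnconv.simulator import CompressedFamily, SizeSampler
from rrnconv.synthetic import FamilySpec, default_size_sampler, generate_operon_family


@pytest.fixture(scope="session")
def ecoli_family():
    return generate_operon_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def ecoli_compressed(ecoli_family):
    return CompressedFamily.from_alignments(ecoli_family.all_alignments)


@pytest.fixture(scope="session")
def ecoli_sampler(ecoli_family):
    return default_size_sampler(ecoli_family, seed=1)


def make_toy_family(seed=0, n_copies=4, length=60, n_het=8):
    """A small gene-region family with known heterologous columns."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=length).astype(np.uint8)
    data = np.tile(base, (n_copies, 1))
    het = np.sort(rng.choice(length, size=n_het, replace=False))
    for c in het:
        k = int(rng.integers(1, n_copies // 2 + 1))
        rows = rng.choice(n_copies, size=k, replace=False)
        alt = (data[0, c] + 1 + rng.integers(3)) % 4
        data[rows, c] = alt
    ids = tuple(f"op{i}" for i in range(n_copies))
    return OperonAlignment("toy", ids, data, kind="gene")


@pytest.fixture()
def toy_family():
    return make_toy_family()


@pytest.fixture()
def toy_sampler():
    return SizeSampler.from_pairs("toy", [(1, 30), (5, 50)], floor=5)
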