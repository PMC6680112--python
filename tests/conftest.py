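import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from palmspec.popgen import GenotypeMatrix
from palmspec.synthetic_data import SimParams, gen_gene_alignments


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(n_genes=40, gene_length_codons=100, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Alignments, genotype matrices and truth for a 40-gene simulation."""
    return gen_gene_alignments(small_params)


def make_gm(
    dosages,
    species,
    positions=None,
    ref=None,
    alt=None,
    gene_id="g",
    **kwargs,
):
    """Convenience constructor for hand-built genotype matrices."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_ind = dosages.shape
    return GenotypeMatrix(
        gene_id=gene_id,
        positions=np.asarray(positions if positions is not None else range(1, n_sites + 1)),
        ref=list(ref) if ref is not None else ["A"] * n_sites,
        alt=list(alt) if alt is not None else ["T"] * n_sites,
        genotypes=dosages,
        samples=[f"s{i}" for i in range(n_ind)],
        species=np.asarray(species),
        **kwargs,
    )
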