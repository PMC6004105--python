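import numpy as np
import pytest

from pstfst.io import MarkerMatrix, TraitTable


def make_markers(bands, pops, region_of=None, locus_ids=None):
    """Build a MarkerMatrix from an array and a per-row population list."""
    bands = np.asarray(bands, dtype=float)
    ids = [f"ind{i + 1}" for i in range(bands.shape[0])]
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(bands.shape[1])]
    return MarkerMatrix(
        individual_ids=ids,
        population_of=dict(zip(ids, pops)),
        bands=bands,
        locus_ids=locus_ids,
        region_of=region_of,
    )


def make_traits(values, pops, trait_ids=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    ids = [f"ind{i + 1}" for i in range(values.shape[0])]
    if trait_ids is None:
        trait_ids = [f"T{j + 1}" for j in range(values.shape[1])]
    return TraitTable(
        individual_ids=ids,
        population_of=dict(zip(ids, pops)),
        values=values,
        trait_ids=trait_ids,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180613)


@pytest.fixture
def small_marker_matrix(rng):
    """3 populations x 5 individuals x 20 random loci."""
    bands = (rng.random((15, 20)) < 0.6).astype(float)
    pops = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
    return make_markers(bands, pops)
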