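"""Shared fixtures: synthetic datasets, alignments and structures.

All fixtures are generated programmatically; nothing is read from disk
except the packaged reference tables.
"""

from __future__ import annotations

import numpy as np
import pytest

from opsinspec import (
    PhotoresponseModel,
    TemplateMixture,
    default_protocol,
    simulate_responses,
)
from opsinspec.sites import (
    DEFAULT_SITES,
    AlignedOpsinSet,
    load_site_residues,
    site_matrix_from_long,
)


@pytest.fixture(scope="session")
def standard_protocol():
    return default_protocol("standard")


@pytest.fixture(scope="session")
def uv_protocol():
    return default_protocol("uv_shifted")


@pytest.fixture(scope="session")
def noiseless_480(standard_protocol):
    """Noise-free dataset from a single 480-nm pigment."""
    model = PhotoresponseModel(truth=TemplateMixture.single(480.0), noise_sd=0.0)
    return simulate_responses(standard_protocol, model, seed=11)


@pytest.fixture(scope="session")
def noisy_488(standard_protocol):
    """Assay-like noisy dataset from a single 488-nm pigment."""
    model = PhotoresponseModel(
        truth=TemplateMixture.single(488.0), noise_sd=0.05, n_replicates=4
    )
    return simulate_responses(standard_protocol, model, seed=42)


@pytest.fixture(scope="session")
def uv_mixture_truth():
    return TemplateMixture(((363.0, 0.69), (438.0, 0.31)))


@pytest.fixture(scope="session")
def noiseless_uv_mixture(uv_protocol, uv_mixture_truth):
    """Noise-free UV-protocol dataset from the two-state pigment mixture."""
    model = PhotoresponseModel(truth=uv_mixture_truth, noise_sd=0.0)
    return simulate_responses(uv_protocol, model, seed=7)


@pytest.fixture(scope="session")
def packaged_site_matrix():
    return site_matrix_from_long(load_site_residues())


@pytest.fixture(scope="session")
def synthetic_alignment(packaged_site_matrix):
    """Aligned melanopsin-like sequences carrying the packaged pocket-site
    residues at their mouse-numbered positions.

    The backbone is a shared poly-Leu scaffold; a gap is inserted in the
    reference at alignment column 10 (present in all other species) so the
    column-to-position mapping is exercised on a gapped reference.
    """
    length = 340
    sequences = {}
    for species, row in packaged_site_matrix.iterrows():
        seq = ["L"] * length
        for site in DEFAULT_SITES:
            seq[site - 1] = row[site]
        # insert one alignment column at index 10: gap in mouse, M elsewhere
        insert = "-" if species == "mouse" else "M"
        aligned = seq[:10] + [insert] + seq[10:]
        sequences[species] = "".join(aligned)
    return AlignedOpsinSet(sequences=sequences, reference_id="mouse")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
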