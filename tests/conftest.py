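"""Shared fixtures: small synthetic references and count matrices."""

import pytest

from apakit.matrix import make_design
from apakit.synthetic import (
    ApaProgram,
    ReferenceConfig,
    generate_reference,
    simulate_counts,
)


@pytest.fixture(scope="session")
def design3():
    return make_design(3)


@pytest.fixture(scope="session")
def small_ref():
    """60-gene reference with sequence, shortening + intronic activation."""
    program = ApaProgram(
        frac_shortened=0.2, frac_lengthened=0.05, frac_intronic_activated=0.15
    )
    return generate_reference(
        ReferenceConfig(n_genes=60, n_decoy_tracts=4), seed=11, program=program
    )


@pytest.fixture(scope="session")
def small_matrix(small_ref, design3):
    return simulate_counts(small_ref.truth, design3, depth=500, dispersion=0.1,
                           seed=12)


@pytest.fixture(scope="session")
def null_ref():
    """All-null 300-gene reference (no programmed effects), truth only."""
    return generate_reference(
        ReferenceConfig(n_genes=300), seed=21, program=ApaProgram(),
        with_sequence=False,
    )
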