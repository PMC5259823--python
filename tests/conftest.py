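"""Shared fixtures: synthetic complexes and annotation batches.

Session-scoped because ASA computation over a batch of complexes is the
expensive step and the annotation statistics are read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from qipi.fixtures import FixtureSpec, make_toy_complex
from qipi.interface import extract_interface
from qipi.structure import ComplexPartition, assign_secondary_structure, compute_asa


def annotate(toy, n_points: int = 960):
    """Extract the interface annotation of a toy complex."""
    struct = toy.structure()
    assign_secondary_structure(struct)
    compute_asa(struct, n_points=n_points)
    return extract_interface(ComplexPartition(struct, {"A"}, {"B"}))


@pytest.fixture(scope="session")
def toy_complex():
    """One default two-sheet complex: 30 residues per side, face ~30%."""
    return make_toy_complex(FixtureSpec(seed=1, n_residues_per_side=30, interface_fraction=0.3))


@pytest.fixture(scope="session")
def toy_annotation(toy_complex):
    return annotate(toy_complex)


@pytest.fixture(scope="session")
def toy_batch():
    """Twenty toy complexes with the default high-propensity enrichment."""
    return [
        make_toy_complex(
            FixtureSpec(seed=100 + k, n_residues_per_side=24, interface_fraction=0.35)
        )
        for k in range(20)
    ]


@pytest.fixture(scope="session")
def batch_annotations(toy_batch):
    return [annotate(toy) for toy in toy_batch]
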