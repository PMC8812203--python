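"""Shared fixtures: tiny hand-built networks and fingerprint helpers."""

from __future__ import annotations

import numpy as np
import pytest

from csln.chem import FP_LENGTH, Fingerprint
from csln.network import DTINetwork


def make_fp(on_bits, molecule_id="") -> Fingerprint:
    """Fingerprint with exactly the given set-bit positions (1-166)."""
    bits = np.zeros(FP_LENGTH, dtype=np.uint8)
    bits[list(on_bits)] = 1
    return Fingerprint(bits=bits, molecule_id=molecule_id)


def random_fp(rng, density=0.2, molecule_id="") -> Fingerprint:
    bits = (rng.random(FP_LENGTH) < density).astype(np.uint8)
    bits[0] = 0
    return Fingerprint(bits=bits, molecule_id=molecule_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_net():
    """4 drugs x 3 targets; target degrees 3, 2, 1."""
    adjacency = np.array(
        [
            [1, 1, 0],
            [1, 1, 0],
            [1, 0, 0],
            [0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return DTINetwork(
        drug_ids=("d1", "d2", "d3", "d4"),
        target_ids=("t1", "t2", "t3"),
        adjacency=adjacency,
    )


@pytest.fixture
def toy_fingerprints(rng):
    return {f"d{i}": random_fp(rng, molecule_id=f"d{i}") for i in range(1, 5)}
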