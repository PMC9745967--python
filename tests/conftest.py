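"""Shared fixtures and random-structure builders for the test suite."""

from __future__ import annotations

import random

import pytest

from glucansim.glycan import GLUCITOL, GLUCOSYL, Glycan, O3, O6


def build_random_glycan(rng: random.Random, max_dp: int = 10,
                        allow_reduced: bool = True) -> Glycan:
    """Grow a random tree residue by residue.

    Starts from a single root and repeatedly attaches a new residue at a
    uniformly chosen free O3/O6 slot; an independent construction path
    from the parser/serializer, suitable for round-trip and
    canonical-form property tests.
    """
    dp = rng.randint(1, max_dp)
    kinds = [GLUCITOL if (allow_reduced and rng.random() < 0.3) else GLUCOSYL]
    bonds: list[tuple[int, int, int]] = []
    # free (parent index, position) slots
    free = [(0, O3), (0, O6)]
    for child in range(1, dp):
        parent, pos = free.pop(rng.randrange(len(free)))
        kinds.append(GLUCOSYL)
        bonds.append((child, parent, pos))
        free.extend([(child, O3), (child, O6)])
    return Glycan.from_bonds(kinds, bonds)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260922)


@pytest.fixture
def random_glycans(rng) -> list[Glycan]:
    """A reproducible batch of 1000 random glycans (DP <= 10)."""
    return [build_random_glycan(rng) for _ in range(1000)]
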