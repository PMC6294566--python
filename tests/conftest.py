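"""Shared fixtures and the brute-force hairpin oracle."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from ringforge.examples import demo_ring_40, demo_ring_64, hairpin_free_ring
from ringforge.nn_thermo import is_complement, revcomp

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def brute_force_hairpins(
    seq: str, min_stem: int = 3, min_loop: int = 3, max_loop: int = 30
) -> set[tuple[int, int, int]]:
    """Independent enumeration of all maximal perfect-stem hairpins.

    Triple loop over every (start, stem_len, loop_len); a geometry counts
    iff the arms are exact reverse complements, bounds hold, and the stem
    is maximal: not outward-extendable (flanking bases pair) and not
    inward-extendable (innermost loop bases pair while the shrunken loop
    would still be legal).  Returns 1-based (start, stem_len, loop_len).
    """
    n = len(seq)
    found = set()
    for i in range(n):
        for s in range(min_stem, n // 2 + 1):
            for loop in range(min_loop, max_loop + 1):
                end = i + 2 * s + loop - 1
                if end >= n:
                    continue
                arm1 = seq[i : i + s]
                arm2 = seq[i + s + loop : i + 2 * s + loop]
                if arm2 != revcomp(arm1):
                    continue
                if 0 < i and end < n - 1 and is_complement(seq[i - 1], seq[end + 1]):
                    continue
                if loop - 2 >= min_loop and is_complement(
                    seq[i + s], seq[i + s + loop - 1]
                ):
                    continue
                found.add((i + 1, s, loop))
    return found


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def ring64() -> str:
    return demo_ring_64()


@pytest.fixture(scope="session")
def ring40() -> str:
    return demo_ring_40()


@pytest.fixture(scope="session")
def inert_ring() -> str:
    return hairpin_free_ring(48)
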