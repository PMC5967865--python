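"""Shared helpers for the test suite."""

from __future__ import annotations

import itertools

from sybodykit.library import CodonSlot


def brute_force_diversity(slots: list[CodonSlot]) -> int:
    """Count distinct amino-acid sequences by exhaustive enumeration.

    Independent oracle for theoretical_diversity; only feasible for toy
    schemes (a few slots).
    """
    choices = [
        tuple(slot.mix.support) if slot.is_randomized else ("*",)
        for slot in slots
    ]
    return len({"".join(combo) for combo in itertools.product(*choices)})


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))
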