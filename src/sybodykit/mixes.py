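"""Trinucleotide (trimer phosphoramidite) mixes used at randomized codon slots.

Each mix is a probability distribution over amino acids.  Mix 1 is fully
specified in the source publication: A, S, T, N, Y at 10.6% each; D, E, Q, R,
K, H, W at 5% each; F, M, V, I, L, G at 2% each.  Cysteine and proline are
excluded from every mix.  Mix 2 removes D and A (disfavoured at the ends of
beta-sheets) and mix 3 removes D, N, Q, G, S and M (disfavoured in the middle
of beta-sheets); only the exclusions are published, so the removed probability
mass is redistributed over the remaining residues (proportionally by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = ["TrinucleotideMix", "mix_definition", "MIX_NAMES"]

MIX_NAMES = ("mix1", "mix2", "mix3")

_MIX1_FREQUENCIES = {
    **{aa: 0.106 for aa in "ASTNY"},
    **{aa: 0.05 for aa in "DEQRKHW"},
    **{aa: 0.02 for aa in "FMVILG"},
}

_EXCLUDED = {
    "mix1": frozenset(),
    "mix2": frozenset("DA"),
    "mix3": frozenset("DNQGSM"),
}

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TrinucleotideMix:
    """A named amino-acid distribution for one randomized codon slot."""

    name: str
    frequencies: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", MappingProxyType(dict(self.frequencies)))
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"mix {self.name!r} frequencies sum to {total!r}, not 1")
        for banned in "CP":
            if self.frequencies.get(banned, 0.0) != 0.0:
                raise ValueError(f"mix {self.name!r} must exclude {banned}")
        if any(p < 0 for p in self.frequencies.values()):
            raise ValueError(f"mix {self.name!r} has negative frequencies")

    @property
    def support(self) -> tuple[str, ...]:
        """Amino acids with nonzero probability, alphabetically."""
        return tuple(sorted(aa for aa, p in self.frequencies.items() if p > 0))

    @property
    def support_size(self) -> int:
        return len(self.support)

    def probability(self, aa: str) -> float:
        return self.frequencies.get(aa, 0.0)


def mix_definition(name: str, renormalization: str = "proportional") -> TrinucleotideMix:
    """Return the published trinucleotide mix ``mix1``, ``mix2`` or ``mix3``.

    Parameters
    ----------
    name:
        One of ``mix1``, ``mix2``, ``mix3``.
    renormalization:
        How the probability mass of residues excluded from mix 2 / mix 3 is
        spread over the remaining residues: ``"proportional"`` (scale the
        surviving mix-1 frequencies) or ``"uniform"`` (add an equal share to
        each surviving residue).  Mix 1 is unaffected.
    """
    if name not in MIX_NAMES:
        raise ValueError(f"unknown trinucleotide mix {name!r}; expected one of {MIX_NAMES}")
    excluded = _EXCLUDED[name]
    kept = {aa: p for aa, p in _MIX1_FREQUENCIES.items() if aa not in excluded}
    removed_mass = 1.0 - sum(kept.values())
    if not excluded:
        freqs = kept
    elif renormalization == "proportional":
        scale = 1.0 / (1.0 - removed_mass)
        freqs = {aa: p * scale for aa, p in kept.items()}
    elif renormalization == "uniform":
        share = removed_mass / len(kept)
        freqs = {aa: p + share for aa, p in kept.items()}
    else:
        raise ValueError(f"unknown renormalization strategy {renormalization!r}")
    # exact-zero entries for the excluded residues, C and P included
    for aa in set("ACDEFGHIKLMNPQRSTVWY") - set(freqs):
        freqs[aa] = 0.0
    return TrinucleotideMix(name=name, frequencies=freqs)
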