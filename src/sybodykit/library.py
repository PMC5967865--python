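"""Randomization schemes: primer parsing, theoretical diversity and sampling.

A sybody library is defined by three CDR assembly primers in which the
placeholder triplets 111/222/333 mark codons synthesized from trinucleotide
mixes 1-3.  Parsing those primers yields ordered codon slots per CDR; the
theoretical library diversity is the product over randomized slots of the
number of amino acids each slot's mix permits, and in-silico library members
are drawn codon-wise from the mix distributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _sequences as seqdata
from .mixes import TrinucleotideMix, mix_definition

__all__ = [
    "CodonSlot",
    "RandomizationScheme",
    "LibraryMember",
    "PrimerParseError",
    "parse_randomized_primer",
    "theoretical_diversity",
    "rounded_diversity",
    "format_diversity",
    "sample_library",
    "scheme_for",
    "LIBRARY_NAMES",
]

LIBRARY_NAMES = ("concave", "loop", "convex")

_PLACEHOLDERS = {"111": "mix1", "222": "mix2", "333": "mix3"}
_DNA_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class CodonSlot:
    """One codon position: a fixed DNA run or a mix-randomized triplet.

    Fixed slots normally hold exactly three bases; 1-2 base partial slots occur
    at primer boundaries where the codon completes outside the primer.
    """

    kind: str  # "fixed" | "randomized"
    bases: str | None = None
    mix: TrinucleotideMix | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if not self.bases or not _DNA_RE.match(self.bases) or len(self.bases) > 3:
                raise ValueError(f"fixed slot needs 1-3 DNA bases, got {self.bases!r}")
        elif self.kind == "randomized":
            if self.mix is None:
                raise ValueError("randomized slot needs a trinucleotide mix")
        else:
            raise ValueError(f"unknown slot kind {self.kind!r}")

    @property
    def is_randomized(self) -> bool:
        return self.kind == "randomized"


class PrimerParseError(ValueError):
    pass


def parse_randomized_primer(
    primer: str,
    mixes: Mapping[str, TrinucleotideMix] | None = None,
    frame: int = 0,
) -> list[CodonSlot]:
    """Parse a whitespace-delimited primer string into ordered codon slots.

    Placeholder triplets 111/222/333 become randomized slots referencing mixes
    1-3; DNA tokens become fixed slots.  Consecutive DNA tokens are joined and
    re-split into triplets in the reading frame given by ``frame`` (bases of a
    run falling before the frame offset, or left over at its end, become
    partial fixed slots).
    """
    if not 0 <= frame <= 2:
        raise ValueError("frame offset must be 0, 1 or 2")
    mixes = mixes or {name: mix_definition(name) for name in _PLACEHOLDERS.values()}

    slots: list[CodonSlot] = []
    run: list[str] = []

    def flush_run() -> None:
        if not run:
            return
        dna = "".join(run)
        run.clear()
        offset = frame if not slots else 0
        if offset:
            slots.append(CodonSlot("fixed", bases=dna[:offset]))
            dna = dna[offset:]
        for i in range(0, len(dna), 3):
            slots.append(CodonSlot("fixed", bases=dna[i : i + 3]))

    for token in primer.split():
        if token in _PLACEHOLDERS:
            flush_run()
            slots.append(CodonSlot("randomized", mix=mixes[_PLACEHOLDERS[token]]))
        elif _DNA_RE.match(token):
            run.append(token)
        else:
            raise PrimerParseError(
                f"token {token!r} is neither a DNA run nor a mix placeholder (111/222/333)"
            )
    flush_run()
    return slots


@dataclass(frozen=True)
class RandomizationScheme:
    """Ordered codon slots per CDR, optionally embedded in a scaffold.

    ``scaffold`` is the full-length non-randomized coding sequence when one is
    available; ``cdr_windows`` maps each CDR to the [start, end) scaffold
    coordinates of the primer-covered region that lies inside the scaffold.
    """

    library_name: str
    cdr_slots: Mapping[str, Sequence[CodonSlot]]
    scaffold: str | None = None
    cdr_windows: Mapping[str, tuple[int, int]] | None = None
    scaffold_synthetic: bool = False

    @property
    def randomized_slots(self) -> list[CodonSlot]:
        return [s for cdr in self.cdr_slots.values() for s in cdr if s.is_randomized]

    @property
    def n_randomized(self) -> int:
        return len(self.randomized_slots)

    def mix_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for slot in self.randomized_slots:
            counts[slot.mix.name] = counts.get(slot.mix.name, 0) + 1
        return counts


def theoretical_diversity(scheme: RandomizationScheme) -> int:
    """Exact count of distinct amino-acid sequences the scheme encodes.

    Product over randomized slots of the mix support size; fixed slots
    contribute a factor of one.  Returned as an exact Python integer.
    """
    diversity = 1
    for slot in scheme.randomized_slots:
        diversity *= slot.mix.support_size
    return diversity


def format_diversity(diversity: int, sig: int = 2) -> str:
    """Render an exact diversity in scientific notation at ``sig`` significant figures."""
    if diversity <= 0:
        raise ValueError("diversity must be positive")
    return f"{diversity:.{sig - 1}e}"


def rounded_diversity(diversity: int, sig: int = 2) -> float:
    """Diversity rounded to ``sig`` significant figures, as a float.

    Round-trips through decimal scientific notation so the result is bit-equal
    to the float a reader gets from the printed value (e.g. exactly 8.3e17).
    """
    return float(format_diversity(diversity, sig))


# -- scaffold embedding -------------------------------------------------------


@dataclass(frozen=True)
class EmbeddedWindow:
    start: int
    end: int
    slot_starts: tuple[int, ...]  # scaffold offset of each randomized slot
    slots: tuple[CodonSlot, ...]  # primer slots trimmed to the scaffold-matching region


def _slots_regex(slots: Sequence[CodonSlot]) -> str:
    return "".join(
        "([ACGT]{3})" if s.is_randomized else re.escape(s.bases) for s in slots
    )


def embed_in_scaffold(slots: Sequence[CodonSlot], scaffold: str) -> EmbeddedWindow:
    """Locate the primer's realized region within a scaffold.

    Primer ends may carry cloning handles absent from the scaffold; literal
    bases are trimmed from either end (never past a randomized slot) until the
    pattern matches exactly once.
    """
    trimmed = list(slots)
    for _ in range(60):
        if not trimmed:
            break
        matches = list(re.finditer(_slots_regex(trimmed), scaffold))
        if len(matches) == 1:
            m = matches[0]
            n_rand = sum(1 for s in trimmed if s.is_randomized)
            return EmbeddedWindow(
                start=m.start(),
                end=m.end(),
                slot_starts=tuple(m.start(g + 1) for g in range(n_rand)),
                slots=tuple(trimmed),
            )
        head, tail = trimmed[0], trimmed[-1]
        lead = len(head.bases) if not head.is_randomized else 0
        trail = len(tail.bases) if not tail.is_randomized else 0
        if lead == 0 and trail == 0:
            break
        if lead >= trail:
            trimmed = ([CodonSlot("fixed", bases=head.bases[1:])] if lead > 1 else []) + trimmed[1:]
        else:
            trimmed = trimmed[:-1] + ([CodonSlot("fixed", bases=tail.bases[:-1])] if trail > 1 else [])
    raise ValueError("primer slots could not be located in the scaffold")


def _loop_scaffold() -> str:
    # local import: assembly also imports this module for primer parsing
    from .assembly import assembled_scaffold

    return assembled_scaffold("loop")


def scheme_for(library: str, renormalization: str = "proportional") -> RandomizationScheme:
    """Build the randomization scheme of one of the three published libraries.

    The concave scheme embeds in the published non-randomized scaffold; the
    loop scheme embeds in a scaffold reconstructed by simulating the published
    assembly (flagged synthetic); the convex scaffold is not published, so the
    convex scheme carries CDR slots only.
    """
    if library not in LIBRARY_NAMES:
        raise ValueError(f"unknown library {library!r}; expected one of {LIBRARY_NAMES}")
    mixes = {name: mix_definition(name, renormalization) for name in ("mix1", "mix2", "mix3")}
    primer_names = seqdata.LIBRARY_CDR_PRIMERS[library]
    cdr_slots = {
        f"CDR{i + 1}": parse_randomized_primer(seqdata.LIBRARY_PRIMERS[p], mixes=mixes)
        for i, p in enumerate(primer_names)
    }
    scaffold = None
    synthetic = False
    if library == "concave":
        scaffold = seqdata.CONCAVE_FRAMEWORK_DNA
    elif library == "loop":
        scaffold = _loop_scaffold()
        synthetic = True
    windows = None
    if scaffold is not None:
        windows = {
            cdr: (w.start, w.end)
            for cdr, w in ((c, embed_in_scaffold(s, scaffold)) for c, s in cdr_slots.items())
        }
    return RandomizationScheme(
        library_name=library,
        cdr_slots=cdr_slots,
        scaffold=scaffold,
        cdr_windows=windows,
        scaffold_synthetic=synthetic,
    )


# -- sampling -----------------------------------------------------------------


@dataclass(frozen=True)
class LibraryMember:
    name: str
    dna: str
    protein: str


def _realize_slots(
    slots: Sequence[CodonSlot],
    rng: np.random.Generator,
    codon_table: Mapping[str, str],
) -> str:
    dna: list[str] = []
    for slot in slots:
        if slot.is_randomized:
            support = slot.mix.support
            probs = np.array([slot.mix.probability(aa) for aa in support])
            aa = str(rng.choice(list(support), p=probs / probs.sum()))
            dna.append(codon_table[aa])
        else:
            dna.append(slot.bases)
    return "".join(dna)


def sample_library(
    scheme: RandomizationScheme,
    n: int,
    seed: int,
    codon_table: Mapping[str, str] | None = None,
) -> list[LibraryMember]:
    """Draw ``n`` library members, codon slots sampled independently from their mixes.

    Members are full-length (scaffold with realized CDR windows) when the
    scheme carries a scaffold, otherwise the realized CDR cassettes joined in
    order.  Deterministic for a given seed; sampled proteins never contain C
    or P at randomized positions (the mixes exclude them).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    from Bio.Seq import Seq

    codon_table = dict(codon_table or seqdata.ECOLI_PREFERRED_CODONS)
    rng = np.random.default_rng(seed)
    windows: list[EmbeddedWindow] = []
    if scheme.scaffold is not None:
        windows = sorted(
            (embed_in_scaffold(s, scheme.scaffold) for s in scheme.cdr_slots.values()),
            key=lambda w: w.start,
        )
    members: list[LibraryMember] = []
    for i in range(n):
        if scheme.scaffold is not None:
            dna = scheme.scaffold
            for w in reversed(windows):  # right-to-left keeps coordinates valid
                dna = dna[: w.start] + _realize_slots(w.slots, rng, codon_table) + dna[w.end :]
        else:
            dna = "".join(
                _realize_slots(slots, rng, codon_table) for slots in scheme.cdr_slots.values()
            )
        protein = str(Seq(dna[: len(dna) - len(dna) % 3]).translate())
        members.append(
            LibraryMember(name=f"{scheme.library_name}_{seed}_{i:06d}", dna=dna, protein=protein)
        )
    return members


def randomized_protein_positions(scheme: RandomizationScheme) -> list[int]:
    """0-based protein positions of the randomized slots (scaffold schemes only)."""
    if scheme.scaffold is None:
        raise ValueError("positions require a scaffold-embedded scheme")
    positions: list[int] = []
    for slots in scheme.cdr_slots.values():
        w = embed_in_scaffold(slots, scheme.scaffold)
        positions.extend(s // 3 for s in w.slot_starts)
    return sorted(positions)


def empirical_frequencies(
    members: Iterable[LibraryMember], scheme: RandomizationScheme
) -> dict[int, dict[str, float]]:
    """Per-randomized-position amino-acid frequencies across sampled members."""
    positions = randomized_protein_positions(scheme)
    counts: dict[int, dict[str, int]] = {p: {} for p in positions}
    total = 0
    for member in members:
        total += 1
        for p in positions:
            aa = member.protein[p]
            counts[p][aa] = counts[p].get(aa, 0) + 1
    return {p: {aa: c / total for aa, c in cnt.items()} for p, cnt in counts.items()}
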