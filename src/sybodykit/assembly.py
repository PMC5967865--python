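"""Type IIS digestion, sticky-end ligation and two-step CDR library assembly.

Linear double-stranded DNA is represented by its top strand (5'->3').  The
Type IIS enzymes used here (BsaI, BpiI, SapI/BspQI) cut downstream of their
recognition motif and leave 5' single-strand overhangs; a digestion fragment
records the top strand it retains plus the overhang at each end.  Overhangs
are stored in top-strand coordinates: the left overhang is the single-stranded
5' extension of the fragment's own top strand (a prefix of ``top``), while the
right overhang is the top-strand projection of the bottom strand's 5'
extension (the actual single-stranded sequence there is its reverse
complement).  Two fragments ligate when the projections agree, which is
exactly when the protruding strands are Watson-Crick complementary, and the
joined top strand is simply the concatenation of the two tops.

Coordinates are 0-based, half-open; all substrates are linear and digestion is
complete (every site is cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import _sequences as seqdata
from .library import CodonSlot, parse_randomized_primer

__all__ = [
    "RestrictionEnzyme",
    "DigestFragment",
    "ENZYMES",
    "DigestError",
    "LigationError",
    "AssemblyError",
    "digest",
    "ligate",
    "translate",
    "fx_overhang_check",
    "fx_wrap",
    "pcr_product",
    "overlap_merge",
    "cdr_fragment",
    "assemble_fragments",
    "assemble_member",
    "assembled_scaffold",
    "AssemblyReport",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Type IIS cut geometry: ``recognition`` N(cut_top) / N(cut_bottom).

    ``cut_top``/``cut_bottom`` are offsets downstream of the motif's 3' end on
    the top and bottom strand for a top-strand site; ``cut_top < cut_bottom``
    yields a 5' overhang of length ``cut_bottom - cut_top``.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    @property
    def overhang_length(self) -> int:
        return self.cut_bottom - self.cut_top


# Editable registry of standard enzyme geometries.
ENZYMES: dict[str, RestrictionEnzyme] = {
    "BsaI": RestrictionEnzyme("BsaI", "GGTCTC", 1, 5),
    "BpiI": RestrictionEnzyme("BpiI", "GAAGAC", 2, 6),
    "SapI": RestrictionEnzyme("SapI", "GCTCTTC", 1, 4),
    "BspQI": RestrictionEnzyme("BspQI", "GCTCTTC", 1, 4),
}


class DigestError(ValueError):
    pass


class LigationError(ValueError):
    pass


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class DigestFragment:
    """A linear duplex with typed single-strand ends (see module docstring)."""

    top: str
    left_overhang: str = ""
    right_overhang: str = ""

    def __post_init__(self) -> None:
        if not self.top.startswith(self.left_overhang):
            raise ValueError("left overhang must be a prefix of the top strand")

    @property
    def left_overhang_strand(self) -> str:
        """Actual 5'->3' single-strand sequence protruding at the left (top strand)."""
        return self.left_overhang

    @property
    def right_overhang_strand(self) -> str:
        """Actual 5'->3' single-strand sequence protruding at the right (bottom strand)."""
        return reverse_complement(self.right_overhang)

    @property
    def is_blunt(self) -> bool:
        return not self.left_overhang and not self.right_overhang

    def reverse_complement(self) -> "DigestFragment":
        full = self.top + self.right_overhang
        return DigestFragment(
            top=reverse_complement(full[len(self.left_overhang) :]),
            left_overhang=self.right_overhang_strand,
            right_overhang=reverse_complement(self.left_overhang),
        )


def _cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, int]]:
    motif = enzyme.recognition
    rc_motif = reverse_complement(motif)
    cuts: list[tuple[int, int]] = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        if window == motif:
            top = i + len(motif) + enzyme.cut_top
            bottom = i + len(motif) + enzyme.cut_bottom
            cuts.append((top, bottom))
        if window == rc_motif and rc_motif != motif:
            top = i - enzyme.cut_bottom
            bottom = i - enzyme.cut_top
            cuts.append((top, bottom))
    for top, bottom in cuts:
        if top < 0 or bottom > len(seq):
            raise DigestError(
                f"{enzyme.name} site too close to a sequence end for a complete cut "
                f"(cut at top={top}, bottom={bottom}, length={len(seq)})"
            )
    cuts.sort()
    for (t1, b1), (t2, b2) in zip(cuts, cuts[1:]):
        if b1 > t2:
            raise DigestError(f"{enzyme.name} cut sites overlap at {b1}/{t2}")
    return cuts


def digest(seq: str, enzyme: RestrictionEnzyme | str) -> list[DigestFragment]:
    """Completely digest linear dsDNA, scanning both strands for the motif.

    Fragments are returned 5'->3' left to right; a sequence without any site
    comes back as a single blunt fragment.
    """
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    seq = seq.upper()
    cuts = _cut_positions(seq, enzyme)
    if not cuts:
        return [DigestFragment(top=seq)]
    fragments: list[DigestFragment] = []
    prev_top, prev_bottom = 0, 0
    for top, bottom in cuts + [(len(seq), len(seq))]:
        fragments.append(
            DigestFragment(
                top=seq[prev_top:top],
                left_overhang=seq[prev_top:prev_bottom],
                right_overhang=seq[top:bottom],
            )
        )
        prev_top, prev_bottom = top, bottom
    return fragments


def ligate(a: DigestFragment, b: DigestFragment) -> DigestFragment:
    """Join two fragments whose facing overhangs are complementary.

    ``a``'s right (bottom-strand) overhang must reverse-complement ``b``'s left
    (top-strand) overhang; in top-strand projection the two are equal.  Blunt
    ends also ligate.  The join is seamless: digest followed by ligate of the
    two pieces reconstructs the original sequence.
    """
    if a.right_overhang != b.left_overhang:
        raise LigationError(
            "incompatible overhangs: left fragment exposes "
            f"5'-{a.right_overhang_strand or '(blunt)'}-3' (bottom strand), right fragment exposes "
            f"5'-{b.left_overhang_strand or '(blunt)'}-3' (top strand)"
        )
    return DigestFragment(
        top=a.top + b.top,
        left_overhang=a.left_overhang,
        right_overhang=b.right_overhang,
    )


def translate(dna: str, strip_stop: bool = True, allow_internal_stop: bool = False) -> str:
    """Standard-code translation of an in-frame coding sequence."""
    dna = dna.upper()
    if len(dna) % 3:
        raise ValueError(f"sequence length {len(dna)} is not divisible by 3")
    protein = str(Seq(dna).translate())
    core, trailing = (protein[:-1], True) if protein.endswith("*") else (protein, False)
    if "*" in core and not allow_internal_stop:
        raise ValueError(f"internal stop codon at protein position {core.index('*')}")
    if trailing and not strip_stop:
        return protein
    return core


# -- FX cloning ---------------------------------------------------------------

# Non-annealing heads of the published FX flanking primers; appending them to
# any insert reproduces the BspQI geometry that releases AGT/GCA sticky ends.
FX_TAIL_5 = "ATATGCTCTTCTAGT"
FX_TAIL_3 = "GCATGAAGAGCTATA"


def fx_wrap(insert: str) -> str:
    """Flank an insert with the FX-cloning BspQI tails (AGT/GCA design)."""
    return FX_TAIL_5 + insert.upper() + FX_TAIL_3


def fx_overhang_check(insert: str) -> tuple[str, str]:
    """Return the two 3-base overhangs a BspQI digest releases from an FX insert.

    The insert must carry one top-strand and one downstream bottom-strand
    GCTCTTC site; a conforming sybody insert yields ('AGT', 'GCA').
    """
    enzyme = ENZYMES["BspQI"]
    seq = insert.upper()
    motif, rc_motif = enzyme.recognition, reverse_complement(enzyme.recognition)
    top_sites = [i for i in range(len(seq)) if seq.startswith(motif, i)]
    bottom_sites = [i for i in range(len(seq)) if seq.startswith(rc_motif, i)]
    if len(top_sites) != 1 or len(bottom_sites) != 1:
        raise AssemblyError(
            f"FX insert needs exactly one {enzyme.name} site per strand; "
            f"found {len(top_sites)} top / {len(bottom_sites)} bottom"
        )
    if top_sites[0] >= bottom_sites[0]:
        raise AssemblyError("FX sites must face each other (top-strand site upstream)")
    fragments = digest(seq, enzyme)
    if len(fragments) != 3:
        raise AssemblyError(f"expected 3 fragments from FX digestion, got {len(fragments)}")
    middle = fragments[1]
    return middle.left_overhang, middle.right_overhang


# -- in-silico PCR / overlap extension ---------------------------------------


def _longest_overlap(left: str, right: str, min_overlap: int) -> int:
    limit = min(len(left), len(right))
    for k in range(limit, min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def overlap_merge(pieces: Sequence[str], min_overlap: int = 12) -> str:
    """Merge single strands by maximal exact 3' / 5' overlaps (overlap-extension PCR)."""
    if not pieces:
        raise ValueError("nothing to merge")
    merged = pieces[0].upper()
    for piece in pieces[1:]:
        piece = piece.upper()
        k = _longest_overlap(merged, piece, min_overlap)
        if not k:
            raise AssemblyError(
                f"no overlap of >= {min_overlap} bases between ...{merged[-20:]} and {piece[:20]}..."
            )
        merged += piece[k:]
    return merged


def pcr_product(template: str, fwd: str, rev: str, min_anneal: int = 12) -> str:
    """Product of a primer pair on a linear template; primers may carry 5' tails.

    The forward primer anneals by its longest 3' suffix found on the top
    strand; the reverse primer by its longest 3' suffix found on the bottom
    strand.  The product is fwd + intervening template + reverse complement of
    rev.
    """
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()

    fwd_len, fwd_pos = 0, -1
    for k in range(len(fwd), min_anneal - 1, -1):
        pos = template.find(fwd[-k:])
        if pos != -1:
            fwd_len, fwd_pos = k, pos
            break
    rcr = reverse_complement(rev)
    rev_len, rev_pos = 0, -1
    for k in range(len(rcr), min_anneal - 1, -1):
        pos = template.find(rcr[:k])
        if pos != -1:
            rev_len, rev_pos = k, pos
            break
    if fwd_len < min_anneal or rev_len < min_anneal:
        raise AssemblyError("primer does not anneal to the template")
    if rev_pos + rev_len < fwd_pos + fwd_len:
        raise AssemblyError("reverse primer anneals upstream of the forward primer")
    return fwd + template[fwd_pos + fwd_len : rev_pos] + rcr


# -- library assembly ---------------------------------------------------------

_DEFAULT_SCAFFOLD_CODON = {"mix1": "AGC", "mix2": "ACC", "mix3": "ACC"}  # Ser / Thr


def _realize_randomized_primer(primer_name: str, codons: Sequence[str] | None) -> str:
    """Substitute codons into a randomized primer's placeholder slots.

    With ``codons=None`` the non-randomized scaffold realization is used: the
    published scaffold codons where the primer region is part of the published
    concave framework, otherwise serine/threonine codons (the scaffold sybodies
    carry Ser/Thr at positions to be randomized).
    """
    slots = parse_randomized_primer(seqdata.LIBRARY_PRIMERS[primer_name])
    n_rand = sum(1 for s in slots if s.is_randomized)
    if codons is None:
        codons = _scaffold_codons(primer_name, slots)
    if len(codons) != n_rand:
        raise AssemblyError(f"{primer_name} needs {n_rand} codons, got {len(codons)}")
    out: list[str] = []
    it = iter(codons)
    for slot in slots:
        out.append(next(it) if slot.is_randomized else slot.bases)
    return "".join(out)


def _scaffold_codons(primer_name: str, slots: Sequence[CodonSlot]) -> list[str]:
    from .library import embed_in_scaffold

    if primer_name in ("CDR1_a_b", "CDR2_a_b", "CDR3_a"):
        w = embed_in_scaffold(slots, seqdata.CONCAVE_FRAMEWORK_DNA)
        return [seqdata.CONCAVE_FRAMEWORK_DNA[s : s + 3] for s in w.slot_starts]
    return [_DEFAULT_SCAFFOLD_CODON[s.mix.name] for s in slots if s.is_randomized]


def cdr_fragment(library: str, cdr: str, codons: Sequence[str] | None = None) -> str:
    """Assembly-PCR product (top strand) of one CDR fragment of a library.

    ``codons`` realizes the randomized slots; ``None`` gives the non-randomized
    scaffold fragment.
    """
    try:
        plan = seqdata.ASSEMBLY_PLAN[library][cdr]
    except KeyError as exc:
        raise AssemblyError(f"no assembly plan for {library}/{cdr}") from exc
    pieces: list[str] = []
    for kind, ref in plan:
        if kind == "megaprimer":
            fwd, rev = ref
            pieces.append(
                pcr_product(
                    seqdata.CONCAVE_FRAMEWORK_DNA,
                    seqdata.LIBRARY_PRIMERS[fwd].replace(" ", ""),
                    seqdata.LIBRARY_PRIMERS[rev].replace(" ", ""),
                )
            )
        elif kind == "primer":
            pieces.append(seqdata.LIBRARY_PRIMERS[ref].replace(" ", ""))
        elif kind == "primer_rc":
            pieces.append(reverse_complement(seqdata.LIBRARY_PRIMERS[ref].replace(" ", "")))
        elif kind == "randomized":
            pieces.append(_realize_randomized_primer(ref, codons))
        else:  # pragma: no cover - plan is static
            raise AssemblyError(f"unknown piece kind {kind!r}")
    return overlap_merge(pieces)


@dataclass(frozen=True)
class AssemblyReport:
    dna: str
    protein: str
    frame: int
    length: int
    in_frame: bool
    internal_stop: bool
    stage: str = "complete"


def _retained_fragment(fragments: Sequence[DigestFragment], enzyme: RestrictionEnzyme, stage: str) -> DigestFragment:
    """The payload fragment of a Golden-Gate digest: longest piece free of the motif."""
    motif, rc = enzyme.recognition, reverse_complement(enzyme.recognition)
    site_free = [f for f in fragments if motif not in f.top and rc not in f.top]
    if not site_free:
        raise AssemblyError(f"{stage}: digestion left no site-free payload fragment")
    return max(site_free, key=lambda f: len(f.top))


def assemble_fragments(
    cdr1: str,
    cdr2: str,
    cdr3: str,
    enzymes: tuple[str, str] = ("BsaI", "BpiI"),
) -> AssemblyReport:
    """Two-step Golden-Gate assembly of the three CDR fragments.

    CDR1 is digested with the first enzyme and CDR2 with the second; their
    4-base overhangs ligate.  The CDR1-CDR2 product is digested with the first
    enzyme and ligated to the second-enzyme digest of CDR3.  The result is
    validated as a single uninterrupted open reading frame.
    """
    enz1, enz2 = (ENZYMES[e] if isinstance(e, str) else e for e in enzymes)
    try:
        f1 = _retained_fragment(digest(cdr1, enz1), enz1, "CDR1 digestion")
        f2 = _retained_fragment(digest(cdr2, enz2), enz2, "CDR2 digestion")
        pair = ligate(f1, f2)
    except (DigestError, LigationError) as exc:
        raise AssemblyError(f"CDR1+CDR2 stage: {exc}") from exc
    try:
        f12 = _retained_fragment(digest(pair.top, enz1), enz1, "CDR1-CDR2 re-digestion")
        f3 = _retained_fragment(digest(cdr3, enz2), enz2, "CDR3 digestion")
        final = ligate(f12, f3)
    except (DigestError, LigationError) as exc:
        raise AssemblyError(f"CDR3 stage: {exc}") from exc

    dna = final.top
    in_frame = len(dna) % 3 == 0
    if not in_frame:
        raise AssemblyError(f"final stage: assembled length {len(dna)} breaks the reading frame")
    protein = str(Seq(dna).translate())
    internal_stop = "*" in protein.rstrip("*")
    if internal_stop:
        raise AssemblyError(
            f"final stage: internal stop codon at protein position {protein.index('*')}"
        )
    return AssemblyReport(
        dna=dna,
        protein=protein.rstrip("*"),
        frame=0,
        length=len(dna),
        in_frame=in_frame,
        internal_stop=internal_stop,
    )


def assemble_member(
    library: str,
    codons: Mapping[str, Sequence[str]] | None = None,
    seed: int | None = None,
) -> AssemblyReport:
    """Assemble one full-length member of the concave or loop library.

    ``codons`` maps CDR1/CDR2/CDR3 to realized codon lists; alternatively a
    ``seed`` samples codons from the trinucleotide mixes.  With neither, the
    non-randomized scaffold sybody is assembled.  The convex library cannot be
    fully assembled because its scaffold (megaprimers 4 and 5) is not
    published.
    """
    if library not in seqdata.ASSEMBLY_PLAN:
        raise AssemblyError(f"unknown library {library!r}")
    if library == "convex":
        raise AssemblyError(
            "full convex assembly is unsupported: the convex scaffold megaprimers are not published"
        )
    if codons is None and seed is not None:
        codons = _sample_codons(library, seed)
    frags = {
        cdr: cdr_fragment(library, cdr, codons.get(cdr) if codons else None)
        for cdr in ("CDR1", "CDR2", "CDR3")
    }
    return assemble_fragments(frags["CDR1"], frags["CDR2"], frags["CDR3"])


def _sample_codons(library: str, seed: int) -> dict[str, list[str]]:
    rng = np.random.default_rng(seed)
    table = seqdata.ECOLI_PREFERRED_CODONS
    out: dict[str, list[str]] = {}
    for i, primer in enumerate(seqdata.LIBRARY_CDR_PRIMERS[library]):
        slots = parse_randomized_primer(seqdata.LIBRARY_PRIMERS[primer])
        codons = []
        for slot in slots:
            if slot.is_randomized:
                support = slot.mix.support
                probs = np.array([slot.mix.probability(aa) for aa in support])
                codons.append(table[str(rng.choice(list(support), p=probs / probs.sum()))])
        out[f"CDR{i + 1}"] = codons
    return out


@lru_cache(maxsize=None)
def assembled_scaffold(library: str) -> str:
    """Full-length non-randomized scaffold DNA produced by the assembly pipeline.

    For the loop library this is a synthetic reconstruction: the CDR3 cassette's
    randomized positions are filled with serine codons because the published
    table prints only the concave scaffold sequence.
    """
    return assemble_member(library).dna
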