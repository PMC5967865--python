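import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import brute_force_diversity
from sybodykit import library
from sybodykit._sequences import CONCAVE_FRAMEWORK_DNA, LIBRARY_PRIMERS
from sybodykit.library import (
    CodonSlot,
    PrimerParseError,
    RandomizationScheme,
    parse_randomized_primer,
)
from sybodykit.mixes import mix_definition


# -- primer parsing -------------------------------------------------------------


def test_parse_cdr1_primer_slots():
    slots = parse_randomized_primer(LIBRARY_PRIMERS["CDR1_a_b"])
    mixes = [s.mix.name for s in slots if s.is_randomized]
    assert mixes == ["mix1", "mix1", "mix1", "mix2", "mix3"]


def test_parse_cdr3_c_has_ten_randomized_slots():
    slots = parse_randomized_primer(LIBRARY_PRIMERS["CDR3_c"])
    counts = {}
    for s in slots:
        if s.is_randomized:
            counts[s.mix.name] = counts.get(s.mix.name, 0) + 1
    assert counts == {"mix1": 9, "mix2": 1}


def test_parse_plain_primer_is_all_fixed():
    slots = parse_randomized_primer(LIBRARY_PRIMERS["FW1_a_b_for"])
    assert all(not s.is_randomized for s in slots)
    assert "".join(s.bases for s in slots) == "CAGGTTCAGCTGGTTGAGAGC"


def test_parse_rejects_non_dna_token():
    with pytest.raises(PrimerParseError, match="XYZ"):
        parse_randomized_primer("GCA XYZ 111")


def test_parse_frame_offset_makes_partial_slot():
    slots = parse_randomized_primer("GCAT 111", frame=1)
    assert slots[0].bases == "G"
    assert slots[1].bases == "CAT"
    assert slots[2].is_randomized


# -- theoretical diversity ------------------------------------------------------


def _toy_scheme(mix_names):
    slots = [CodonSlot("randomized", mix=mix_definition(m)) for m in mix_names]
    return RandomizationScheme(library_name="toy", cdr_slots={"CDR1": slots})


@pytest.mark.parametrize(
    "mix_names",
    [[], ["mix1"], ["mix2", "mix3"], ["mix1", "mix2", "mix3"], ["mix3"] * 4],
)
def test_theoretical_diversity_matches_brute_force(mix_names):
    scheme = _toy_scheme(mix_names)
    slots = list(scheme.cdr_slots["CDR1"])
    assert library.theoretical_diversity(scheme) == brute_force_diversity(slots)


def test_diversity_of_empty_scheme_is_one():
    assert library.theoretical_diversity(_toy_scheme([])) == 1


def test_library_randomized_counts():
    assert library.scheme_for("concave").n_randomized == 15
    assert library.scheme_for("loop").n_randomized == 16
    assert library.scheme_for("convex").n_randomized == 18


def test_loop_diversity_exact_product():
    scheme = library.scheme_for("loop")
    assert scheme.mix_counts() == {"mix1": 12, "mix2": 2, "mix3": 2}
    assert library.theoretical_diversity(scheme) == 18**12 * 16**2 * 12**2


def test_rounded_diversity_and_format():
    assert library.rounded_diversity(831979165027663872) == 8.3e17
    assert library.format_diversity(831979165027663872) == "8.3e+17"
    assert library.rounded_diversity(999) == 1.0e3
    with pytest.raises(ValueError):
        library.format_diversity(0)


# -- scaffold embedding ---------------------------------------------------------


def test_concave_windows_cover_scaffold_uniquely():
    scheme = library.scheme_for("concave")
    assert scheme.scaffold == CONCAVE_FRAMEWORK_DNA
    windows = sorted(
        (library.embed_in_scaffold(s, scheme.scaffold) for s in scheme.cdr_slots.values()),
        key=lambda w: w.start,
    )
    assert len(windows) == 3
    for a, b in zip(windows, windows[1:]):
        assert a.end <= b.start  # non-overlapping, ordered


def test_randomized_protein_positions_in_range():
    scheme = library.scheme_for("concave")
    positions = library.randomized_protein_positions(scheme)
    assert len(positions) == 15
    assert all(0 <= p < len(CONCAVE_FRAMEWORK_DNA) // 3 for p in positions)


def test_loop_scheme_uses_synthetic_scaffold():
    scheme = library.scheme_for("loop")
    assert scheme.scaffold_synthetic
    assert scheme.scaffold is not None and len(scheme.scaffold) % 3 == 0


# -- sampling -------------------------------------------------------------------


def test_sampling_is_deterministic_per_seed():
    scheme = library.scheme_for("concave")
    a = library.sample_library(scheme, n=5, seed=7)
    b = library.sample_library(scheme, n=5, seed=7)
    c = library.sample_library(scheme, n=5, seed=8)
    assert [m.dna for m in a] == [m.dna for m in b]
    assert [m.dna for m in a] != [m.dna for m in c]


def test_sampling_zero_and_negative():
    scheme = library.scheme_for("concave")
    assert library.sample_library(scheme, n=0, seed=0) == []
    with pytest.raises(ValueError):
        library.sample_library(scheme, n=-1, seed=0)


def test_sampled_members_have_framework_outside_windows():
    scheme = library.scheme_for("concave")
    windows = sorted(
        (library.embed_in_scaffold(s, scheme.scaffold) for s in scheme.cdr_slots.values()),
        key=lambda w: w.start,
    )
    member = library.sample_library(scheme, n=1, seed=3)[0]
    assert len(member.dna) == len(CONCAVE_FRAMEWORK_DNA)
    cursor = 0
    for w in windows:
        assert member.dna[cursor : w.start] == CONCAVE_FRAMEWORK_DNA[cursor : w.start]
        cursor = w.end
    assert member.dna[cursor:] == CONCAVE_FRAMEWORK_DNA[cursor:]


def test_no_cysteine_or_proline_at_randomized_positions():
    scheme = library.scheme_for("concave")
    positions = library.randomized_protein_positions(scheme)
    for member in library.sample_library(scheme, n=200, seed=11):
        residues = {member.protein[p] for p in positions}
        assert "C" not in residues
        assert "P" not in residues
        assert "*" not in member.protein


def test_sampled_frequencies_match_mix_chisquare():
    # pooled counts at the mix1 positions of CDR3 against mix1 probabilities
    scheme = library.scheme_for("concave")
    members = library.sample_library(scheme, n=20000, seed=5)
    freqs = library.empirical_frequencies(members, scheme)
    mix1 = mix_definition("mix1")
    mix_by_pos = {}
    for slots in scheme.cdr_slots.values():
        w = library.embed_in_scaffold(slots, scheme.scaffold)
        rand = [s for s in w.slots if s.is_randomized]
        for start, slot in zip(w.slot_starts, rand):
            mix_by_pos[start // 3] = slot.mix.name
    counts = {aa: 0.0 for aa in mix1.support}
    n_pos = 0
    for p, observed in freqs.items():
        if mix_by_pos[p] != "mix1":
            continue
        n_pos += 1
        for aa, f in observed.items():
            counts[aa] += f * len(members)
    assert n_pos == 7  # concave carries seven mix1 positions
    total = sum(counts.values())
    expected = np.array([mix1.probability(aa) * total for aa in mix1.support])
    observed_arr = np.array([counts[aa] for aa in mix1.support])
    stat, p_value = chisquare(observed_arr, expected)
    assert p_value > 0.01


def test_convex_scheme_has_no_scaffold_but_samples_cassettes():
    scheme = library.scheme_for("convex")
    assert scheme.scaffold is None
    member = library.sample_library(scheme, n=1, seed=1)[0]
    assert set(member.dna) <= set("ACGT")


def test_unknown_library_errors():
    with pytest.raises(ValueError):
        library.scheme_for("flat")
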