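"""Design the three sybody libraries and inspect their theoretical diversity.

Each library randomizes its CDRs with trinucleotide mixes that exclude
cysteine and proline; the theoretical diversity is the product of the number
of amino acids each randomized codon can encode.
"""

from sybodykit import library

for name in ("concave", "loop", "convex"):
    scheme = library.scheme_for(name)
    exact = library.theoretical_diversity(scheme)
    print(f"{name:8s}: {scheme.n_randomized} randomized positions "
          f"{scheme.mix_counts()} -> {library.format_diversity(exact)} sequences")

# Sample a few concave members; the scaffold is untouched outside the CDRs
# and the sampled CDR residues never include C or P.
scheme = library.scheme_for("concave")
members = library.sample_library(scheme, n=3, seed=1)
positions = library.randomized_protein_positions(scheme)
for m in members:
    cdr_residues = "".join(m.protein[p] for p in positions)
    print(f"{m.name}: randomized residues {cdr_residues}")
print("Every member keeps the invariant framework; only the CDR windows vary.")
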