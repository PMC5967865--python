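"""Published sequence constants: library primers, the concave scaffold and codon usage.

Primer strings keep the whitespace layout of the published primer table; the
placeholder triplets 111/222/333 mark codons synthesized from trinucleotide
mixes 1-3.
"""

# Non-randomized concave scaffold sybody (coding strand, one ORF, no stop).
CONCAVE_FRAMEWORK_DNA = (
    "CAGGTTCAGCTGGTTGAGAGCGGTGGTGGCCTGGTCCAAGCTGGCGGTTCGCTGCGTCTGAGCTGCGCCGCAAGCGGTTT"
    "CCCGGTGAGCAGCAGCACGATGACCTGGTATCGTCAGGCACCGGGCAAAGAACGTGAGTGGGTCGCGGCGATTTCCAGCT"
    "CTGGTAGCACCACGACCTACGCAGATTCTGTTAAGGGCCGCTTTACCATCAGCCGCGACAACGCGAAGAATACGGTCTAT"
    "TTGCAGATGAATAGCCTGAAACCGGAAGATACCGCGGTTTACTACTGTACCGTGACCGTGGGTAGCACGTACACGGGCCA"
    "AGGTACCCAAGTGACTGTGAGC"
)

# Library assembly primers (5'->3').  Randomized CDR primers carry the
# 111/222/333 mix placeholders.
LIBRARY_PRIMERS = {
    "CDR1_a_b": "GCA AGC GGT TTC CCG GTG 111 111 111 222 ATG 333 TGG TAT CGT CAG GCA CCG G",
    "CDR1_c": "C TGT GCG GCT AGC GGC 111 ATT 111 111 ATC 222 TAC CTG GGC TGG TTT CGC C",
    "CDR2_a_b": "GA AGA CCT GTC GCG GCG ATT 111 AGC 111 GGT 111 222 ACG 333 TAC GCA GAT TCT GTT AAG GGC CG",
    "CDR2_c": "CGA AGA CCT GCA GCG CTG 111 ACC 111 111 GGT 222 ACC TAC TAC GCG GAC AGC G",
    "CDR3_a": "GA AGA CCT GCG GTT TAC TAC TGT 333 GTG 222 GTG GGT 111 222 TAC 333 GGC CAA GGT ACC CAA GTG AC",
    "CDR3_b": "CGC GAA GAC CTC GTG AAA GAC 111 GGT 111 111 111 111 111 TAC GAC TAT TGG GGC CAA GGT ACC CAA GTG AC",
    "CDR3_c": "GAA GAC CTC TGC GCG GCA GCC 111 111 GGC 111 111 111 CCG CTG 111 111 111 111 TAT 222 TAC TGG GGT CAG GGC ACC CAA GTT ACC GTT TCT",
    "FW1_a_b_for": "CAG GTT CAG CTG GTT GAG AGC",
    "FW1_a_b_rev": "CAC CGG GAA ACC GCT TGC",
    "FW1_c_for": "CAA GTC CAG CTG GTG GAA TCG",
    "FW1_c_rev": "GCC GCT AGC CGC ACA G",
    "FW2_a_b_rev": "ATG CAT GGT CTC ACG ACC CAC TCA CGT TCT TTG CCC GGT GCC TGA CGA TAC CA",
    "FW2_c_rev": "ATG CAT GGT CTC ACT GCG ACG CCC TCA CGC TCT TTG CCC GGT GCC TGG CGA AAC CAG CCC AGG",
    "FW3_a_b_for": "CGC AGA TTC TGT TAA GGG CCG",
    "FW3_c_for": "ACC TAC TAC GCG GAC AGC G",
    "FW4_a_b_rev": "GCT CAC AGT CAC TTG GGT ACC TTG GCC",
    "FW4_c_rev": "AGA AAC GGT AAC TTG GGT GCC CTG",
    "Link1_a_b_for": "ATG CAT GAA GAC CTG TCG CGG CG",
    "Link1_a_b_rev": "ATG CAT GGT CTC ACG ACC",
    "Link1_c_for": "TAT ATC GAA GAC CTG CAG CGC TG",
    "Link1_c_rev": "ATG CAT GGT CTC ACT GCG ACG",
    "Link2_a_for": "TAT ATC GAA GAC CTG CGG TTT ACT ACT G",
    "Link2_a_rev": "ATG CAT GGT CTC ACC GCG GTA TCT TCC GGT TTC",
    "Link2_b_rev": "ATG CAT GGT CTC ACA CGT TAC AGT AGT AAA CCG CGG",
    "Link2_c_for": "ATA TAT GAA GAC CTC TGC GCG GC",
    "Link2_c_rev": "ATG CAT GGT CTC AGC AGT AAT ACA AAG CAG TAT CTT CCG G",
}

# FX-cloning flanking primers for the medium (concave/loop) and long (convex)
# sybody formats; BspQI digestion of their PCR product yields the AGT / GCA
# sticky ends used for PCR-free subcloning.
FX_PRIMERS = {
    "Med_FX_for": "ATA TGC TCT TCT AGT CAG GTT CAG CTG GTT GAG AGC G",
    "Med_FX_rev": "TAT AGC TCT TCA TGC GCT CAC AGT CAC TTG GGT ACC",
    "Long_FX_for": "ATA TGC TCT TCT AGT CAA GTC CAG CTG GTG GAA TCG",
    "Long_FX_rev": "TAT AGC TCT TCA TGC AGA AAC GGT AAC TTG GGT GCC C",
}

# Ordered single-strand pieces whose overlap-extension merge yields each CDR
# assembly-PCR product.  Piece kinds: "primer" (top strand as printed),
# "primer_rc" (reverse complement of a printed reverse primer),
# "megaprimer" (PCR product of the concave/loop scaffold with a primer pair),
# "randomized" (the realized randomized primer).
ASSEMBLY_PLAN = {
    "concave": {
        "CDR1": [
            ("megaprimer", ("FW1_a_b_for", "FW1_a_b_rev")),
            ("randomized", "CDR1_a_b"),
            ("primer_rc", "FW2_a_b_rev"),
        ],
        "CDR2": [
            ("primer", "Link1_a_b_for"),
            ("randomized", "CDR2_a_b"),
            ("megaprimer", ("FW3_a_b_for", "Link2_a_rev")),
        ],
        "CDR3": [
            ("primer", "Link2_a_for"),
            ("randomized", "CDR3_a"),
            ("primer_rc", "FW4_a_b_rev"),
        ],
    },
    "loop": {
        "CDR1": [
            ("megaprimer", ("FW1_a_b_for", "FW1_a_b_rev")),
            ("randomized", "CDR1_a_b"),
            ("primer_rc", "FW2_a_b_rev"),
        ],
        "CDR2": [
            ("primer", "Link1_a_b_for"),
            ("randomized", "CDR2_a_b"),
            ("megaprimer", ("FW3_a_b_for", "Link2_b_rev")),
        ],
        # The published forward assembly primer entry for the loop CDR3 is
        # corrupt in the source table; the CDR3_b primer itself carries the
        # 5' BpiI handle, so no further extension is needed.
        "CDR3": [
            ("randomized", "CDR3_b"),
            ("primer_rc", "FW4_a_b_rev"),
        ],
    },
    # Megaprimers 4/5 derive from the unpublished convex scaffold; only the
    # primer-covered parts of the convex fragments can be reconstructed.
    "convex": {
        "CDR1": [
            ("randomized", "CDR1_c"),
            ("primer_rc", "FW2_c_rev"),
        ],
        "CDR2": [
            ("primer", "Link1_c_for"),
            ("randomized", "CDR2_c"),
        ],
        "CDR3": [
            ("primer", "Link2_c_for"),
            ("randomized", "CDR3_c"),
            ("primer_rc", "FW4_c_rev"),
        ],
    },
}

# CDR primers per library, in CDR order.
LIBRARY_CDR_PRIMERS = {
    "concave": ("CDR1_a_b", "CDR2_a_b", "CDR3_a"),
    "loop": ("CDR1_a_b", "CDR2_a_b", "CDR3_b"),
    "convex": ("CDR1_c", "CDR2_c", "CDR3_c"),
}

# One codon per amino acid for realizing sampled library DNA, mirroring the
# one-codon-per-residue chemistry of trimer phosphoramidites.  Most frequent
# E. coli K-12 codon per residue; override via sample_library(codon_table=...).
ECOLI_PREFERRED_CODONS = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAG", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}
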