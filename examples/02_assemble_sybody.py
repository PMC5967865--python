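"""Simulate the two-step Golden-Gate assembly of a sybody gene.

Three CDR fragments are produced by assembly PCR, digested with Type IIS
enzymes (BsaI / BpiI) and ligated via their programmed 4-base overhangs; the
product is validated as a single open reading frame.  FX-cloning tails then
provide the AGT/GCA overhangs used for subcloning.
"""

from sybodykit import assembly

# Non-randomized control: the fragments reassemble the published scaffold.
scaffold = assembly.assemble_member("concave")
print(f"scaffold assembly: {scaffold.length} nt, in frame: {scaffold.in_frame}, "
      f"protein starts {scaffold.protein[:12]}...")

# A randomized member sampled from the trinucleotide mixes.
member = assembly.assemble_member("loop", seed=7)
print(f"randomized loop member: {member.length} nt, internal stop: {member.internal_stop}")
print(f"protein: {member.protein}")

# FX wrapping releases the designed sticky ends on BspQI digestion.
overhangs = assembly.fx_overhang_check(assembly.fx_wrap(member.dna))
print(f"FX overhangs: {overhangs} (AGT/GCA by design)")
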