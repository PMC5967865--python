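"""Monitor a selection campaign: qPCR enrichment and the diversity cascade.

Eluted polynucleotide copies are quantified against a standard curve;
enrichment is the fold excess of target over background elution.  The
expected number of distinct binders surviving each selection step follows
from the distinct-count formula for sampling with replacement.
"""

from sybodykit import selection, simulate

# Synthetic round-1 elution data at a known 170-fold enrichment.
ds = simulate.generate(simulate.ScenarioConfig("qpcr_selection", seed=3, params={"fold": 170}))
curve = selection.StandardCurve(slope=ds.truth["slope"], intercept=ds.truth["intercept"])
print(f"standard curve efficiency: {curve.efficiency:.1%}")

results = {r.sample_id: r for r in selection.quantify(ds.data["qpcr"], curve)}
fold = selection.enrichment_fold(
    results["target"].copies, results["background"].copies,
    results["target"].copies_sd, results["background"].copies_sd,
)
print(f"enrichment: {fold.fold:.0f} +/- {fold.fold_sd:.0f} fold "
      f"(truth {ds.truth['fold']:.0f}); noise comes from 0.15-cycle Ct scatter")

# Diversity bottleneck: display samples ~1e12 molecules from ~1e18 sequences.
cascade = selection.cascade_diversity(selection.CascadeParams())
for stage in cascade.stages:
    print(f"  {stage.name:14s} draws {stage.draws:9.2e} -> {stage.diversity:9.2e} distinct")
print(f"bottleneck stage: {cascade.bottleneck}")
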