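# sybodykit

Design, assembly simulation and selection analytics for synthetic
single-domain antibody (sybody) libraries.

Sybodies are nanobody-scaffold binders whose complementarity determining
regions (CDR1–3) are randomized at the codon level with trinucleotide
(trimer phosphoramidite) mixes, selected in vitro by ribosome and phage
display, and characterized by SPR kinetics, competition binding, enzyme
inhibition and thermal-shift assays.  This package implements the desk-scale
quantitative core of such a platform:

- **Library design** (`sybodykit.library`, `sybodykit.mixes`) — parse
  randomized CDR primers (placeholder codons `111`/`222`/`333` mark
  trinucleotide mixes 1–3), embed them in the scaffold, compute theoretical
  diversities and sample library members.  The mixes encode 18, 16 and 12
  amino acids respectively and exclude cysteine and proline.
- **Assembly simulation** (`sybodykit.assembly`) — overlap-extension assembly
  PCR, Type IIS digestion (BsaI `GGTCTC(1/5)`, BpiI `GAAGAC(2/6)`,
  BspQI/SapI `GCTCTTC(1/4)`), sticky-end ligation, two-step Golden-Gate
  assembly of the three CDR fragments, reading-frame validation, and
  FX-cloning overhang checks (`AGT`/`GCA`).
- **Selection analytics** (`sybodykit.selection`) — absolute qPCR
  quantification via standard curves `Ct = intercept + slope·log10(copies)`
  with efficiency `E = 10^(−1/slope) − 1`, enrichment folds with error
  propagation, and diversity propagation through the selection cascade using
  the distinct-count formula `E[unique] = D·(1 − (1 − 1/D)^n)`.
- **Binding models** (`sybodykit.binding`) — global 1:1 Langmuir kinetics
  (`KD = koff/kon`), Schild-type competition `y = (x/B + 1)/(αx/B + 1)`
  saturating at `1/α`, hyperbolic inhibition `y = y0 + a·IC50/(IC50 + x)`,
  and Boltzmann melt curves
  `S(T) = bottom + (top − bottom)/(1 + exp((Tm − T)/slope))`, all fit with
  [lmfit](https://lmfit.github.io/lmfit-py/).
- **Synthetic data** (`sybodykit.simulate`) — seeded scenario generators
  (library FASTA, qPCR dilution/selection, ELISA plates, sensorgrams,
  competition, inhibition, melts) with ground-truth sidecars for
  parameter-recovery testing.
- **CLI** (`sybody`) — thin wrappers: `design`, `assemble`, `enrich`,
  `cascade`, `elisa`, `fit-spr`, `fit-schild`, `fit-ic50`, `fit-melt`,
  `simulate`.

## Worked example

```python
from sybodykit import library

for name in ("concave", "loop", "convex"):
    scheme = library.scheme_for(name)
    exact = library.theoretical_diversity(scheme)
    print(name, scheme.n_randomized, library.format_diversity(exact))
```

prints

```
concave 15 8.3e+17
loop 16 4.3e+19
convex 18 2.8e+22
```

and on the command line:

```
$ sybody design --library concave --n 10 --seed 1 --out lib.fasta
{
  "library": "concave",
  "n_written": 10,
  "randomized_positions": 15,
  "theoretical_diversity": 8.3e+17
}
```

The scripts in `examples/` walk through each capability end to end:
library design, Golden-Gate assembly, selection enrichment and the four
binding-model fits, each printing computed numbers with one-line
interpretations.

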