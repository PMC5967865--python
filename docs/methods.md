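# Methods

This note records the models implemented in `sybodykit`, the assumptions
behind them, default parameter values with their rationale, and what the
synthetic-data generator does and does not emulate.

## Library design

### Trinucleotide mixes

Randomized CDR codons are synthesized from trinucleotide (trimer
phosphoramidite) mixes, i.e. whole-codon building blocks, so no stop codons
and no frame shifts occur at randomized positions.  Mix 1 is fully specified:
A, S, T, N, Y at 10.6% each; D, E, Q, R, K, H, W at 5% each; F, M, V, I, L, G
at 2% each (sums to 1 exactly).  Cysteine and proline are excluded from every
mix.  Mix 2 removes D and A (16 amino acids), mix 3 removes D, N, Q, G, S and
M (12 amino acids).  Only the exclusions are published for mixes 2 and 3, so
the removed probability mass must be redistributed; `mix_definition` supports
`"proportional"` (default: scale surviving frequencies — the natural model of
leaving ingredients out of a mixture) and `"uniform"` (equal share to each
survivor).  The *support* (which amino acids are possible) is identical under
both, so diversity computations are unaffected by this choice.

### Primer parsing and diversity

CDR primers carry placeholder triplets `111`, `222`, `333` marking mix-1/2/3
codons.  `parse_randomized_primer` tokenizes the whitespace-delimited primer
into fixed codon slots and randomized slots; fixed runs are re-split into
triplets in the declared reading frame, with 1–2 base partial slots allowed at
primer boundaries.

The theoretical diversity is the exact integer product of the per-slot support
sizes over all randomized slots; per library:

- concave: 7×mix1 + 4×mix2 + 4×mix3 → 18⁷·16⁴·12⁴ ≈ 8.3 × 10¹⁷
- loop: 12×mix1 + 2×mix2 + 2×mix3 → 18¹²·16²·12² ≈ 4.3 × 10¹⁹
- convex: 15×mix1 + 3×mix2 → 18¹⁵·16³ ≈ 2.8 × 10²²

This counts amino-acid sequences (one codon per residue, mirroring the
chemistry).  `rounded_diversity` rounds through decimal scientific notation so
the result is bit-identical to the float literal a reader would write
(e.g. exactly `8.3e17`).

### Scaffolds

Only the concave scaffold DNA (342 nt) is published.  The loop scaffold is
reconstructed by running the assembly simulation with scaffold codons where
the published record is silent (serine/threonine placeholders at CDR3
positions); the resulting scheme is flagged `scaffold_synthetic`.  The convex
scaffold cannot be reconstructed because its framework "megaprimers" are
unpublished; convex members are sampled as joined CDR cassettes only and
`assemble_member("convex")` raises.

Sampling uses `numpy.random.default_rng(seed)` and a one-codon-per-residue
table (most frequent E. coli K-12 codon per amino acid) to realize DNA.

## Assembly simulation

Fragments are modeled as a top-strand string with typed single-strand ends.
A 5′ overhang is stored as the overhang's top-coordinate projection, which
makes ligation compatibility a string equality and ligation itself a plain
concatenation — guaranteeing the digest→ligate round-trip identity exactly.

Type IIS geometries: BsaI `GGTCTC(1/5)`, BpiI `GAAGAC(2/6)`,
SapI/BspQI `GCTCTTC(1/4)`; both strands are scanned, cuts too close to an end
or overlapping cuts raise `DigestError`.

Assembly PCR is modeled as overlap-extension merging (maximal exact 3′/5′
overlaps, minimum 12 nt) of primers, their reverse complements and
scaffold "megaprimer" PCR products.  Two-step Golden-Gate assembly digests
CDR1 with BsaI and CDR2 with BpiI, ligates (GTCG junction), re-digests with
BsaI and ligates the BpiI-digested CDR3 (GCGG junction for concave, CGTG for
loop).  At each digest the retained payload is the longest fragment free of
the digesting enzyme's motif on both strands.  The final product is validated
as a single open reading frame without internal stops.

FX cloning wraps an insert in BspQI tails `ATATGCTCTTCTAGT … GCATGAAGAGCTATA`;
digestion releases the designed 3-base overhangs `AGT`/`GCA`.

One published loop assembly primer is corrupt in the source table (it
duplicates another primer and cannot anneal to its fragment); the loop CDR3
plan therefore omits that extension piece — the CDR3 primer itself already
carries the required BpiI handle.

## Selection analytics

### qPCR

Standard curve `Ct = intercept + slope·log10(copies)` with `slope < 0`;
efficiency `E = 10^(−1/slope) − 1` (−3.32 cycles/decade ↔ 100%).  Replicates
are aggregated as mean Ct then transformed (default), with the copies SD from
the delta method `sd(copies) = copies·ln10/|slope|·sd(Ct)`; a `copies_mean`
mode transforms per replicate first.  Enrichment is the ratio of target to
background copies with first-order error propagation; an undetectable
background yields a flagged lower bound against a detection floor.

### Diversity cascade

Sampling `n` molecules with replacement from a pool of `D` equiprobable
distinct members retains `E[unique] = D(1 − (1 − 1/D)^n)` distinct members,
computed stably via `expm1`/`log1p`; `estimate_diversity` inverts this with
Brent's method.  `cascade_diversity` propagates this expectation through
display → capture → recovery → phage library → infection, clamping diversity
to be non-increasing, and reports the stage with the largest fractional loss
as the bottleneck.  Defaults reflect the published platform magnitudes:
9 × 10¹² sampled molecules, 10¹² displayed complexes, ~5 × 10⁶ captured,
10⁷-member phage library, 2% infection.  This is an expectation-level model:
it ignores clonal abundance skew and selection bias within a round.

### ELISA

A well is a hit when `signal/background ≥ 3` (configurable); background wells
below 0.01 absorbance are floored to avoid ratio blow-up.

## Binding models

All fits minimize unweighted least squares with `lmfit` (trust-region
reflective with bounds); `FitResult` carries convergence, standard errors
when available, and the residual norm.  The test-suite cross-checks against
`scipy.optimize.curve_fit` as an independent optimizer.

- **1:1 Langmuir kinetics.** Association
  `R(t) = Req(1 − e^(−(kon·C + koff)t))` with `Req = Rmax·C/(C + KD)`,
  dissociation `R(t) = R(t_assoc)·e^(−koff·(t−t_assoc))`, `KD = koff/kon`.
  Fit globally across concentrations with shared kon, koff, Rmax.  Bounds:
  kon ∈ [1, 10¹²] M⁻¹s⁻¹, koff ∈ [10⁻⁸, 10³] s⁻¹.  Initialization: koff from
  the log-linear dissociation slope, Rmax/KD from the plateau isotherm.
- **Schild-type competition.** `y = (x/B + 1)/(αx/B + 1)` with competitor
  affinity `B` and allosteric constant `α ∈ (0, 1]`; `y(0) = 1` and the
  ratio saturates at `1/α`.
- **Hyperbolic inhibition.** `y = y0 + a·IC50/(IC50 + x)`; `y(0) = y0 + a`,
  midpoint at `x = IC50`, floor `y0`.
- **Boltzmann melt.** `S = bottom + (top − bottom)/(1 + exp((Tm − T)/slope))`
  with the invariant `bottom < top`; a falling melt curve therefore has
  `slope < 0`, and the fitted slope is bounded on the side implied by the
  data's gradient at the steepest point.  Flat curves are flagged
  non-converged rather than fitted.

## Synthetic data

`simulate.generate(ScenarioConfig(scenario, seed, params))` is deterministic
per seed and returns the dataset plus a ground-truth record (written as a
`truth.json` sidecar).  Default noise levels: SPR responses 1% of Rmax
(additive Gaussian), melt signals 2% of the top−bottom span, qPCR Ct
SD 0.15 cycles.  Scenario defaults sit in published regimes: qPCR efficiency
96%, enrichment fold 170, competition series 0–100 µM with B = 1.0 µM and
α = 0.017, inhibition series 0–729 nM with IC50 = 62 nM, melt gradient
30–60 °C with ΔTm = 6.1 °C.

The generator emulates idealized instruments: Gaussian noise, no baseline
drift, no mass-transport limitation in SPR, no plate edge effects, no PCR
inhibition.  It is intended for algorithm validation, not for mimicking raw
instrument exports.

## Limitations

- The loop scaffold is a synthetic reconstruction and the convex scaffold is
  unavailable (see above); assembly-level results for those libraries carry
  that caveat.
- Diversity arithmetic treats mixes as exact and positions as independent;
  real trimer coupling efficiencies and synthesis errors are not modeled.
- The cascade model is expectation-level and assumes uniform abundance.
- Wet-lab campaign outcomes (specific enrichment folds, hit counts, ΔTm of
  particular binders) depend on unreleased raw measurements; the package
  treats them as regime anchors for synthetic scenarios, not reproducible
  targets.
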