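# Methods

## Conversion-chemistry model

Both libraries are modelled at the read level. In the BS arm an
unmodified cytosine deaminates (reads T) with probability β; 5mC and 5hmC
are protected apart from failure rates ε_m, ε_h (0 by default). In the
oxBS arm 5hmC is oxidised to 5fC with probability ω and then converts
like unmodified C. The unconverted-call probabilities are

    P_C(BS)   = m(1−ε_m) + h(1−ε_h) + (1−m−h)(1−β)
    P_C(oxBS) = m(1−ε_m) + h[(1−ω)(1−ε_h) + ω(1−β)] + (1−m−h)(1−β)

Defaults β = 0.995 and ω = 0.975 sit just inside the usual QC gates
(bisulfite > 99 %, oxidation > 97 %). Two consequences worth keeping in
mind when reading output: the oxBS (mC) readout carries an upward bias of
roughly (1−m−h)(1−β) ≈ 0.5 points from bisulfite failure, and the
differenced hmC estimate is attenuated by ωβ ≈ 0.97 (15 % truth reads as
~14.6 %). `quant.corrected_levels` inverts the model exactly when β and ω
are supplied:

    h = (L_BS − L_ox) / (ωβ),   m = (L_BS − (1−β)) / β − h

clipped to the simplex with a flag. No correction is applied by default;
the raw differenced levels are the primary output.

## Estimation conventions

- Levels are count-weighted: pooled level = Σ modified / Σ total calls
  over a site group — identical to the coverage-weighted mean of site
  levels. hmC is always computed from separately pooled BS and oxBS
  readouts; per-site hmC (clamped at 0) is diagnostic only, so clamping
  never biases aggregates.
- CG sites on the two strands are kept separate (no CpG-unit collapsing);
  context is read 5'→3' on the site's own strand, with CH rolled up from
  CHG + CHH.
- Coordinates are 0-based half-open internally; cytosine-report TSVs are
  1-based on disk, matching the Bismark dialect.
- Per-site output requires ≥ 1 read in each library; pooled quantities
  have no depth floor (pooling is count-based).
- Chromosome summaries pool all autosomes together and report chrX and
  chrY separately; a female-labelled sample containing chrY records is a
  hard error (design/label mismatch). "Autosomes" is the pooled value,
  not a mean over chromosomes.
- Conversion QC: β is the T fraction at unmodified-C spike-in sites,
  per library; ω is the hmC-site T fraction in oxBS divided by that same
  library's β, so oxidation is isolated from conversion. SEs are binomial
  (delta method for the ratio). Gates (β ≥ 0.99, ω ≥ 0.97) are treated as
  per-sample minima; failing samples are flagged, or fatal in strict mode.
- mC spike-ins report protection failure descriptively; no correction.

## Region definitions

Shores span 0–2 kb and shelves 2–4 kb from each island edge ("±4 kb" is
read as the standard shores-then-shelves convention; widths are
configurable). Flanks are truncated at chromosome bounds (flagged) and at
the midpoint between neighbouring islands. Promoter bins tile TSS ± 2 kb
in 100-bp bins oriented 5'→3' along the gene; 1-kb super-bins pool the
same span for group statistics (pooled, not bin-averaged — a flag-level
alternative was considered unnecessary). CGI meta-profiles use 200-bp
edge-anchored flank bins plus one whole-body bin: variable-length island
interiors are summarised as a single value to avoid length-rescaling
artifacts. Meta-profiles pool counts within an element's bin and then
average elements unweighted; a bin with no covered sites in an element
drops that element from the mean (missing ≠ zero). Overlapping elements
are all retained; sites may contribute to several. The repeat surrogate
deliberately reports the BS-library level (mC + hmC combined, as
repeat-element pyrosequencing would) beside the genome-wide BS level to
expose the surrogate's upward bias.

## Statistics

Two-way fixed-effects ANOVA (sex × age with interaction) via OLS;
balanced designs are the default and give the classical decomposition,
unbalanced input falls back to Type II sums of squares with a warning.
Zero error variance is flagged and p left undefined. SNK post hoc runs
only for effects passing α = 0.05: means are sorted and spans tested
step-down against studentized-range critical values for the span width;
spans inside a non-significant span are not subdivided, and unequal group
sizes use the harmonic-mean n (flagged). Benjamini–Hochberg adjustment is
applied within declared endpoint families (one family per panel-like
group: CGI region classes, promoter super-bins, gene sets). Note that BH
is not idempotent as a map on p-vectors; the invariants we guarantee are
monotonicity in rank, never decreasing any p, and capping at 1.

## Assay quantitation

- qPCR efficiency: least-squares slope of Ct on log10(input quantity),
  E = 10^(−1/slope) − 1 (slope −3.3219 ⇔ E = 1). The published form of
  this relation is often garbled; this is the standard one and reproduces
  a 75 % efficiency for a per-cycle factor of 1.75 exactly on noiseless
  data. Fold changes use (1+E)^(−ΔΔCt) with ΔΔCt = ΔCt_sample − mean
  ΔCt_calibrator; analysing a b < 2 assay with E = 1 provably inflates
  ratios above 1, which the suite asserts.
- dPCR: λ = −ln(1 − positives/total); copies/µL = λ / partition volume
  (default 8.09e-4 µL, QuantStudio-3D-class chips, configurable);
  copies per µg = copies/µL × template volume × dilution factor / mass,
  assuming 1:1 RNA→cDNA carryover. Saturated chips are an error.
- ELISA: absorbance is affine in per-base modified-cytosine density;
  sample levels are interpolated on a linear standard curve (4-parameter
  fits were out of scope; plates are generated in the linear regime).
  When standards are built from material k-fold denser in CG cytosines
  than the sample genome (k = 5 for the classic synthetic standard vs a
  mammalian genome at ~1 % CG cytosines), the raw reading understates
  truth by exactly 1/k; corrected % = raw % × k.

## The synthetic methylome

The generator emulates an adult rodent hippocampus methylome on a small
mock genome (default three 300-kb autosomes, 200-kb chrX, 100-kb chrY;
~1.2 Mb ≈ 1.2 × 10⁵ CG sites — chosen so binomial recovery is tight at
10× coverage while a full 12-sample study runs in seconds):

- random near-uniform sequence; 60 CpG islands (300–600 bp) built with an
  elevated CG-dinucleotide emission rate (≥ 3× background density by
  construction), placed in evenly spaced slots on autosomes + chrX;
  60 promoters with the TSS at an island midpoint and random gene strand
  (the common CGI-promoter arrangement, which produces the U-shaped
  TSS profile); repeat intervals (150–400 bp, ~10 % of each chromosome)
  standing in for hypermethylated LINE/SINE elements.
- compartment CG means: background ~0.50/0.15 (mCG/hmCG), island
  interiors 0.05/0.02, repeats 0.95/0.03, chrY hmCG 0.05; CH contexts
  0.005/0.0005 everywhere. Because islands (low) and repeats (high)
  would drag the pooled level away from the global 50 %/15 % targets, the
  background means are solved from the realized autosomal CG-site shares
  so the pooled autosomal expectation equals the targets exactly.
- effects: +0.02 mCG on female chrX, +0.02 hmCG on male chrX, +0.03 hmCG
  in shores/shelves of old animals (both sexes), −0.015 mCG in TSS ± 1 kb
  of old males. Means are clipped to the unit simplex with a warning
  (the only sites that clip are repeats inside shores of old samples).
- per-site, per-sample truth is drawn from a Dirichlet over
  (m, h, unmodified) with concentration 20, giving Beta marginals around
  the compartment means; this one parameter carries both site-to-site
  and replicate-to-replicate variance (no separate between-animal
  variance component — a free choice, as biological replicate variance
  has no obvious reference value). Concentration = ∞ gives point masses
  for exact tests.
- depth is Poisson(coverage) per site and library; zero-depth sites are
  emitted and excluded downstream. Spike-ins are three fixed 48-mers with
  disjoint site classes (unmodified / mC / hmC). The read simulator
  draws fragments uniformly from both strands, applies conversion once
  per fragment, and encodes exact placement in the read name, so read QC
  is testable without an aligner; note per-strand coverage is half the
  nominal total.
- all randomness flows from one seed through named substreams
  (reference, truth per sample, counts per sample, reads, spike-ins,
  assays), so each stage is independently reproducible and emitters are
  byte-deterministic (gzip mtime pinned).

What the generator does **not** emulate — sequencing errors, PCR
duplicates, mapping bias, adapter read-through, CH compartment structure,
genome-scale repeat families — bounds what passing tests show: they
validate the estimators and bookkeeping under the stated chemistry model,
not robustness to alignment artifacts on real data.

## Known limitations

- hmC differencing is noisy at single sites by construction; the package
  aggregates (chromosome classes, regions, bins) and does no site-level
  differential testing.
- No fC/caC modelling; oxidised intermediates are treated as fully
  converting.
- The X-homologous chrY masking used with real alignments is unnecessary
  here (coordinate-tagged reads) and is out of scope.
- ELISA curves are linear; saturating plates would need the logistic
  extension.
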