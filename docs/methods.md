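# Methods

This note records the models behind `searchtune`, the parameters that
matter, what the synthetic data generator does and does not emulate, the
numerical choices, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model and assumptions

The package automates search-parameter selection for DDA proteomics under
three assumptions:

1. a small subset of *identifiable* spectra is representative enough to rank
   parameter values (spectra without a readable sequence tag contribute
   little but noise);
2. the sequence database can be restricted to proteins supported by de novo
   peptide evidence without distorting which parameter value wins;
3. the quality of a search result is measured by its FDR-gated
   identifications, compared through score *ranks* rather than raw scores,
   so different engines' scoring scales are interchangeable.

## Spectrum subsetting

- **Target subset size** depends on the engine class: 1500 spectra for a
  slow (X!Tandem-class) engine, raised to 2000 above 100,000 total spectra
  so the FDR estimate stays populated; 3000 for a fast (Sage-class) engine;
  always capped at the data-set size. Engines unknown to the sizing rule get
  the conservative 1500/2000 rule.
- **Sectioning**: < 2000 spectra → 4 sections; 2000–10,000 → one section per
  ~500 spectra, i.e. ceil(total/500) clamped to [4, 20] (the rule is only
  printed for multiples of 500; the ceiling is the simplest consistent
  reading); > 10,000 → 20 sections. Sections are contiguous in acquisition
  order with sizes differing by at most one.
- **Tag filtering**: spectra whose best length-3 sequence tag has
  e-value ≥ 0.01 are excluded; the cutoff is exclusive for retention
  (e = 0.01 is excluded).
- **Quotas** are apportioned to sections proportionally to their confident
  counts by largest-remainder rounding (ties to the lower section index), so
  Σ quota = min(target, total confident) exactly and each section's share
  deviates from proportionality by at most 1/Σquota.
- **Sampling** within a section takes confident spectra at positions
  0, n, 2n, … with n = max(1, floor(confident/quota)) until the quota is
  filled. The sampling phase (start at 0) and the floor rounding are fixed
  conventions. A consequence worth knowing: the *membership* of the subset
  is only stable under small target-size changes while the integer stride
  does not flip; at stride boundaries the selected set can change
  substantially even though its sectionwise coverage (and, in our
  experiments, the downstream parameter choices) does not. The package keeps
  the simple deterministic rule rather than a nested sampling order.

## Database reduction

PE filtering keeps records whose UniProt header carries `PE=1`; records
without a PE token are dropped by default (strict UniProt reading,
`keep_unannotated=True` to retain). De novo peptides match proteins as exact
contiguous substrings under I/L equivalence — de novo sequencing cannot
distinguish the isobaric pair — with no substitution tolerance. Decoys are
whole-sequence reversals with accession prefix `DECOY_`, appended after
reduction (one per target). A peptide found in both a target and a decoy
protein counts as target, the standard target-decoy convention.

## Built-in search engine

The engine exists so the pipeline is self-contained; it does not attempt to
reproduce any production engine's scores numerically.

- **Digestion** rules: trypsin (after K/R, not before P), Lys-C (after K),
  Arg-C (after R, not before P), chymotrypsin (after F/W/Y, not before P),
  Glu-C (after E), and no-enzyme (all substrings). `specific` requires both
  termini enzymatic (protein termini count); `semi` requires one.
- **Modifications** are fixed mass deltas from a small built-in table
  (carbamidomethyl C +57.02146, oxidation M +15.99491, deamidation N/Q
  +0.98402, acetyl N-term +42.01057, dimethyl K +28.03130, pyro-Glu
  E −18.01056 / Q −17.02655 Da). Fixed mods occupy every eligible site;
  variable mods are expanded combinatorially up to `max_variable_mods`
  (default 2), one modification per site.
- **Scoring**: candidates whose modified monoisotopic mass matches the
  observed neutral precursor mass within the precursor tolerance are scored
  as hyperscore = ln(Σ matched fragment intensity) + ln Nb! + ln Ny! over
  singly protonated b/y ions within the fragment tolerance and the fragment
  m/z range; factorials are capped at 20! to bound score growth. Zero
  matched fragments ⇒ no PSM. Best-hit ties break to the longer, then
  lexicographically smaller peptide, making results bit-reproducible.
- **FDR gating**: FDR(s) = #{decoy ≥ s} / max(1, #{target ≥ s}); the
  threshold is the smallest observed score with FDR ≤ α (α = 0.01 by
  default) and the validated set holds the target PSMs at or above it. No
  q-value monotonization is applied; with tied scores the count at a score
  value includes every PSM at or above it. Every search is gated
  independently.

## CScore

Reference quartiles use linear interpolation between order statistics (the
common numerical-library default; no convention is published). Rank
intervals are half-open with rank 4 closed at the top, so degenerate
quartiles (all reference scores equal) rank a score at the common value 4.
The adjacent-shift disregard (|Δrank| ≤ 1 contributes 0) applies to the
shared term only, as defined. PSMs are paired by spectrum id alone, and the
ranks of gained/lost PSMs are computed against the reference quartiles — the
only quartiles defined. At least 4 validated reference PSMs are required to
section the distribution. Consequences verified by the property suite:
self-comparison is exactly 0, the total is monotone in the unique sets, and
any strictly increasing transform applied jointly to all scores leaves the
breakdown unchanged.

## Greedy optimization

"Best value" means the strictly positive maximum CScore total; ties break to
the earlier candidate in the configured list, and all-nonpositive landscapes
keep the default (the default is sticky). Numeric parameters are optimized
over their configured grid only — no refinement between grid points. The
reference for each parameter is recomputed under the currently chosen
settings (the parameter set changed, so caching across parameters would be
incorrect bookkeeping); a reference validating fewer than 4 PSMs skips its
parameter with a warning. A candidate search that raises is logged, scored
as −∞, and can never win. The shipped order (enzyme → specificity → missed
cleavages → tolerances → fixed mods → variable mods → max variable mods)
puts high-impact, naturally-ordered parameters first; `max_variable_mods`
declares a dependency on `variable_mods` and the loader rejects configs that
order a parameter before its dependencies.

## Synthetic data

`SyntheticConfig` defaults describe a toy high-resolution Orbitrap-like DDA
run: 20 proteins of 150–300 residues built from protease-friendly segments
(every protein is guaranteed a fully tryptic peptide of length 7–20), 60
spectra of which 20% are pure noise, 5 ppm Gaussian m/z jitter, 6 uniform
noise peaks per identifiable spectrum with intensities below the median true
peak, and 20% of headers carrying PE ≠ 1. Identifiable spectra are singly
charged b/y ladders of peptides digested with the configured true enzyme and
carrying the configured true modifications. All generators are pure
functions of (config, seed).

What the generator does **not** emulate: isotope envelopes, higher fragment
charges, neutral losses, co-isolated (chimeric) precursors, retention time,
intensity structure along the ladder, and realistic protein sequence
composition. A green test on this world therefore establishes the
*algorithmic* correctness of subsetting, reduction, gating, scoring and
selection — not identification performance on real instruments.

**Recovery fixture.** The parameter-recovery suite uses a mixed-digest
world: 120 chymotryptic spectra with carbamidomethylated cysteines and
15 ppm precursor jitter over a 40-spectrum tryptic background. The
background keeps the trypsin-default reference search above the 4-PSM
viability floor, while each tuned parameter has one unambiguous correct grid
point: chymotrypsin (its peptides contain internal K/R, so no tryptic search
can cover them), carbamidomethyl C (cysteine peptides are otherwise off by
+57.02 Da per site), and 50 ppm (≈3.3 σ of the planted jitter; 10 ppm
truncates half the precursors, 5 ppm more). The background size was chosen
for statistical power of the reference search before the replicate seeds
were frozen. A separate test plants a Lys-C digest and recovers the enzyme
under a strict no-missed-cleavage base search — with missed cleavages
allowed, tryptic digestion legitimately covers Lys-C peptides (internal
arginines count as missed sites), the CScore is correctly ≈ 0, and the
default is kept; this is a property of the biology, not a failure of the
selector.

## Built-in evidence providers

The tag scorer counts length-3 residue-mass ladder paths (four peaks, three
gaps, 0.02 Da gap tolerance) and converts the count to a Poisson upper-tail
e-value under a null model of uniformly spread peaks; a spectrum with no
path gets e-value 1. The null rate is estimated from peak density, the
number of distinct residue masses and the tolerance — it is a rough model,
adequate because planted ladders yield tens of paths (e ≈ 0) while pure
noise almost always yields none (e = 1). The noisy de novo provider emits
the longest consecutive-gap residue chain in both orientations (a chain over
y ions reads the peptide backwards) when it is at least 5 residues long;
the exact provider replays planted ground truth and stands in for an
external de novo sequencer on synthetic data.

## Known limitations

- Only singly charged b/y fragments; no isotope-error handling, open
  modification search or chimeric spectra.
- The hyperscore is a minimal stand-in: CScore consumes any monotone match
  score, but absolute score values here are not comparable to any production
  engine.
- Subset membership (not parameter choice) can be unstable across every-n
  stride boundaries; see the subsetting section.
- The greedy loop inherits order sensitivity: a badly wrong early choice
  conditions everything after it. The shipped order mitigates, not removes,
  this.
- DDA only; no mzML/mzXML readers (MGF in, MGF out).
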