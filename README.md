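# searchtune

Automatic selection of proteomics database-search parameter values.

Choosing search-engine settings for a shotgun (DDA) proteomics experiment —
digestion enzyme, enzyme specificity, missed cleavages, precursor and
fragment mass tolerances, fixed and variable modifications — normally takes
expert knowledge or many slow trial searches over the full data set.
`searchtune` automates the choice: it reduces the spectrum file to a small
but representative subset, shrinks the sequence database to proteins the
data can support, and then tunes one parameter at a time by running cheap
reference/test searches and comparing their confident identifications.
It is aimed at proteomics researchers re-analyzing public data sets with
missing or doubtful metadata, and at anyone who wants reproducible,
data-driven search settings without hand-tuning.

## The method

1. **Spectrum subsetting.** The acquisition is split into 4–20 contiguous
   sections. A sequence tagger assigns each spectrum an e-value for carrying
   a readable amino-acid ladder; spectra with e ≥ 0.01 are excluded. Each
   section contributes a quota of confident spectra proportional to its
   confident count (largest-remainder rounding), sampled at a fixed
   "every-*n*" stride, up to an engine-dependent target size (1500–2000
   spectra for an X!Tandem-class engine, 3000 for a Sage-class one).
2. **Database reduction.** Only proteins with UniProt protein existence
   PE=1 that contain at least one de-novo-read peptide (I/L equivalent
   substring match) are kept; reversed-sequence decoys are concatenated.
3. **Target–decoy FDR gating.** Every search is thresholded at the smallest
   score *s* with #{decoy ≥ s} / #{target ≥ s} ≤ 1%; only the validated
   target PSMs enter any comparison.
4. **CScore.** A test search is compared against a reference search through
   quartile ranks: the reference hyperscores define quartiles Q1/median/Q3,
   every PSM (both searches) is ranked 1–4 against them, and

   CScore = shared + gained − lost

   where *shared* = Σ (test rank − reference rank) over spectra identified
   in both searches (|Δrank| ≤ 1 disregarded as noise), *gained* = Σ ranks
   of test-only identifications, *lost* = Σ ranks of reference-only ones.
   Because only ranks enter, the score is invariant to the engine's score
   scale.
5. **Greedy ordered optimization.** Parameters are tuned in a configured
   order (digestion first, then tolerances, then modifications). For each
   parameter, the reference search uses its default under the currently
   chosen settings and one test search runs per candidate value; the best
   strictly positive CScore wins, otherwise the default is kept, and the
   chosen value is folded in before the next parameter.

A minimal hyperscore search engine (X!Tandem-style
`ln(Σ matched intensity · Nb! · Ny!)` over singly charged b/y ions) is built
in so the pipeline runs end to end with no external binaries; any engine
exposing a monotone match score can be plugged in through the
`SearchEngine`/`TagProvider`/`DeNovoProvider` contracts.

## Worked example

`examples/05_full_pipeline.py` generates a synthetic 60-spectrum acquisition
whose peptides carry carbamidomethylated cysteines (fixed) and oxidized
methionines (variable), writes it as MGF + FASTA, and runs the whole
pipeline. It prints:

```
22 searches run in total

enzyme                 -> 'trypsin'  candidate CScores: {'"lys-c"': -29, '"chymotrypsin"': -33}
specificity            -> 'semi'  candidate CScores: {'"semi"': 7}
max_missed_cleavages   -> 2  candidate CScores: {'0': -7, '1': 0}
precursor_tolerance    -> [50, 'ppm']  candidate CScores: {'[5.0, "ppm"]': -19, '[50.0, "ppm"]': 1}
fragment_tolerance     -> [0.02, 'Da']  candidate CScores: {'[0.05, "Da"]': -1, '[0.5, "Da"]': -1}
fixed_mods             -> ['carbamidomethyl_c']  candidate CScores: {'["carbamidomethyl_c"]': 52}
variable_mods          -> ['oxidation_m']  candidate CScores: {'["oxidation_m"]': 32, '["deamidation_n", "oxidation_m"]': 30}
max_variable_mods      -> 2  candidate CScores: {'1': 0, '3': 0}

final parameters: enzyme=trypsin, fixed=['carbamidomethyl_c'], variable=['oxidation_m']
```

Reading it: wrong enzymes *lose* validated identifications (negative
CScores), so the trypsin default stays. Modeling carbamidomethylation gains
52 rank points — every cysteine-containing peptide whose precursor mass was
off by +57.02 Da per cysteine becomes identifiable — so it is adopted, as is
oxidation of M (+32). Candidates that change nothing (CScore ≤ 0) leave the
default in place. The other examples (`examples/01`–`04`) walk through each
stage in isolation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance quantity from scratch: it generates a
seeded synthetic PSM table of 5,000 target and 5,000 decoy scores from
overlapping Gaussians, applies the target–decoy thresholding at the 1% FDR
level, re-counts decoys and targets above the threshold directly, and writes
the empirical FDR of the validated set (in percent) as JSON.

## Layout

- `src/searchtune/` — library modules: `spectra_io` (MGF), `subsetting`,
  `dbreduce` (FASTA, decoys), `search_core` (engine + FDR), `cscore`,
  `optimizer` (greedy loop + pipeline), `providers` (tagger / de novo),
  `synthetic` (fixture generators), `data/parameter_config.json`
  (shipped parameter order).
- `examples/` — one narrative script per capability.
- `tests/` — pytest suite; `tests/test_acceptance.py` holds the
  printed-rule worked examples and statistical property checks.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
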