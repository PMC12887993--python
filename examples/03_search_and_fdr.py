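"""Run the built-in hyperscore search and gate it at 1% target-decoy FDR.

Each spectrum gets its best-scoring candidate peptide (hyperscore =
ln(summed matched intensity * Nb! * Ny!) over singly charged b/y ions);
the score threshold is the smallest one at which decoy matches make up
at most 1% of the target matches above it.
"""

import searchtune as st

cfg = st.SyntheticConfig(seed=7)
proteome = st.generate_proteome(cfg)
spectra, truth = st.generate_spectra(cfg, proteome)
db = st.append_decoys(proteome)

result = st.search(spectra, db, st.SearchParameters())
print(f"{len(spectra)} spectra searched, {len(result.psms)} PSMs")
print(f"1% FDR score threshold: {result.fdr_threshold:.2f}")
print(f"validated target PSMs: {len(result.validated)}")

recovered = sum(
    1
    for row in truth.itertuples(index=False)
    if any(p.spectrum_id == row.spectrum_id and p.peptide == row.modified_peptide
           for p in result.validated)
)
print(f"planted peptides recovered: {recovered}/{len(truth)}")
# The validated list is what every downstream comparison consumes: PSMs the
# decoy model says are (at most 1%) wrong.
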