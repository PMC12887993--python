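"""Shrink a FASTA database to proteins with de novo evidence, add decoys.

Only proteins with experimental protein-level evidence (PE=1) that contain
at least one de-novo-read peptide (I/L treated as equivalent) are kept;
reversed-sequence decoys are then concatenated for FDR estimation.
"""

import searchtune as st

cfg = st.SyntheticConfig(n_proteins=100, fraction_non_pe1=0.2, seed=5)
db = st.generate_proteome(cfg)
spectra, truth = st.generate_spectra(cfg, db)

# de novo evidence read back from the spectra (here: the exact provider,
# standing in for an external de novo sequencer on synthetic data)
peptides = st.ExactDeNovoProvider(truth).sequence(spectra)
print(f"database: {len(db)} proteins, {sum(r.pe_level == 1 for r in db)} with PE=1")
print(f"de novo evidence: {len(peptides)} peptides from {len(spectra)} spectra")

reduced = st.reduce_database(db, peptides)
searched = st.append_decoys(reduced)
print(f"reduced database: {len(reduced)} proteins with peptide evidence")
print(f"with decoys appended: {len(searched)} entries (one reversed decoy per target)")
print(f"example decoy: {searched[-1].accession} = reverse of {reduced[-1].accession}")
# The search that follows only has to digest the proteins the data can
# actually support, which is what makes repeated test searches affordable.
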