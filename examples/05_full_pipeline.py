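"""End-to-end parameter selection on a synthetic acquisition.

Writes an MGF and a FASTA to a scratch directory, then runs the whole
pipeline: subset selection -> database reduction -> decoys -> greedy ordered
optimization of every parameter in the shipped configuration.
"""

import tempfile
from pathlib import Path

import searchtune as st

workdir = Path(tempfile.mkdtemp(prefix="searchtune_"))
cfg = st.SyntheticConfig(
    true_fixed_mods=frozenset({"carbamidomethyl_c"}),
    true_variable_mods=frozenset({"oxidation_m"}),
    seed=23,
)
proteome = st.generate_proteome(cfg)
spectra, truth = st.generate_spectra(cfg, proteome)
mgf = st.write_mgf(spectra, workdir / "run.mgf")
fasta = st.write_fasta(proteome, workdir / "db.fasta")

report = st.run_pipeline(
    mgf, fasta, workdir / "out", denovo_provider=st.ExactDeNovoProvider(truth)
)

print(f"artifacts in {workdir / 'out'}")
print(f"{report.total_searches} searches run in total\n")
for entry in report.entries:
    totals = {k: (b.total if b else "failed") for k, b in entry.breakdowns.items()}
    note = " (skipped)" if entry.skipped else ""
    print(f"{entry.name:22s} -> {entry.chosen!r}{note}  candidate CScores: {totals}")

final = report.final_parameters
print(f"\nfinal parameters: enzyme={final.enzyme}, fixed={sorted(final.fixed_mods)}, "
      f"variable={sorted(final.variable_mods)}")
# Every parameter whose candidates never beat the reference (CScore <= 0)
# keeps its default; the planted modifications are picked up because the
# searches that model them gain validated identifications.
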