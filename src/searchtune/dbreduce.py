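"""FASTA handling, evidence-based database reduction, and reversed decoys.

The reduction mirrors standard practice for speeding up database searches:
keep only proteins with experimental protein-level evidence (UniProt PE=1),
then keep only those supported by at least one de novo peptide read from the
spectrum subset, and finally concatenate reversed-sequence decoys for
target-decoy FDR estimation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_PE_RE = re.compile(r"\bPE=(\d)\b")
_VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "XBZU")

DECOY_PREFIX = "DECOY_"

# I and L are isobaric: de novo reads cannot tell them apart.
_IL_TABLE = str.maketrans("I", "L")


@dataclass
class ProteinRecord:
    """One FASTA entry; ``header`` is the full description line, verbatim."""

    accession: str
    header: str
    pe_level: int | None
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")


@dataclass
class DeNovoPeptide:
    """A peptide sequence proposed for one spectrum by a de novo provider."""

    spectrum_id: str
    peptide: str
    score: float

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("empty de novo peptide")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA database.

    The accession is the first whitespace-delimited header token; the
    UniProt protein-existence level is taken from a ``PE=<digit>`` token
    when present. Multi-line sequences are concatenated and uppercased.
    """
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path.name}: sequence data before any '>' header")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        accession = header.split()[0]
        m = _PE_RE.search(header)
        pe = int(m.group(1)) if m else None
        records.append(
            ProteinRecord(
                accession=accession,
                header=header,
                pe_level=pe,
                sequence=str(rec.seq).upper(),
                is_decoy=accession.startswith(DECOY_PREFIX),
            )
        )
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as FASTA, preserving headers verbatim."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


def filter_pe1(db: list[ProteinRecord], keep_unannotated: bool = False) -> list[ProteinRecord]:
    """Keep only proteins with experimental protein-level evidence (PE=1).

    Records lacking a PE token are dropped by default (strict UniProt
    reading); set ``keep_unannotated`` to retain them.
    """
    kept = []
    for rec in db:
        if rec.pe_level == 1 or (rec.pe_level is None and keep_unannotated):
            kept.append(rec)
    return kept


def match_peptides(
    peptides: list[DeNovoPeptide],
    db: list[ProteinRecord],
    equate_il: bool = True,
) -> dict[str, set[str]]:
    """Map accession -> set of de novo peptides found in its sequence.

    Matching is exact contiguous substring under I/L equivalence (de novo
    sequencing cannot distinguish the two); accessions with no match are
    omitted from the result.
    """
    if not db:
        raise ValueError("empty database")
    queries = {}
    for p in peptides:
        key = p.peptide.translate(_IL_TABLE) if equate_il else p.peptide
        queries.setdefault(key, set()).add(p.peptide)
    matches: dict[str, set[str]] = {}
    for rec in db:
        seq = rec.sequence.translate(_IL_TABLE) if equate_il else rec.sequence
        hit = {orig for key, origs in queries.items() if key in seq for orig in origs}
        if hit:
            matches[rec.accession] = hit
    return matches


def reduce_database(
    db: list[ProteinRecord],
    peptides: list[DeNovoPeptide],
    keep_unannotated: bool = False,
    equate_il: bool = True,
) -> list[ProteinRecord]:
    """PE=1 filter followed by de-novo-evidence filter; order preserved."""
    pe1 = filter_pe1(db, keep_unannotated=keep_unannotated)
    if not pe1:
        raise ValueError(
            "no PE=1 proteins in the database; re-run with keep_unannotated=True "
            "or disable PE filtering"
        )
    matched = match_peptides(peptides, pe1, equate_il=equate_il)
    reduced = [rec for rec in pe1 if rec.accession in matched]
    if not reduced:
        raise ValueError(
            "database reduction removed every protein; use a larger spectrum "
            "subset or disable PE filtering"
        )
    return reduced


def append_decoys(db: list[ProteinRecord]) -> list[ProteinRecord]:
    """Concatenate one reversed-sequence decoy per target protein.

    Decoy accessions are ``DECOY_<accession>``; the output holds the targets
    followed by their decoys (2x the input size).
    """
    if any(rec.is_decoy for rec in db):
        raise ValueError("database already contains decoy records")
    decoys = []
    seen = {rec.accession for rec in db}
    for rec in db:
        acc = DECOY_PREFIX + rec.accession
        if acc in seen:
            raise ValueError(f"decoy accession collision: {acc}")
        seen.add(acc)
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            logger.info("palindromic sequence %s: decoy equals target", rec.accession)
        decoys.append(
            ProteinRecord(
                accession=acc,
                header=f"{acc} DECOY reversed of {rec.accession}",
                pe_level=rec.pe_level,
                sequence=rev,
                is_decoy=True,
            )
        )
    return list(db) + decoys


def read_denovo_tsv(path: str | Path) -> list[DeNovoPeptide]:
    """Read a de novo peptide sidecar TSV (spectrum_id, peptide, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str})
    return [
        DeNovoPeptide(str(r.spectrum_id), str(r.peptide), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_denovo_tsv(peptides: list[DeNovoPeptide], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(p.spectrum_id, p.peptide, p.score) for p in peptides],
        columns=["spectrum_id", "peptide", "score"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
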