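"""Synthetic proteome, spectra and PSM-table generators.

The generators emulate, at toy scale, a high-resolution DDA run of a tryptic
(or alternative-enzyme) digest: each identifiable spectrum is the singly
charged b/y ladder of a planted peptide with ppm-level Gaussian m/z jitter
and a few uniform noise peaks, a configurable fraction of spectra is pure
noise (untaggable), and the FASTA headers carry UniProt-style PE codes.
Everything is a pure function of (config, seed), so the fixtures used in the
tests are regenerated identically at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import PROTON, get_modification, format_peptide, modification_sites, peptide_mass
from .dbreduce import ProteinRecord
from .search_core import digest, fragment_ions
from .spectra_io import Spectrum, SpectrumSet

_SEGMENT_INNER = list("ACDEFGHILMNQSTVWY")  # no K/R (cut sites), no P (blocking)


@dataclass
class SyntheticConfig:
    """The stated world of the synthetic fixtures.

    Defaults describe a small but realistic Orbitrap-like acquisition: 20
    proteins of 150-300 residues, 60 spectra of which 20% are unidentifiable
    noise, 5 ppm mass jitter and 6 noise peaks per identifiable spectrum.
    """

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (150, 300)
    true_enzyme: str = "trypsin"
    true_fixed_mods: frozenset[str] = frozenset()
    true_variable_mods: frozenset[str] = frozenset()
    n_spectra: int = 60
    fragment_noise_peaks: int = 6
    mass_jitter_ppm: float = 5.0
    fraction_untaggable: float = 0.2
    fraction_non_pe1: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.n_spectra < 0 or self.fragment_noise_peaks < 0:
            raise ValueError("counts must be nonnegative")
        for frac in (self.fraction_untaggable, self.fraction_non_pe1):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        self.true_fixed_mods = frozenset(self.true_fixed_mods)
        self.true_variable_mods = frozenset(self.true_variable_mods)


def generate_proteome(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Random proteins built from tryptic-segment blocks.

    Sequences are concatenations of segments of 4-20 non-K/R residues each
    terminated by K or R (never followed by P), so every protein is
    guaranteed at least one fully tryptic peptide of length 7-20. A
    configurable fraction of headers carries PE=2..5 instead of PE=1.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.protein_length_range
    records = []
    for i in range(cfg.n_proteins):
        target_len = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        first = True
        total = 0
        while total < target_len:
            # first segment is forced into 7..20 so a length-range tryptic
            # peptide always exists
            seg_len = int(rng.integers(7, 20)) if first else int(rng.integers(4, 20))
            first = False
            inner = "".join(rng.choice(_SEGMENT_INNER, size=seg_len - 1))
            seg = inner + ("K" if rng.random() < 0.5 else "R")
            parts.append(seg)
            total += len(seg)
        seq = "".join(parts)
        pe = int(rng.integers(2, 6)) if rng.random() < cfg.fraction_non_pe1 else 1
        acc = f"sp|SYN{i:04d}|SYN{i:04d}_SYN"
        header = f"{acc} Synthetic protein {i} OS=Synthetic OX=0 PE={pe} SV=1"
        records.append(
            ProteinRecord(accession=acc, header=header, pe_level=pe, sequence=seq)
        )
    return records


def _apply_true_mods(
    peptide: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[tuple[int, str], ...]:
    """Fixed mods on every site; each variable mod on one random site, p=0.6."""
    mods: list[tuple[int, str]] = []
    taken: set[int] = set()
    for name in sorted(cfg.true_fixed_mods):
        for pos in modification_sites(peptide, get_modification(name)):
            if pos not in taken:
                mods.append((pos, name))
                taken.add(pos)
    for name in sorted(cfg.true_variable_mods):
        sites = [p for p in modification_sites(peptide, get_modification(name)) if p not in taken]
        if sites and rng.random() < 0.6:
            pos = int(rng.choice(sites))
            mods.append((pos, name))
            taken.add(pos)
    return tuple(sorted(mods))


def generate_spectra(
    cfg: SyntheticConfig, proteome: list[ProteinRecord], seed: int | None = None
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Plant peptide b/y ladders into spectra, plus pure-noise spectra.

    Returns the spectrum set (acquisition order is a seeded permutation of
    identifiable and noise spectra) and the ground-truth table with one row
    per identifiable spectrum: spectrum_id, peptide, modified_peptide,
    protein, mods.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    pool: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in proteome:
        for pep in digest(rec.sequence, cfg.true_enzyme, "specific", 0, (7, 20)):
            if pep not in seen:
                seen.add(pep)
                pool.append((pep, rec.accession))
    if not pool:
        raise ValueError("proteome yields no peptides under the true enzyme")

    n_noise = int(round(cfg.n_spectra * cfg.fraction_untaggable))
    n_ident = cfg.n_spectra - n_noise
    kinds = np.array(["ident"] * n_ident + ["noise"] * n_noise)
    kinds = kinds[rng.permutation(cfg.n_spectra)]

    spectra: list[Spectrum] = []
    truth_rows = []
    jitter = cfg.mass_jitter_ppm * 1e-6
    for idx, kind in enumerate(kinds):
        sid = f"scan={idx}"
        if kind == "ident":
            pep, acc = pool[int(rng.integers(len(pool)))]
            mods = _apply_true_mods(pep, cfg, rng)
            b, y = fragment_ions(pep, mods)
            ions = np.concatenate([b, y])
            intens = rng.uniform(200.0, 1000.0, size=len(ions))
            ions = ions * (1.0 + rng.normal(0.0, jitter, size=len(ions)))
            if cfg.fragment_noise_peaks:
                noise_mz = rng.uniform(100.0, float(ions.max()) + 50.0, size=cfg.fragment_noise_peaks)
                noise_in = rng.uniform(1.0, float(np.median(intens)), size=cfg.fragment_noise_peaks)
                ions = np.concatenate([ions, noise_mz])
                intens = np.concatenate([intens, noise_in])
            mass = peptide_mass(pep, mods)
            pre_mz = (mass + PROTON) * (1.0 + rng.normal(0.0, jitter))
            spectra.append(
                Spectrum(sid, pre_mz, 1, np.column_stack([ions, intens]), idx)
            )
            truth_rows.append(
                (
                    sid,
                    pep,
                    format_peptide(pep, mods),
                    acc,
                    ";".join(f"{name}@{pos + 1}" for pos, name in mods),
                )
            )
        else:
            noise_mz = rng.uniform(100.0, 1500.0, size=25)
            noise_in = rng.uniform(50.0, 500.0, size=25)
            pre_mz = float(rng.uniform(400.0, 1200.0))
            spectra.append(
                Spectrum(sid, pre_mz, 1, np.column_stack([noise_mz, noise_in]), idx)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["spectrum_id", "peptide", "modified_peptide", "protein", "mods"],
    )
    return SpectrumSet(spectra=spectra, source_name="synthetic"), truth


def generate_psm_tables(
    n_targets: int,
    n_decoys: int,
    score_distributions: tuple[tuple[float, float], tuple[float, float]] = (
        (25.0, 4.0),
        (18.0, 4.0),
    ),
    seed: int = 0,
):
    """Labeled PSM tables for isolated FDR/CScore tests.

    ``score_distributions`` holds (mean, sd) of the target and decoy
    hyperscore Gaussians (targets high, decoys low by default).
    """
    from .search_core import PSM

    (mu_t, sd_t), (mu_d, sd_d) = score_distributions
    rng = np.random.default_rng(seed)
    psms = []
    for i in range(n_targets):
        psms.append(
            PSM(
                spectrum_id=f"target_scan={i}",
                peptide="PEPTIDEK",
                protein_accessions=frozenset({"sp|T|T"}),
                hyperscore=float(rng.normal(mu_t, sd_t)),
                is_decoy=False,
            )
        )
    for i in range(n_decoys):
        psms.append(
            PSM(
                spectrum_id=f"decoy_scan={i}",
                peptide="KEDITPEP",
                protein_accessions=frozenset({"DECOY_sp|T|T"}),
                hyperscore=float(rng.normal(mu_d, sd_d)),
                is_decoy=True,
            )
        )
    return psms
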