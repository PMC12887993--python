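"""Built-in hyperscore search engine and target-decoy FDR gating.

This is a deliberately minimal database search engine so that the parameter
selection pipeline is runnable end to end without external binaries. Scoring
follows the classic X!Tandem-style hyperscore,

    hyperscore = ln( (sum of matched fragment intensities) * Nb! * Ny! )

over singly charged b/y ions, with the factorials capped at 20!. Any engine
exposing a monotone match-quality score can be substituted through the
:class:`SearchEngine` contract — the downstream quartile-rank comparison is
insensitive to the score's scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

from .chem import (
    PROTON,
    RESIDUE_MASSES,
    WATER,
    get_modification,
    format_peptide,
    modification_sites,
    peptide_mass,
    residue_deltas,
)
from .dbreduce import ProteinRecord
from .spectra_io import Spectrum, SpectrumSet

logger = logging.getLogger(__name__)

# residues after which each enzyme cleaves; None marks "no P restriction"
ENZYME_RULES: dict[str, tuple[str, str]] = {
    # (cleave after these residues, blocked when next residue in ...)
    "trypsin": ("KR", "P"),
    "lys-c": ("K", ""),
    "arg-c": ("R", "P"),
    "chymotrypsin": ("FWY", "P"),
    "glu-c": ("E", ""),
}

_FACTORIAL_CAP = 20


@dataclass(frozen=True)
class Tolerance:
    """A mass tolerance with a unit (ppm or Da)."""

    value: float
    unit: str  # "ppm" | "Da"

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'Da', got {self.unit!r}")
        if not (self.value > 0):
            raise ValueError("tolerance must be positive")

    def window(self, reference_mass: float) -> float:
        """Absolute half-window in Da around ``reference_mass``."""
        if self.unit == "ppm":
            return abs(reference_mass) * self.value * 1e-6
        return self.value


@dataclass(frozen=True)
class SearchParameters:
    """The tunable knobs of a database search."""

    enzyme: str = "trypsin"
    specificity: str = "specific"  # "specific" | "semi"
    max_missed_cleavages: int = 2
    precursor_tolerance: Tolerance = Tolerance(10.0, "ppm")
    fragment_tolerance: Tolerance = Tolerance(0.02, "Da")
    fixed_mods: frozenset[str] = frozenset()
    variable_mods: frozenset[str] = frozenset()
    peptide_length_range: tuple[int, int] = (7, 30)
    fragment_mz_range: tuple[float, float] = (100.0, 2000.0)
    max_variable_mods: int = 2
    extra: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_range
        if lo > hi:
            raise ValueError("peptide_length_range min > max")
        flo, fhi = self.fragment_mz_range
        if flo > fhi:
            raise ValueError("fragment_mz_range min > max")

    def with_value(self, **kwargs) -> "SearchParameters":
        return replace(self, **kwargs)


@dataclass
class PSM:
    """Best peptide-to-spectrum match for one spectrum in one search."""

    spectrum_id: str
    peptide: str
    protein_accessions: frozenset[str]
    hyperscore: float
    is_decoy: bool
    charge: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.hyperscore):
            raise ValueError(f"non-finite hyperscore for {self.spectrum_id!r}")


@dataclass
class SearchResult:
    """All PSMs of one search plus the FDR-gated (validated) target PSMs."""

    parameters: SearchParameters
    psms: list[PSM]
    fdr_threshold: float | None
    validated: list[PSM]


class SearchEngine(Protocol):
    """Contract for pluggable engines: (spectra, decoy-appended db, params) -> result."""

    def run(
        self, spectra: SpectrumSet, db: list[ProteinRecord], params: SearchParameters
    ) -> SearchResult: ...


def digest(
    sequence: str,
    enzyme: str,
    specificity: str = "specific",
    max_missed: int = 0,
    length_range: tuple[int, int] = (1, 50),
) -> list[str]:
    """In silico digestion of one protein sequence.

    Returns the deduplicated peptides consistent with the cleavage rule,
    the missed-cleavage bound, the specificity mode and the length range.
    ``no-enzyme`` enumerates every substring in the length range.
    """
    lo, hi = length_range
    if enzyme == "no-enzyme":
        out = {
            sequence[i : i + n]
            for n in range(lo, hi + 1)
            for i in range(0, len(sequence) - n + 1)
        }
        return sorted(out)
    if enzyme not in ENZYME_RULES:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; supported: "
            + ", ".join(sorted(ENZYME_RULES) + ["no-enzyme"])
        )
    after, blocked_by = ENZYME_RULES[enzyme]
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in after and sequence[i + 1] not in blocked_by:
            cuts.append(i + 1)
    cuts.append(len(sequence))
    segments = [sequence[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]

    peptides: set[str] = set()
    for i in range(len(segments)):
        for j in range(i, min(i + max_missed + 1, len(segments))):
            pep = "".join(segments[i : j + 1])
            if specificity == "specific":
                if lo <= len(pep) <= hi:
                    peptides.add(pep)
            elif specificity == "semi":
                # one terminus must stay enzymatic: trim from either end only
                for n in range(lo, min(hi, len(pep)) + 1):
                    peptides.add(pep[:n])
                    peptides.add(pep[-n:])
            else:
                raise ValueError(f"unknown specificity {specificity!r}")
    return sorted(peptides)


def _expand_mods(
    sequence: str, params: SearchParameters
) -> list[tuple[tuple[tuple[int, str], ...], float]]:
    """All modification assignments of a peptide allowed by ``params``.

    Fixed modifications occupy every eligible site; variable modifications
    are combinatorially placed on the remaining sites up to
    ``max_variable_mods``. Returns ``(mods, total_delta)`` pairs.
    """
    fixed: list[tuple[int, str]] = []
    taken: set[int] = set()
    for name in sorted(params.fixed_mods):
        mod = get_modification(name)
        for pos in modification_sites(sequence, mod):
            if pos not in taken:
                fixed.append((pos, name))
                taken.add(pos)

    var_sites: list[tuple[int, str]] = []
    for name in sorted(params.variable_mods):
        mod = get_modification(name)
        for pos in modification_sites(sequence, mod):
            if pos not in taken:
                var_sites.append((pos, name))

    results = []
    max_var = min(params.max_variable_mods, len(var_sites))
    from itertools import combinations

    for k in range(0, max_var + 1):
        for combo in combinations(var_sites, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue  # one modification per site
            mods = tuple(sorted(fixed + list(combo)))
            delta = sum(get_modification(n).delta for _, n in mods)
            results.append((mods, delta))
    return results


@dataclass
class _Candidate:
    sequence: str
    mods: tuple[tuple[int, str], ...]
    mass: float
    accessions: frozenset[str]
    is_decoy: bool


class PeptideIndex:
    """Digested, modification-expanded peptide candidates sorted by mass."""

    def __init__(self, db: list[ProteinRecord], params: SearchParameters):
        pep_to_acc: dict[str, set[str]] = {}
        for rec in db:
            for pep in digest(
                rec.sequence,
                params.enzyme,
                params.specificity,
                params.max_missed_cleavages,
                params.peptide_length_range,
            ):
                pep_to_acc.setdefault(pep, set()).add(rec.accession)
        decoy_acc = {rec.accession for rec in db if rec.is_decoy}
        self.candidates: list[_Candidate] = []
        for pep in sorted(pep_to_acc):
            if any(aa not in RESIDUE_MASSES for aa in pep):
                continue  # skip peptides with ambiguous residues (X/B/Z/U)
            accs = frozenset(pep_to_acc[pep])
            base = peptide_mass(pep)
            is_decoy = accs <= decoy_acc  # target wins when shared with a decoy
            for mods, delta in _expand_mods(pep, params):
                self.candidates.append(
                    _Candidate(pep, mods, base + delta, accs, is_decoy)
                )
        self.candidates.sort(key=lambda c: c.mass)
        self.masses = np.array([c.mass for c in self.candidates])

    def in_window(self, mass: float, half_window: float) -> Iterable[_Candidate]:
        lo = np.searchsorted(self.masses, mass - half_window, side="left")
        hi = np.searchsorted(self.masses, mass + half_window, side="right")
        return self.candidates[lo:hi]


def fragment_ions(
    sequence: str, mods: tuple[tuple[int, str], ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Singly protonated b and y ion m/z arrays (b1..b_{n-1}, y1..y_{n-1})."""
    residues = np.array([RESIDUE_MASSES[aa] for aa in sequence])
    residues = residues + residue_deltas(sequence, mods)
    prefix = np.cumsum(residues)
    b = prefix[:-1] + PROTON
    y = (prefix[-1] - prefix[:-1])[::-1] + WATER + PROTON
    return b, y


def _score_candidate(
    spectrum: Spectrum,
    cand: _Candidate,
    frag_tol: Tolerance,
    frag_range: tuple[float, float],
) -> float | None:
    """Hyperscore of a candidate against a spectrum; None when nothing matches."""
    b, y = fragment_ions(cand.sequence, cand.mods)
    mz = spectrum.mz
    inten = spectrum.intensity
    if len(mz) == 0:
        return None
    lo, hi = frag_range
    total = 0.0
    counts = []
    for ions in (b, y):
        ions = ions[(ions >= lo) & (ions <= hi)]
        n_matched = 0
        for ion in ions:
            i = np.searchsorted(mz, ion)
            w = frag_tol.window(ion)
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(mz) and abs(mz[j] - ion) <= w:
                    if best is None or abs(mz[j] - ion) < abs(mz[best] - ion):
                        best = j
            if best is not None:
                n_matched += 1
                total += inten[best]
        counts.append(n_matched)
    nb, ny = counts
    if nb + ny == 0 or total <= 0:
        return None
    return (
        math.log(total)
        + math.lgamma(min(nb, _FACTORIAL_CAP) + 1)
        + math.lgamma(min(ny, _FACTORIAL_CAP) + 1)
    )


def search(
    spectra: SpectrumSet,
    db: list[ProteinRecord],
    params: SearchParameters,
    alpha: float = 0.01,
    index: PeptideIndex | None = None,
) -> SearchResult:
    """Run the built-in engine over ``spectra`` against a decoy-appended ``db``.

    For each spectrum the best-hyperscore candidate whose modified precursor
    mass fits the precursor tolerance is kept (ties: longer peptide, then
    lexicographically smaller). The PSM list is then gated at ``alpha`` FDR
    by :func:`estimate_fdr_threshold`.
    """
    if not db:
        raise ValueError("empty protein database")
    if index is None:
        index = PeptideIndex(db, params)
    psms: list[PSM] = []
    for spectrum in spectra:
        charge = spectrum.precursor_charge or 1
        neutral = spectrum.precursor_mz * charge - charge * PROTON
        half = params.precursor_tolerance.window(neutral)
        best: tuple[float, int, str] | None = None
        best_cand: _Candidate | None = None
        for cand in index.in_window(neutral, half):
            score = _score_candidate(
                spectrum, cand, params.fragment_tolerance, params.fragment_mz_range
            )
            if score is None:
                continue
            key = (score, len(cand.sequence), _neg_lex(cand.sequence))
            if best is None or key > best:
                best = key
                best_cand = cand
        if best_cand is not None and best is not None:
            psms.append(
                PSM(
                    spectrum_id=spectrum.spectrum_id,
                    peptide=format_peptide(best_cand.sequence, best_cand.mods),
                    protein_accessions=best_cand.accessions,
                    hyperscore=best[0],
                    is_decoy=best_cand.is_decoy,
                    charge=charge,
                )
            )
    threshold, validated = estimate_fdr_threshold(psms, alpha=alpha) if psms else (None, [])
    return SearchResult(parameters=params, psms=psms, fdr_threshold=threshold, validated=validated)


class _NegLex(str):
    """Reverses lexicographic comparison so max() prefers the smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _neg_lex(s: str) -> _NegLex:
    return _NegLex(s)


class BuiltinEngine:
    """The in-package hyperscore engine behind the :class:`SearchEngine` contract."""

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def run(
        self, spectra: SpectrumSet, db: list[ProteinRecord], params: SearchParameters
    ) -> SearchResult:
        return search(spectra, db, params, alpha=self.alpha)


def estimate_fdr_threshold(
    psms: list[PSM], alpha: float = 0.01
) -> tuple[float | None, list[PSM]]:
    """Target-decoy score threshold for a given FDR level.

    FDR(s) = #{decoy >= s} / max(1, #{target >= s}); the threshold is the
    smallest observed score with FDR <= alpha and the validated list holds
    the target PSMs at or above it. When no score qualifies the validated
    list is empty and the threshold is None.
    """
    if not psms:
        raise ValueError("no PSMs to threshold")
    scores = np.array([p.hyperscore for p in psms])
    is_decoy = np.array([p.is_decoy for p in psms])
    order = np.argsort(scores)  # ascending
    sorted_scores = scores[order]
    sorted_decoy = is_decoy[order]
    n = len(psms)
    # counting from the top: suffix sums of decoys/targets at >= each score
    decoys_ge = np.cumsum(sorted_decoy[::-1])[::-1]
    targets_ge = np.arange(n, 0, -1) - decoys_ge
    # with tied scores only the first occurrence counts every PSM with >= s
    uniq_scores, first_idx = np.unique(sorted_scores, return_index=True)
    fdr = decoys_ge[first_idx] / np.maximum(1, targets_ge[first_idx])
    ok = np.nonzero(fdr <= alpha)[0]
    if len(ok) == 0:
        return None, []
    threshold = float(uniq_scores[ok[0]])
    validated = [p for p in psms if not p.is_decoy and p.hyperscore >= threshold]
    return threshold, validated


def psms_to_table(result: SearchResult) -> pd.DataFrame:
    """Flatten a search result into the PSM TSV schema."""
    validated_ids = {id(p) for p in result.validated}
    rows = [
        (
            p.spectrum_id,
            p.peptide,
            ";".join(sorted(p.protein_accessions)),
            p.hyperscore,
            p.is_decoy,
            id(p) in validated_ids,
        )
        for p in result.psms
    ]
    return pd.DataFrame(
        rows,
        columns=["spectrum_id", "peptide", "accessions", "hyperscore", "is_decoy", "validated"],
    )


def write_psm_tsv(result: SearchResult, path: str | Path) -> Path:
    psms_to_table(result).to_csv(path, sep="\t", index=False)
    return Path(path)
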