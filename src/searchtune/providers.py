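"""Built-in tag-confidence and de novo providers.

Real deployments of this kind of pipeline call external tools for the two
evidence streams: a sequence tagger that scores whether a spectrum carries a
readable amino-acid ladder, and a de novo sequencer that proposes peptide
strings from the ladder. Both are modeled here as pluggable contracts plus
self-contained reference implementations so the pipeline has no external
binaries: the tagger counts length-3 residue-mass ladder paths between peaks
and converts the count to a Poisson-tail e-value; the de novo provider
either reads back planted ground truth (exact mode, for synthetic data) or
greedily assembles the longest consecutive-gap ladder (noisy mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .chem import DISTINCT_RESIDUE_MASSES, RESIDUE_MASSES
from .dbreduce import DeNovoPeptide
from .spectra_io import Spectrum, SpectrumSet
from .subsetting import TagConfidence

# residue-mass span the tag scorer's null model integrates over
_MASS_LO = float(DISTINCT_RESIDUE_MASSES.min())
_MASS_HI = float(DISTINCT_RESIDUE_MASSES.max())

_MASS_TO_AA = {}
for aa, m in RESIDUE_MASSES.items():
    if aa != "I":  # I/L ambiguous: report L
        _MASS_TO_AA[round(m, 5)] = aa


class TagProvider(Protocol):
    """Contract: best-sequence-tag confidence for each spectrum."""

    def tag(self, spectra: SpectrumSet) -> list[TagConfidence]: ...


class DeNovoProvider(Protocol):
    """Contract: candidate peptide sequences for each spectrum."""

    def sequence(self, spectra: SpectrumSet) -> list[DeNovoPeptide]: ...


def _gap_edges(mz: np.ndarray, tol: float) -> list[tuple[int, int, str]]:
    """Ordered peak pairs whose m/z gap equals a residue mass within ``tol``."""
    edges = []
    n = len(mz)
    for i in range(n):
        for j in range(i + 1, n):
            gap = mz[j] - mz[i]
            if gap > _MASS_HI + tol:
                break
            if gap < _MASS_LO - tol:
                continue
            k = np.searchsorted(DISTINCT_RESIDUE_MASSES, gap)
            for kk in (k - 1, k):
                if 0 <= kk < len(DISTINCT_RESIDUE_MASSES) and abs(
                    DISTINCT_RESIDUE_MASSES[kk] - gap
                ) <= tol:
                    edges.append((i, j, _MASS_TO_AA[round(float(DISTINCT_RESIDUE_MASSES[kk]), 5)]))
                    break
    return edges


@dataclass
class LadderTagProvider:
    """Score spectra by counting length-3 residue-ladder paths.

    A "tag" is a path of three consecutive residue-mass gaps (four peaks).
    The e-value is the Poisson upper-tail probability of observing at least
    the counted number of such paths under a null model where peaks are
    uniformly spread over the observed m/z range; spectra with no tag at all
    get e-value 1.0.
    """

    tolerance_da: float = 0.02
    tag_length: int = 3

    def tag_one(self, spectrum: Spectrum) -> TagConfidence:
        mz = spectrum.mz
        n = len(mz)
        if n < self.tag_length + 1:
            return TagConfidence(spectrum.spectrum_id, 1.0, "")
        edges = _gap_edges(mz, self.tolerance_da)
        # count paths of tag_length consecutive edges by dynamic programming
        succ: dict[int, list[tuple[int, str]]] = {}
        for i, j, aa in edges:
            succ.setdefault(i, []).append((j, aa))
        count = 0
        best_tag = ""
        for _, j0, aa0 in edges:
            # depth-limited DFS from the edge's target peak; each path is
            # counted once via its unique first edge
            stack = [(j0, aa0, 1)]
            while stack and count < 10_000:
                node, tag, depth = stack.pop()
                if depth == self.tag_length:
                    count += 1
                    if not best_tag:
                        best_tag = tag
                    continue
                for nxt, aa in succ.get(node, []):
                    stack.append((nxt, tag + aa, depth + 1))
        if count == 0:
            return TagConfidence(spectrum.spectrum_id, 1.0, "")
        lam = self._null_rate(spectrum)
        e_value = float(stats.poisson.sf(count - 1, lam))
        return TagConfidence(spectrum.spectrum_id, e_value, best_tag)

    def _null_rate(self, spectrum: Spectrum) -> float:
        """Expected number of random length-3 ladder paths in this spectrum."""
        mz = spectrum.mz
        n = len(mz)
        span = max(float(mz[-1] - mz[0]), 1.0)
        n_masses = len(DISTINCT_RESIDUE_MASSES)
        # expected residue-matching continuations per peak
        per_peak = n * n_masses * 2 * self.tolerance_da / span
        return max(n * per_peak**self.tag_length, 1e-12)

    def tag(self, spectra: SpectrumSet) -> list[TagConfidence]:
        return [self.tag_one(s) for s in spectra]


@dataclass
class ExactDeNovoProvider:
    """Read planted peptides back from a synthetic ground-truth table.

    Synthetic stand-in for an external de novo sequencer; the table must
    have columns ``spectrum_id`` and ``peptide`` (unmodified sequence).
    """

    ground_truth: pd.DataFrame

    def sequence(self, spectra: SpectrumSet) -> list[DeNovoPeptide]:
        ids = set(spectra.ids())
        out = []
        for row in self.ground_truth.itertuples(index=False):
            if row.spectrum_id in ids:
                out.append(DeNovoPeptide(row.spectrum_id, row.peptide, 1.0))
        return out


@dataclass
class LadderDeNovoProvider:
    """Greedy partial de novo: longest chain of consecutive residue gaps.

    Walks the gap graph from every peak and keeps the longest residue chain.
    The chain is emitted in both orientations (a chain over y ions reads the
    peptide backwards), each as a candidate peptide; chains shorter than
    ``min_length`` residues are discarded as uninformative.
    """

    tolerance_da: float = 0.02
    min_length: int = 5

    def sequence_one(self, spectrum: Spectrum) -> list[DeNovoPeptide]:
        mz = spectrum.mz
        if len(mz) < self.min_length + 1:
            return []
        edges = _gap_edges(mz, self.tolerance_da)
        succ: dict[int, list[tuple[int, str]]] = {}
        for i, j, aa in edges:
            succ.setdefault(i, []).append((j, aa))
        best = ""
        memo: dict[int, str] = {}

        def longest_from(node: int) -> str:
            if node in memo:
                return memo[node]
            best_local = ""
            for nxt, aa in succ.get(node, []):
                cand = aa + longest_from(nxt)
                if len(cand) > len(best_local):
                    best_local = cand
            memo[node] = best_local
            return best_local

        for node in list(succ):
            chain = longest_from(node)
            if len(chain) > len(best):
                best = chain
        if len(best) < self.min_length:
            return []
        score = float(len(best))
        return [
            DeNovoPeptide(spectrum.spectrum_id, best, score),
            DeNovoPeptide(spectrum.spectrum_id, best[::-1], score),
        ]

    def sequence(self, spectra: SpectrumSet) -> list[DeNovoPeptide]:
        out: list[DeNovoPeptide] = []
        for s in spectra:
            out.extend(self.sequence_one(s))
        return out
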