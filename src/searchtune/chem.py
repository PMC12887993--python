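"""Monoisotopic masses, modification table and peptide mass arithmetic.

The built-in search engine works exclusively with monoisotopic residue
masses and singly protonated b/y fragments, matching the synthetic
spectra it is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.0105646863
PROTON = 1.00727646688

#: distinct residue masses (I/L collapse), ascending — used by the tag scorer.
DISTINCT_RESIDUE_MASSES = np.array(sorted(set(RESIDUE_MASSES.values())))


@dataclass(frozen=True)
class Modification:
    """A fixed-mass residue modification.

    ``targets`` is the set of one-letter residue codes the modification can
    sit on; ``nterm_only`` restricts it to the peptide N-terminal position
    (an empty ``targets`` with ``nterm_only`` means "any N-terminal residue",
    as for acetylation).
    """

    name: str
    delta: float
    targets: frozenset[str]
    nterm_only: bool = False


MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in [
        Modification("carbamidomethyl_c", 57.02146, frozenset("C")),
        Modification("oxidation_m", 15.99491, frozenset("M")),
        Modification("deamidation_n", 0.98402, frozenset("N")),
        Modification("deamidation_q", 0.98402, frozenset("Q")),
        Modification("acetyl_nterm", 42.01057, frozenset(), nterm_only=True),
        Modification("dimethyl_k", 28.03130, frozenset("K")),
        Modification("pyroglu_e", -18.01056, frozenset("E"), nterm_only=True),
        Modification("pyroglu_q", -17.02655, frozenset("Q"), nterm_only=True),
    ]
}


def get_modification(name: str) -> Modification:
    try:
        return MODIFICATIONS[name]
    except KeyError:
        known = ", ".join(sorted(MODIFICATIONS))
        raise KeyError(f"unknown modification {name!r}; known: {known}") from None


def modification_sites(sequence: str, mod: Modification) -> list[int]:
    """0-based residue positions of ``sequence`` where ``mod`` can be placed."""
    if mod.nterm_only:
        if not mod.targets or sequence[0] in mod.targets:
            return [0]
        return []
    return [i for i, aa in enumerate(sequence) if aa in mod.targets]


def residue_deltas(sequence: str, mods: tuple[tuple[int, str], ...]) -> np.ndarray:
    """Per-residue mass deltas for a list of ``(position, mod_name)`` pairs."""
    deltas = np.zeros(len(sequence))
    for pos, name in mods:
        deltas[pos] += get_modification(name).delta
    return deltas


def peptide_mass(sequence: str, mods: tuple[tuple[int, str], ...] = ()) -> float:
    """Monoisotopic neutral mass of a (possibly modified) peptide."""
    mass = WATER + sum(RESIDUE_MASSES[aa] for aa in sequence)
    for _, name in mods:
        mass += get_modification(name).delta
    return mass


def format_peptide(sequence: str, mods: tuple[tuple[int, str], ...]) -> str:
    """Annotated peptide string, e.g. ``PEPTMIDE(oxidation_m@5)``."""
    if not mods:
        return sequence
    inner = ";".join(f"{name}@{pos + 1}" for pos, name in sorted(mods))
    return f"{sequence}({inner})"
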