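"""Representative spectrum-subset selection.

The full acquisition is cut into contiguous sections, spectra without a
confident sequence tag (e-value >= 0.01) are excluded, and each section
contributes a quota of confident spectra proportional to its confident
count (largest-remainder rounding), sampled deterministically at a
section-specific "every-n" interval. The result is a small subset that
still covers the whole run and over-represents identifiable spectra.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .spectra_io import SpectrumSet

logger = logging.getLogger(__name__)

EVALUE_CUTOFF = 0.01  # tags at or above this e-value are low-confidence


@dataclass(frozen=True)
class TagConfidence:
    """Best sequence-tag evidence for one spectrum."""

    spectrum_id: str
    e_value: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be nonnegative")


@dataclass
class Section:
    """One contiguous slice of the acquisition with its sampling plan."""

    index: int
    spectrum_ids: list[str]
    confident_ids: list[str] = field(default_factory=list)
    quota: int = 0
    sampling_interval: int | None = None


@dataclass
class SubsetPlan:
    engine: str
    total_spectra: int
    target_size: int
    sections: list[Section]


def target_subset_size(engine: str, total_spectra: int) -> int:
    """Subset size appropriate for the data-set size and search engine.

    The slower the engine, the smaller the subset it can afford: 1500
    spectra for an X!Tandem-class engine (2000 above 100,000 spectra to keep
    FDR estimation reliable on huge runs), 3000 for a Sage-class engine.
    Never exceeds the data-set size. Unknown engines get the conservative
    X!Tandem-class rule.
    """
    if total_spectra < 0:
        raise ValueError("total_spectra must be nonnegative")
    if engine == "sage":
        return min(total_spectra, 3000)
    if total_spectra > 100_000:
        return 2000
    return min(total_spectra, 1500)


def section_count(total_spectra: int) -> int:
    """Number of contiguous sections the acquisition is split into.

    Fewer than 2000 spectra: 4 sections; 2000-10,000: one section per ~500
    spectra (clamped to 4..20); above 10,000: 20 sections.
    """
    if total_spectra < 1:
        raise ValueError("total_spectra must be positive")
    if total_spectra < 2000:
        return 4
    if total_spectra > 10_000:
        return 20
    return min(20, max(4, math.ceil(total_spectra / 500)))


def partition_sections(spectra: SpectrumSet, k: int) -> list[Section]:
    """Split the acquisition into ``k`` contiguous, near-equal sections."""
    if k < 1:
        raise ValueError("section count must be >= 1")
    ids = spectra.ids()
    n = len(ids)
    if k > n:
        logger.warning("more sections (%d) than spectra (%d); some will be empty", k, n)
    base, rem = divmod(n, k)
    sections = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        sections.append(Section(index=i, spectrum_ids=ids[start : start + size]))
        start += size
    return sections


def filter_confident(tags: list[TagConfidence]) -> list[TagConfidence]:
    """Keep only high-confidence tags (e-value strictly below 0.01)."""
    return [t for t in tags if t.e_value < EVALUE_CUTOFF]


def allocate_quotas(counts: list[int], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` across section counts.

    Quotas are proportional to the confident counts, floors first, then the
    leftover units go to the largest fractional remainders (ties broken by
    lower section index). The quotas sum exactly to ``total`` and never
    exceed the per-section counts as long as ``total <= sum(counts)``.
    """
    grand = sum(counts)
    if total > grand:
        raise ValueError("cannot allocate more than the total confident count")
    if grand == 0:
        return [0] * len(counts)
    shares = [c / grand * total for c in counts]
    quotas = [math.floor(s) for s in shares]
    remainder = total - sum(quotas)
    by_frac = sorted(range(len(counts)), key=lambda i: (-(shares[i] - quotas[i]), i))
    for i in by_frac[:remainder]:
        quotas[i] += 1
    return quotas


def plan_subset(
    spectra: SpectrumSet,
    tags: list[TagConfidence],
    engine: str,
    target_size: int | None = None,
) -> SubsetPlan:
    """Build the sectioned sampling plan for the representative subset.

    Section quotas are allocated proportionally to each section's confident
    count with largest-remainder rounding (ties to the lower section index),
    so the subset preserves the sectionwise ratio of identifiable spectra.
    """
    total = len(spectra)
    if target_size is None:
        target_size = target_subset_size(engine, total)
    confident_ids = {t.spectrum_id for t in filter_confident(tags)}
    if not confident_ids:
        raise ValueError(
            "no spectra carry a confident sequence tag; the data appear "
            "untaggable — check spectral quality or the tag provider"
        )
    sections = partition_sections(spectra, section_count(total))
    for sec in sections:
        sec.confident_ids = [sid for sid in sec.spectrum_ids if sid in confident_ids]

    counts = [len(sec.confident_ids) for sec in sections]
    quotas = allocate_quotas(counts, min(target_size, sum(counts)))

    for sec, quota in zip(sections, quotas):
        sec.quota = quota
        if quota > 0:
            sec.sampling_interval = max(1, len(sec.confident_ids) // quota)
    return SubsetPlan(engine=engine, total_spectra=total, target_size=target_size, sections=sections)


def sample_subset(plan: SubsetPlan, spectra: SpectrumSet) -> SpectrumSet:
    """Execute a plan: every-n sampling of confident spectra per section.

    Within each section the confident spectra at positions 0, n, 2n, ... in
    acquisition order (n the section's sampling interval) are taken until
    the quota is filled; the output keeps acquisition order and contains
    exactly the sum of the quotas.
    """
    chosen: set[str] = set()
    for sec in plan.sections:
        if sec.quota == 0 or sec.sampling_interval is None:
            continue
        picked = sec.confident_ids[:: sec.sampling_interval][: sec.quota]
        chosen.update(picked)
    # copy so that re-assigned scan_index does not disturb the source set
    subset = [dataclasses.replace(s) for s in spectra if s.spectrum_id in chosen]
    return SpectrumSet(spectra=subset, source_name=f"{spectra.source_name}_subset")


def read_tag_tsv(path: str | Path) -> list[TagConfidence]:
    """Read a tag-confidence sidecar TSV (spectrum_id, e_value, tag)."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "tag": str})
    return [
        TagConfidence(str(r.spectrum_id), float(r.e_value), str(r.tag))
        for r in df.itertuples(index=False)
    ]


def write_tag_tsv(tags: list[TagConfidence], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(t.spectrum_id, t.e_value, t.tag) for t in tags],
        columns=["spectrum_id", "e_value", "tag"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
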