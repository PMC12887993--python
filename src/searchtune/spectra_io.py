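"""MGF peak-list reading/writing and the in-memory spectrum model.

The dialect is the plain Mascot Generic Format: ``BEGIN IONS``/``END IONS``
blocks with ``TITLE``, ``PEPMASS`` and optional ``CHARGE`` headers followed
by ``m/z intensity`` peak lines. ``TITLE`` becomes the spectrum id; when it
is absent an ``index=<scan_index>`` id is synthesized so downstream joins
always have a key.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_CHARGE_RE = re.compile(r"^(\d+)\+?$")


@dataclass
class Spectrum:
    """One MS/MS scan.

    peaks is an ``(n, 2)`` array of (m/z, intensity); rows are kept sorted
    ascending by m/z. ``precursor_charge`` may be None when the file did not
    state it — defaulting is left to the search stage.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int | None
    peaks: np.ndarray
    scan_index: int = 0

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size:
            if np.isnan(peaks).any():
                raise ValueError(f"spectrum {self.spectrum_id!r}: NaN peak values")
            if (peaks[:, 0] <= 0).any() or (peaks[:, 1] < 0).any():
                raise ValueError(
                    f"spectrum {self.spectrum_id!r}: non-positive m/z or negative intensity"
                )
            order = np.argsort(peaks[:, 0], kind="stable")
            peaks = peaks[order]
        self.peaks = peaks
        if not (self.precursor_mz > 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: precursor m/z must be positive")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SpectrumSet:
    """Ordered collection of spectra from one acquisition (file order kept)."""

    spectra: list[Spectrum] = field(default_factory=list)
    source_name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, s in enumerate(self.spectra):
            if s.spectrum_id in seen:
                raise ValueError(f"duplicate spectrum id {s.spectrum_id!r}")
            seen.add(s.spectrum_id)
            s.scan_index = i

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def ids(self) -> list[str]:
        return [s.spectrum_id for s in self.spectra]

    def by_id(self, spectrum_id: str) -> Spectrum:
        for s in self.spectra:
            if s.spectrum_id == spectrum_id:
                return s
        raise KeyError(spectrum_id)


def _parse_charge(raw: str) -> int | None:
    m = _CHARGE_RE.match(raw.strip())
    if m is None:
        raise ValueError(f"unparseable CHARGE value {raw!r}")
    return int(m.group(1))


def read_mgf(path: str | Path) -> SpectrumSet:
    """Read an MGF file into a :class:`SpectrumSet`.

    Spectra keep file order (scan_index = block order); peaks are sorted
    ascending by m/z if the file is not. A block without PEPMASS is a hard
    error naming the block index; an empty file gives an empty set with a
    logged warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    spectra: list[Spectrum] = []
    in_block = False
    block_index = -1
    title: str | None = None
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise ValueError(f"{path.name}:{lineno}: nested BEGIN IONS")
            in_block = True
            block_index += 1
            title, pepmass, charge, peaks = None, None, None, []
            continue
        if line == "END IONS":
            if not in_block:
                raise ValueError(f"{path.name}:{lineno}: END IONS outside a block")
            if pepmass is None:
                raise ValueError(
                    f"{path.name}: block {block_index} is missing PEPMASS"
                )
            sid = title if title is not None else f"index={block_index}"
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=pepmass,
                    precursor_charge=charge,
                    peaks=np.array(peaks, dtype=float).reshape(-1, 2),
                    scan_index=block_index,
                )
            )
            in_block = False
            continue
        if not in_block:
            continue  # tolerate inter-block parameter lines (e.g. global CHARGE)
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            key = key.strip().upper()
            if key == "TITLE":
                title = value.strip()
            elif key == "PEPMASS":
                pepmass = float(value.split()[0])
            elif key == "CHARGE":
                charge = _parse_charge(value)
            continue
        cols = line.split()
        mz = float(cols[0])
        inten = float(cols[1]) if len(cols) > 1 else 0.0
        peaks.append((mz, inten))

    if in_block:
        raise ValueError(f"{path.name}: block {block_index} not closed by END IONS")
    if not spectra:
        logger.warning("MGF file %s contains no spectra", path)
    return SpectrumSet(spectra=spectra, source_name=path.stem)


def write_mgf(spectra: SpectrumSet, path: str | Path) -> Path:
    """Write a :class:`SpectrumSet` as MGF (LF newlines, 6-decimal numbers).

    Zero-intensity peaks are dropped on write; everything else round-trips
    through :func:`read_mgf` to within 1e-6.
    """
    path = Path(path)
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.spectrum_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        if s.precursor_charge is not None:
            lines.append(f"CHARGE={s.precursor_charge}+")
        for mz, inten in s.peaks:
            if inten == 0.0:
                continue
            lines.append(f"{mz:.6f} {inten:.6f}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8", newline="\n")
    return path
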