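"""Greedy ordered multi-parameter optimization and the end-to-end pipeline.

Parameters are tuned one at a time in a configured order: for each parameter
a reference search runs with its default value under the currently chosen
settings, one test search runs per alternative candidate, every test is
compared to the reference by CScore, and the best strictly positive
candidate wins (the default is sticky otherwise). Each chosen value is
folded into the current settings before the next parameter — parameters with
a large effect are therefore placed early in the shipped order (digestion
first, then tolerances, then modifications), since early mistakes compound.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .cscore import CScoreBreakdown, cscore
from .dbreduce import (
    ProteinRecord,
    append_decoys,
    read_fasta,
    reduce_database,
    write_denovo_tsv,
    write_fasta,
)
from .providers import DeNovoProvider, LadderDeNovoProvider, LadderTagProvider, TagProvider
from .search_core import (
    BuiltinEngine,
    SearchEngine,
    SearchParameters,
    SearchResult,
    Tolerance,
    write_psm_tsv,
)
from .spectra_io import SpectrumSet, read_mgf, write_mgf
from .subsetting import plan_subset, sample_subset, write_tag_tsv

logger = logging.getLogger(__name__)

_KINDS = ("categorical", "numeric")
_MOD_SET_PARAMS = ("fixed_mods", "variable_mods")
_TOLERANCE_PARAMS = ("precursor_tolerance", "fragment_tolerance")
_RANGE_PARAMS = ("peptide_length_range", "fragment_mz_range")


@dataclass(frozen=True)
class ParameterSpec:
    """One tunable parameter: its kind, default, and ordered candidates."""

    name: str
    kind: str
    default: object
    candidates: tuple
    applies_to: frozenset[str] = frozenset()
    depends_on: tuple[str, ...] = ()


def canonical_value(name: str, value: object) -> object:
    """Hashable canonical form of a candidate value for comparison/reporting."""
    if name in _MOD_SET_PARAMS:
        return tuple(sorted(value))  # type: ignore[arg-type]
    if name in _TOLERANCE_PARAMS:
        v, unit = value  # type: ignore[misc]
        return (float(v), str(unit))
    if name in _RANGE_PARAMS:
        lo, hi = value  # type: ignore[misc]
        return (lo, hi)
    return value


def apply_parameter(params: SearchParameters, name: str, value: object) -> SearchParameters:
    """Return a copy of ``params`` with one named parameter set to ``value``.

    JSON-style values are coerced (mod lists to frozensets, [value, unit]
    pairs to :class:`Tolerance`); unknown names land in the open ``extra``
    map for engine-specific knobs.
    """
    if name in _MOD_SET_PARAMS:
        return params.with_value(**{name: frozenset(value)})  # type: ignore[arg-type]
    if name in _TOLERANCE_PARAMS:
        v, unit = value  # type: ignore[misc]
        return params.with_value(**{name: Tolerance(float(v), str(unit))})
    if name in _RANGE_PARAMS:
        lo, hi = value  # type: ignore[misc]
        return params.with_value(**{name: (lo, hi)})
    if name in ("enzyme", "specificity"):
        return params.with_value(**{name: str(value)})
    if name in ("max_missed_cleavages", "max_variable_mods"):
        return params.with_value(**{name: int(value)})  # type: ignore[arg-type]
    extra = dict(params.extra)
    extra[name] = value
    return params.with_value(extra=tuple(sorted(extra.items())))


def default_config_path() -> Path:
    """Path of the parameter-order configuration shipped with the package."""
    return Path(str(resources.files("searchtune") / "data" / "parameter_config.json"))


def load_parameter_config(path: str | Path | None = None, engine: str = "builtin") -> list[ParameterSpec]:
    """Load and validate the ordered parameter list for one engine.

    Hard errors name the offending parameter: unknown kind, empty candidate
    list, a default missing from the candidates, or a dependency that is not
    decided earlier in the order (which also rules out cycles).
    """
    path = default_config_path() if path is None else Path(path)
    config = json.loads(Path(path).read_text())
    if engine not in config:
        raise ValueError(f"engine {engine!r} not in config; available: {sorted(config)}")
    specs: list[ParameterSpec] = []
    seen: list[str] = []
    for entry in config[engine]:
        name = entry["name"]
        kind = entry["kind"]
        if kind not in _KINDS:
            raise ValueError(f"parameter {name!r}: unknown kind {kind!r}")
        candidates = entry["candidates"]
        if not candidates:
            raise ValueError(f"parameter {name!r}: empty candidate list")
        default = entry["default"]
        canon = [canonical_value(name, c) for c in candidates]
        if canonical_value(name, default) not in canon:
            raise ValueError(f"parameter {name!r}: default {default!r} not among candidates")
        for dep in entry.get("depends_on", []):
            if dep not in seen:
                raise ValueError(
                    f"parameter {name!r} depends on {dep!r}, which is not decided "
                    "earlier in the order"
                )
        specs.append(
            ParameterSpec(
                name=name,
                kind=kind,
                default=default,
                candidates=tuple(candidates),
                applies_to=frozenset(entry.get("applies_to", [engine])),
                depends_on=tuple(entry.get("depends_on", [])),
            )
        )
        seen.append(name)
    return specs


@dataclass
class SelectionEntry:
    """Audit record for one parameter: every candidate's breakdown, the winner."""

    name: str
    chosen: object
    breakdowns: dict[str, CScoreBreakdown | None]
    n_searches: int
    skipped: bool = False


@dataclass
class SelectionReport:
    entries: list[SelectionEntry] = field(default_factory=list)
    final_parameters: SearchParameters | None = None

    @property
    def total_searches(self) -> int:
        return sum(e.n_searches for e in self.entries)

    def to_dict(self) -> dict:
        entries = []
        for e in self.entries:
            entries.append(
                {
                    "parameter": e.name,
                    "chosen": _jsonable(e.chosen),
                    "skipped": e.skipped,
                    "n_searches": e.n_searches,
                    "candidates": {
                        key: None
                        if b is None
                        else {
                            "shared": b.shared,
                            "gained": b.gained,
                            "lost": b.lost,
                            "total": b.total,
                            "n_paired": b.n_paired,
                            "n_gained": b.n_gained,
                            "n_lost": b.n_lost,
                        }
                        for key, b in e.breakdowns.items()
                    },
                }
            )
        return {
            "entries": entries,
            "total_searches": self.total_searches,
            "final_parameters": _params_dict(self.final_parameters),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _jsonable(value: object) -> object:
    if isinstance(value, frozenset):
        return sorted(value)
    if isinstance(value, tuple):
        return list(value)
    return value


def _params_dict(params: SearchParameters | None) -> dict | None:
    if params is None:
        return None
    return {
        "enzyme": params.enzyme,
        "specificity": params.specificity,
        "max_missed_cleavages": params.max_missed_cleavages,
        "precursor_tolerance": [params.precursor_tolerance.value, params.precursor_tolerance.unit],
        "fragment_tolerance": [params.fragment_tolerance.value, params.fragment_tolerance.unit],
        "fixed_mods": sorted(params.fixed_mods),
        "variable_mods": sorted(params.variable_mods),
        "peptide_length_range": list(params.peptide_length_range),
        "fragment_mz_range": list(params.fragment_mz_range),
        "max_variable_mods": params.max_variable_mods,
        "extra": {k: _jsonable(v) for k, v in params.extra},
    }


def _candidate_key(name: str, value: object) -> str:
    return json.dumps(_jsonable(canonical_value(name, value)))


def select_parameter_value(
    spec: ParameterSpec,
    current: SearchParameters,
    spectra: SpectrumSet,
    db: list[ProteinRecord],
    engine: SearchEngine | None = None,
) -> tuple[object, SelectionEntry, SearchResult | None]:
    """Choose the best value of one parameter by reference/test CScores.

    The reference search uses the parameter's default under the current
    settings; every other candidate gets a test search. The winner is the
    candidate with the maximum strictly positive CScore total (ties: earlier
    candidate); otherwise the default is retained. A reference with fewer
    than 4 validated PSMs skips the parameter with a warning.
    """
    engine = engine or BuiltinEngine()
    ref_params = apply_parameter(current, spec.name, spec.default)
    reference = engine.run(spectra, db, ref_params)
    breakdowns: dict[str, CScoreBreakdown | None] = {}
    n_searches = 1
    default_canon = canonical_value(spec.name, spec.default)
    if len(reference.validated) < 4:
        logger.warning(
            "parameter %s: reference search validated only %d PSMs; skipping "
            "and retaining the default",
            spec.name,
            len(reference.validated),
        )
        entry = SelectionEntry(spec.name, spec.default, breakdowns, n_searches, skipped=True)
        return spec.default, entry, reference

    best_value = spec.default
    best_total = 0  # the default must be beaten strictly
    for candidate in spec.candidates:
        if canonical_value(spec.name, candidate) == default_canon:
            continue
        key = _candidate_key(spec.name, candidate)
        try:
            test = engine.run(spectra, db, apply_parameter(current, spec.name, candidate))
            n_searches += 1
            breakdown = cscore(reference, test)
        except Exception:  # noqa: BLE001 — a failed candidate must never win
            logger.exception("parameter %s: candidate %s failed; scored -inf", spec.name, key)
            breakdowns[key] = None
            n_searches += 1
            continue
        breakdowns[key] = breakdown
        if breakdown.total > best_total:
            best_total = breakdown.total
            best_value = candidate
    entry = SelectionEntry(spec.name, best_value, breakdowns, n_searches)
    return best_value, entry, reference


def optimize_all(
    specs: list[ParameterSpec],
    spectra: SpectrumSet,
    db: list[ProteinRecord],
    engine: SearchEngine | None = None,
    base_params: SearchParameters | None = None,
) -> SelectionReport:
    """Greedy ordered optimization over all parameters.

    Each parameter's chosen value is folded into the current settings before
    the next parameter is optimized, so later decisions are conditioned on
    earlier ones. The report records every candidate breakdown and the exact
    number of searches run.
    """
    engine = engine or BuiltinEngine()
    current = base_params or SearchParameters()
    report = SelectionReport()
    for spec in specs:
        chosen, entry, _ = select_parameter_value(spec, current, spectra, db, engine)
        current = apply_parameter(current, spec.name, chosen)
        report.entries.append(entry)
    report.final_parameters = current
    return report


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the pipeline stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    mgf_path: str | Path,
    fasta_path: str | Path,
    out_dir: str | Path,
    config_path: str | Path | None = None,
    engine_name: str = "builtin",
    engine: SearchEngine | None = None,
    tag_provider: TagProvider | None = None,
    denovo_provider: DeNovoProvider | None = None,
    alpha: float = 0.01,
    subset_size: int | None = None,
) -> SelectionReport:
    """End-to-end run: subset the spectra, reduce the database, optimize.

    Writes the subset MGF, tag/de-novo TSVs, the reduced decoy-appended
    FASTA, the final-parameter PSM TSV, per-parameter CScore TSVs and the
    selection-report JSON into ``out_dir``. Identical inputs yield
    byte-identical report JSON (no randomness anywhere in the pipeline).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag_provider = tag_provider or LadderTagProvider()
    denovo_provider = denovo_provider or LadderDeNovoProvider()
    engine = engine or BuiltinEngine(alpha=alpha)

    with _stage("spectra_io"):
        spectra = read_mgf(mgf_path)

    with _stage("subsetting"):
        tags = tag_provider.tag(spectra)
        write_tag_tsv(tags, out / "tags.tsv")
        plan = plan_subset(spectra, tags, engine_name, target_size=subset_size)
        subset = sample_subset(plan, spectra)
        write_mgf(subset, out / "subset.mgf")

    with _stage("dbreduce"):
        db = read_fasta(fasta_path)
        peptides = denovo_provider.sequence(subset)
        write_denovo_tsv(peptides, out / "denovo.tsv")
        reduced = reduce_database(db, peptides)
        searched_db = append_decoys(reduced)
        write_fasta(searched_db, out / "reduced_with_decoys.fasta")

    with _stage("optimizer"):
        specs = load_parameter_config(config_path, engine=engine_name if config_path else "builtin")
        report = optimize_all(specs, subset, searched_db, engine=engine)
        for entry in report.entries:
            rows = [
                (
                    key,
                    b.shared if b else None,
                    b.gained if b else None,
                    b.lost if b else None,
                    b.total if b else None,
                    b.n_paired if b else None,
                    b.n_gained if b else None,
                    b.n_lost if b else None,
                )
                for key, b in entry.breakdowns.items()
            ]
            pd.DataFrame(
                rows,
                columns=[
                    "candidate", "shared", "gained", "lost", "total",
                    "n_paired", "n_gained", "n_lost",
                ],
            ).to_csv(out / f"cscore_{entry.name}.tsv", sep="\t", index=False)
        assert report.final_parameters is not None
        final_result = engine.run(subset, searched_db, report.final_parameters)
        write_psm_tsv(final_result, out / "final_psms.tsv")
        (out / "selection_report.json").write_text(report.to_json())

    return report
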