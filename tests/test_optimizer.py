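"""Parameter-config loading, greedy value selection and the full pipeline."""

import json

import pytest

import searchtune as st
from searchtune.optimizer import apply_parameter, canonical_value

from conftest import gated_result


class TestLoadParameterConfig:
    def test_shipped_config_order(self):
        specs = st.load_parameter_config()
        names = [s.name for s in specs]
        assert names.index("enzyme") < names.index("specificity") < names.index(
            "max_missed_cleavages"
        )
        assert names.index("variable_mods") < names.index("max_variable_mods")

    def test_dependency_must_be_decided_earlier(self, tmp_path):
        config = {
            "builtin": [
                {"name": "max_variable_mods", "kind": "numeric", "default": 2,
                 "candidates": [1, 2], "depends_on": ["variable_mods"]},
                {"name": "variable_mods", "kind": "categorical", "default": [],
                 "candidates": [[]], "depends_on": []},
            ]
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(config))
        with pytest.raises(ValueError, match="max_variable_mods"):
            st.load_parameter_config(path)

    @pytest.mark.parametrize(
        "entry,match",
        [
            ({"name": "p", "kind": "weird", "default": 1, "candidates": [1]}, "kind"),
            ({"name": "p", "kind": "numeric", "default": 1, "candidates": []}, "empty"),
            ({"name": "p", "kind": "numeric", "default": 9, "candidates": [1, 2]}, "default"),
        ],
    )
    def test_invalid_entries_name_the_parameter(self, tmp_path, entry, match):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"builtin": [entry]}))
        with pytest.raises(ValueError, match=match):
            st.load_parameter_config(path)

    def test_unknown_engine_errors(self):
        with pytest.raises(ValueError, match="engine"):
            st.load_parameter_config(engine="nope")


class TestApplyParameter:
    def test_known_names_are_coerced(self):
        p = st.SearchParameters()
        p = apply_parameter(p, "precursor_tolerance", [50, "ppm"])
        assert p.precursor_tolerance == st.Tolerance(50.0, "ppm")
        p = apply_parameter(p, "fixed_mods", ["carbamidomethyl_c"])
        assert p.fixed_mods == frozenset({"carbamidomethyl_c"})
        p = apply_parameter(p, "peptide_length_range", [5, 25])
        assert p.peptide_length_range == (5, 25)

    def test_unknown_names_go_to_extra(self):
        p = apply_parameter(st.SearchParameters(), "minimum_ion_index", 3)
        assert dict(p.extra)["minimum_ion_index"] == 3

    def test_canonical_value_equates_json_forms(self):
        assert canonical_value("fixed_mods", ["b", "a"]) == canonical_value(
            "fixed_mods", ("a", "b")
        )
        assert canonical_value("precursor_tolerance", [10, "ppm"]) == (10.0, "ppm")


class FakeEngine:
    """Engine whose CScore landscape is dictated by a 'knob' extra parameter.

    The reference (knob=A) validates 8 PSMs scoring 1..8; other knob values
    add/remove unique PSMs so that cscore totals hit preset values.
    """

    def __init__(self, totals):
        self.totals = totals  # knob value -> desired cscore total

    def run(self, spectra, db, params):
        knob = dict(params.extra).get("knob", "A")
        base_ids = [f"r{i}" for i in range(8)]
        base_scores = list(range(1, 9))  # quartiles 2.75 / 4.5 / 6.25
        total = self.totals[knob]
        ids, scores = list(base_ids), list(base_scores)
        if total > 0:
            k4, k1 = divmod(total, 4)
            ids += [f"g{i}" for i in range(k4)] + [f"h{i}" for i in range(k1)]
            scores += [7.0] * k4 + [1.0] * k1  # rank 4 and rank 1 gains
        elif total < 0:
            # drop top-ranked reference PSMs (rank 4 each) and rank-1 ones
            k4, k1 = divmod(-total, 4)
            drop = [f"r{7 - i}" for i in range(k4)] + [f"r{i}" for i in range(k1)]
            keep = [(i, s) for i, s in zip(ids, scores) if i not in drop]
            ids, scores = [i for i, _ in keep], [s for _, s in keep]
        return gated_result(scores, ids=ids, params=params)


def knob_spec(candidates=("A", "B", "C"), default="A"):
    return st.ParameterSpec(
        name="knob", kind="categorical", default=default, candidates=tuple(candidates)
    )


class TestSelectParameterValue:
    def test_max_positive_total_wins(self):
        engine = FakeEngine({"A": 0, "B": 41, "C": -5})
        chosen, entry, _ = st.select_parameter_value(
            knob_spec(), st.SearchParameters(), st.SpectrumSet(), [None], engine
        )
        assert chosen == "B"
        assert entry.breakdowns['"B"'].total == 41
        assert entry.breakdowns['"C"'].total == -5

    def test_all_nonpositive_keeps_default(self):
        engine = FakeEngine({"A": 0, "B": -3, "C": 0})
        chosen, _, _ = st.select_parameter_value(
            knob_spec(), st.SearchParameters(), st.SpectrumSet(), [None], engine
        )
        assert chosen == "A"

    def test_tie_broken_by_candidate_order(self):
        engine = FakeEngine({"A": 0, "B": 10, "C": 10})
        chosen, _, _ = st.select_parameter_value(
            knob_spec(), st.SearchParameters(), st.SpectrumSet(), [None], engine
        )
        assert chosen == "B"

    def test_small_reference_skips_with_default(self, caplog):
        class TinyEngine:
            def run(self, spectra, db, params):
                return gated_result([1.0, 2.0], ids=["a", "b"])

        with caplog.at_level("WARNING"):
            chosen, entry, _ = st.select_parameter_value(
                knob_spec(), st.SearchParameters(), st.SpectrumSet(), [None], TinyEngine()
            )
        assert chosen == "A"
        assert entry.skipped
        assert any("skipping" in r.message for r in caplog.records)

    def test_failing_candidate_never_wins(self):
        class FlakyEngine(FakeEngine):
            def run(self, spectra, db, params):
                if dict(params.extra).get("knob") == "B":
                    raise RuntimeError("engine crashed")
                return super().run(spectra, db, params)

        engine = FlakyEngine({"A": 0, "B": 99, "C": 7})
        chosen, entry, _ = st.select_parameter_value(
            knob_spec(), st.SearchParameters(), st.SpectrumSet(), [None], engine
        )
        assert chosen == "C"
        assert entry.breakdowns['"B"'] is None


class TestOptimizeAll:
    def test_empty_specs_is_identity(self):
        report = st.optimize_all([], st.SpectrumSet(), [None], FakeEngine({"A": 0}))
        assert report.entries == []
        assert report.final_parameters == st.SearchParameters()

    def test_search_count_bookkeeping(self):
        engine = FakeEngine({"A": 0, "B": 5, "C": -1})
        specs = [knob_spec(), knob_spec()]
        report = st.optimize_all(specs, st.SpectrumSet(), [None], engine)
        # per parameter: 1 reference + 2 test searches
        assert report.total_searches == 6
        assert [e.n_searches for e in report.entries] == [3, 3]

    def test_chosen_value_folds_into_next_reference(self):
        seen = []

        class RecordingEngine(FakeEngine):
            def run(self, spectra, db, params):
                seen.append(dict(params.extra).get("knob", "A"))
                return super().run(spectra, db, params)

        engine = RecordingEngine({"A": 0, "B": 5, "C": -1})
        st.optimize_all(
            [knob_spec(), st.ParameterSpec("other", "numeric", 1, (1, 2))],
            st.SpectrumSet(),
            [None],
            engine,
        )
        # after knob=B wins, the second parameter's searches all run with B
        assert seen[3:] == ["B", "B"]


class TestParameterRecovery:
    def test_lysc_digest_recovered_under_strict_search(self):
        """A Lys-C-digested acquisition searched with no missed cleavages:
        the optimizer must switch the enzyme from the trypsin default.
        (With missed cleavages allowed, tryptic digestion legitimately covers
        Lys-C peptides — internal arginines just count as missed sites — so
        the strict base search is what makes the enzyme effect visible.)"""
        cfg = st.SyntheticConfig(true_enzyme="lys-c", n_spectra=80, seed=41)
        proteome = st.generate_proteome(cfg)
        spectra, _ = st.generate_spectra(cfg, proteome)
        db = st.append_decoys(proteome)
        report = st.optimize_all(
            [st.ParameterSpec("enzyme", "categorical", "trypsin", ("trypsin", "lys-c", "chymotrypsin"))],
            spectra,
            db,
            base_params=st.SearchParameters(max_missed_cleavages=0),
        )
        assert report.entries[0].chosen == "lys-c"

    def test_planted_enzyme_recovered(self):
        from conftest import RECOVERY_SPECS, make_recovery_world

        proteome, spectra = make_recovery_world(seed=100)
        db = st.append_decoys(proteome)
        report = st.optimize_all([RECOVERY_SPECS[0]], spectra, db)
        assert report.entries[0].chosen == "chymotrypsin"

    def test_order_robust_for_separable_parameters(self):
        from conftest import RECOVERY_SPECS, make_recovery_world

        enzyme_spec, _, fixed_spec = RECOVERY_SPECS
        proteome, spectra = make_recovery_world(seed=100)
        db = st.append_decoys(proteome)
        fwd = st.optimize_all([enzyme_spec, fixed_spec], spectra, db)
        rev = st.optimize_all([fixed_spec, enzyme_spec], spectra, db)
        assert fwd.final_parameters.enzyme == rev.final_parameters.enzyme == "chymotrypsin"
        assert (
            fwd.final_parameters.fixed_mods
            == rev.final_parameters.fixed_mods
            == frozenset({"carbamidomethyl_c"})
        )


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory):
    root = tmp_path_factory.mktemp("pipeline")
    cfg = st.SyntheticConfig(true_variable_mods=frozenset({"oxidation_m"}), seed=23)
    proteome = st.generate_proteome(cfg)
    spectra, truth = st.generate_spectra(cfg, proteome)
    mgf = st.write_mgf(spectra, root / "run.mgf")
    fasta = st.write_fasta(proteome, root / "db.fasta")
    return root, mgf, fasta, truth


class TestRunPipeline:
    def test_end_to_end_artifacts_and_recovery(self, pipeline_inputs):
        root, mgf, fasta, truth = pipeline_inputs
        report = st.run_pipeline(mgf, fasta, root / "out", denovo_provider=st.ExactDeNovoProvider(truth))
        for name in ("subset.mgf", "reduced_with_decoys.fasta", "final_psms.tsv",
                     "selection_report.json", "cscore_enzyme.tsv", "tags.tsv"):
            assert (root / "out" / name).exists()
        # planted variable modification is recovered
        assert "oxidation_m" in report.final_parameters.variable_mods
        # exact bookkeeping: every search accounted for
        assert report.total_searches == sum(e.n_searches for e in report.entries)

    def test_rerun_is_byte_identical(self, pipeline_inputs):
        root, mgf, fasta, truth = pipeline_inputs
        st.run_pipeline(mgf, fasta, root / "out_a", denovo_provider=st.ExactDeNovoProvider(truth))
        st.run_pipeline(mgf, fasta, root / "out_b", denovo_provider=st.ExactDeNovoProvider(truth))
        a = (root / "out_a" / "selection_report.json").read_bytes()
        b = (root / "out_b" / "selection_report.json").read_bytes()
        assert a == b

    def test_stage_errors_name_the_stage(self, pipeline_inputs, tmp_path):
        root, mgf, _, _ = pipeline_inputs
        empty_fasta = tmp_path / "empty.fasta"
        empty_fasta.write_text(">p PE=2 SV=1\nAAAA\n")
        with pytest.raises(RuntimeError, match=r"\[dbreduce\]"):
            st.run_pipeline(mgf, empty_fasta, tmp_path / "out")
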