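"""Digestion, hyperscore search and target-decoy FDR gating."""

import numpy as np
import pytest

import searchtune as st
from searchtune.search_core import ENZYME_RULES, PeptideIndex

from conftest import make_psm


def brute_digest(seq, enzyme, specificity, max_missed, length_range):
    """Independent enumeration oracle over all substrings."""
    after, blocked = ENZYME_RULES[enzyme]
    sites = {
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in after and seq[i + 1] not in blocked
    }
    valid = {0, len(seq)} | sites
    lo, hi = length_range
    out = set()
    for a in range(len(seq)):
        for b in range(a + 1, len(seq) + 1):
            nt, ct = a in valid, b in valid
            if specificity == "specific" and not (nt and ct):
                continue
            if specificity == "semi" and not (nt or ct):
                continue
            if sum(1 for s in sites if a < s < b) > max_missed:
                continue
            if lo <= b - a <= hi:
                out.add(seq[a:b])
    return out


class TestDigest:
    def test_tryptic_worked_example(self):
        assert set(st.digest("AKRB", "trypsin", "specific", 0, (1, 10))) == {"AK", "R", "B"}

    def test_missed_cleavage_adds_runs(self):
        got = set(st.digest("AKRB", "trypsin", "specific", 1, (1, 10)))
        assert got == {"AK", "R", "B", "AKR", "RB"}

    def test_no_enzyme_enumerates_substrings(self):
        assert set(st.digest("ABCD", "no-enzyme", "specific", 0, (2, 3))) == {
            "AB", "BC", "CD", "ABC", "BCD",
        }

    def test_unknown_enzyme_lists_supported(self):
        with pytest.raises(ValueError, match="trypsin"):
            st.digest("PEPTIDEK", "pepsin", "specific", 0, (1, 10))

    @pytest.mark.parametrize("enzyme", ["trypsin", "lys-c", "chymotrypsin", "glu-c"])
    @pytest.mark.parametrize("specificity", ["specific", "semi"])
    @pytest.mark.parametrize("max_missed", [0, 2])
    def test_against_brute_force_oracle(self, enzyme, specificity, max_missed):
        rng = np.random.default_rng(42)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            got = set(st.digest(seq, enzyme, specificity, max_missed, (2, 12)))
            want = brute_digest(seq, enzyme, specificity, max_missed, (2, 12))
            assert got == want

    def test_proline_blocks_tryptic_cleavage(self):
        assert set(st.digest("AKPA", "trypsin", "specific", 0, (1, 10))) == {"AKPA"}


class TestSearch:
    def test_planted_peptide_is_top_psm(self, clean_world):
        cfg, proteome, spectra, truth = clean_world
        db = st.append_decoys(proteome)
        params = st.SearchParameters(max_missed_cleavages=0, peptide_length_range=(7, 20))
        result = st.search(spectra, db, params)
        by_id = {p.spectrum_id: p for p in result.psms}
        hits = sum(
            1
            for row in truth.itertuples(index=False)
            if row.spectrum_id in by_id and by_id[row.spectrum_id].peptide == row.modified_peptide
        )
        assert hits / len(truth) >= 0.95

    def test_unmatchable_precursor_gives_no_psm(self, clean_world):
        _, proteome, _, _ = clean_world
        db = st.append_decoys(proteome)
        s = st.Spectrum("odd", 5000.0, 1, np.array([[200.0, 10.0]]), 0)
        result = st.search(st.SpectrumSet(spectra=[s]), db, st.SearchParameters())
        assert result.psms == []

    def test_wider_fragment_tolerance_increases_decoy_psms(self):
        # noisy fixture: half the spectra are pure noise; a Da-level
        # precursor window guarantees they have candidates to mis-match
        cfg = st.SyntheticConfig(
            fragment_noise_peaks=40,
            mass_jitter_ppm=10,
            fraction_untaggable=0.5,
            n_spectra=80,
            seed=9,
        )
        proteome = st.generate_proteome(cfg)
        spectra, _ = st.generate_spectra(cfg, proteome)
        db = st.append_decoys(proteome)
        precursor = st.Tolerance(2.0, "Da")
        tight = st.search(
            spectra, db, st.SearchParameters(precursor_tolerance=precursor)
        )
        loose = st.search(
            spectra,
            db,
            st.SearchParameters(
                precursor_tolerance=precursor,
                fragment_tolerance=st.Tolerance(2.0, "Da"),  # 100x the 0.02 default
            ),
        )
        n_tight = sum(p.is_decoy for p in tight.psms)
        n_loose = sum(p.is_decoy for p in loose.psms)
        assert n_loose > n_tight

    def test_empty_db_errors(self, default_world):
        _, _, spectra, _ = default_world
        with pytest.raises(ValueError, match="empty"):
            st.search(spectra, [], st.SearchParameters())

    def test_determinism(self, default_world):
        _, proteome, spectra, _ = default_world
        db = st.append_decoys(proteome)
        a = st.search(spectra, db, st.SearchParameters())
        b = st.search(spectra, db, st.SearchParameters())
        assert [(p.spectrum_id, p.peptide, p.hyperscore) for p in a.psms] == [
            (p.spectrum_id, p.peptide, p.hyperscore) for p in b.psms
        ]
        assert a.fdr_threshold == b.fdr_threshold

    def test_shared_target_decoy_counts_as_target(self, clean_world):
        _, proteome, _, _ = clean_world
        db = st.append_decoys(proteome)
        index = PeptideIndex(db, st.SearchParameters(enzyme="no-enzyme", peptide_length_range=(4, 4)))
        # palindromic 4-mers appear in both orientations; any candidate shared
        # with its decoy must be labeled target
        for cand in index.candidates:
            if any(a.startswith("DECOY_") for a in cand.accessions) and any(
                not a.startswith("DECOY_") for a in cand.accessions
            ):
                assert not cand.is_decoy


def brute_threshold(psms, alpha):
    """Exhaustive scan over every observed score."""
    for s in sorted({p.hyperscore for p in psms}):
        d = sum(1 for p in psms if p.is_decoy and p.hyperscore >= s)
        t = sum(1 for p in psms if not p.is_decoy and p.hyperscore >= s)
        if d / max(1, t) <= alpha:
            return s
    return None


class TestFDRThreshold:
    def test_well_separated_validates_all_targets(self):
        psms = st.generate_psm_tables(200, 2, ((40.0, 1.0), (5.0, 1.0)), seed=1)
        threshold, validated = st.estimate_fdr_threshold(psms)
        assert len(validated) == 200
        assert all(not p.is_decoy for p in validated)

    def test_zero_decoys_validates_everything(self):
        psms = [make_psm(f"s{i}", 10 + i) for i in range(5)]
        threshold, validated = st.estimate_fdr_threshold(psms)
        assert threshold == 10
        assert len(validated) == 5

    def test_all_decoys_above_targets_validates_nothing(self):
        psms = [make_psm(f"t{i}", 5 + i) for i in range(10)] + [
            make_psm(f"d{i}", 100 + i, decoy=True) for i in range(10)
        ]
        threshold, validated = st.estimate_fdr_threshold(psms)
        assert threshold is None
        assert validated == []

    def test_tied_scores_counted_correctly(self):
        # a decoy tied with the lone target: FDR at that score is 1, not 0
        psms = [make_psm("t", 5.0), make_psm("d", 5.0, decoy=True)]
        threshold, validated = st.estimate_fdr_threshold(psms, alpha=0.5)
        assert validated == []

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            st.estimate_fdr_threshold([])

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_d = int(rng.integers(5, 400)), int(rng.integers(5, 400))
        psms = st.generate_psm_tables(
            n_t, n_d, ((rng.uniform(15, 30), 4.0), (rng.uniform(10, 25), 4.0)), seed=seed
        )
        threshold, validated = st.estimate_fdr_threshold(psms)
        assert threshold == brute_threshold(psms, 0.01)
        if validated:
            d = sum(1 for p in psms if p.is_decoy and p.hyperscore >= threshold)
            t = sum(1 for p in psms if not p.is_decoy and p.hyperscore >= threshold)
            assert d / max(1, t) <= 0.01
            assert len(validated) == t
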