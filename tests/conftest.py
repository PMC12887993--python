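import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import searchtune as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# The separable parameter-recovery world: a chymotryptic acquisition with
# carbamidomethylated cysteines and 15 ppm precursor jitter, over a smaller
# tryptic background (so the trypsin-default reference search stays viable).
# Each tuned parameter has one unambiguous correct grid point: chymotrypsin,
# 50 ppm (~3.3 sigma of the planted jitter) and carbamidomethyl C.
RECOVERY_SPECS = [
    st.ParameterSpec("enzyme", "categorical", "trypsin", ("trypsin", "lys-c", "chymotrypsin")),
    st.ParameterSpec(
        "precursor_tolerance", "numeric", [10, "ppm"], ([5, "ppm"], [10, "ppm"], [50, "ppm"])
    ),
    st.ParameterSpec("fixed_mods", "categorical", (), ((), ("carbamidomethyl_c",))),
]

RECOVERY_TRUTH = {
    "enzyme": "chymotrypsin",
    "precursor_tolerance": st.Tolerance(50.0, "ppm"),
    "fixed_mods": frozenset({"carbamidomethyl_c"}),
}


def make_recovery_world(seed):
    """Build one replicate of the separable recovery fixture."""
    cfg_major = st.SyntheticConfig(
        true_enzyme="chymotrypsin",
        true_fixed_mods=frozenset({"carbamidomethyl_c"}),
        n_spectra=120,
        mass_jitter_ppm=15.0,
        seed=seed,
    )
    cfg_minor = dataclasses.replace(cfg_major, true_enzyme="trypsin", n_spectra=40, seed=seed + 1000)
    proteome = st.generate_proteome(cfg_major)
    major, _ = st.generate_spectra(cfg_major, proteome)
    minor, _ = st.generate_spectra(cfg_minor, proteome)
    spectra = st.SpectrumSet(
        spectra=[dataclasses.replace(s, spectrum_id="c:" + s.spectrum_id) for s in major]
        + [dataclasses.replace(s, spectrum_id="t:" + s.spectrum_id) for s in minor]
    )
    return proteome, spectra


@pytest.fixture(scope="session")
def default_world():
    """Default synthetic acquisition: proteome, spectra and ground truth."""
    cfg = st.SyntheticConfig()
    proteome = st.generate_proteome(cfg)
    spectra, truth = st.generate_spectra(cfg, proteome)
    return cfg, proteome, spectra, truth


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free, jitter-free world where the engine must be exact."""
    cfg = st.SyntheticConfig(
        fragment_noise_peaks=0, mass_jitter_ppm=0.0, fraction_untaggable=0.0, seed=7
    )
    proteome = st.generate_proteome(cfg)
    spectra, truth = st.generate_spectra(cfg, proteome)
    return cfg, proteome, spectra, truth


def make_spectrum(sid="s0", peaks=None, precursor=500.0, charge=1, index=0):
    peaks = peaks if peaks is not None else [(100.0, 10.0), (200.0, 20.0)]
    return st.Spectrum(sid, precursor, charge, np.array(peaks, dtype=float), index)


def make_spectrum_set(n, prefix="s"):
    return st.SpectrumSet(
        spectra=[make_spectrum(f"{prefix}{i}", index=i) for i in range(n)]
    )


def make_psm(sid, score, decoy=False, peptide="PEPTIDEK"):
    acc = "DECOY_sp|P|P" if decoy else "sp|P|P"
    return st.PSM(sid, peptide, frozenset({acc}), float(score), decoy)


def gated_result(scores, ids=None, params=None):
    """Build a SearchResult whose validated list holds target PSMs with scores."""
    ids = ids or [f"scan={i}" for i in range(len(scores))]
    psms = [make_psm(sid, sc) for sid, sc in zip(ids, scores)]
    return st.SearchResult(
        parameters=params or st.SearchParameters(),
        psms=psms,
        fdr_threshold=min(scores) if len(scores) else None,
        validated=psms,
    )
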