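"""Select a representative spectrum subset from a synthetic acquisition.

The acquisition is cut into contiguous sections, every spectrum is scored
for a readable sequence tag, low-confidence spectra (tag e-value >= 0.01)
are excluded, and each section contributes a proportional quota of confident
spectra sampled at a fixed every-n stride.
"""

import searchtune as st

# a 400-spectrum run; 20% of the spectra are unidentifiable noise
cfg = st.SyntheticConfig(n_proteins=40, n_spectra=400, seed=3)
proteome = st.generate_proteome(cfg)
spectra, _ = st.generate_spectra(cfg, proteome)

tags = st.LadderTagProvider().tag(spectra)
confident = st.filter_confident(tags)
print(f"{len(spectra)} spectra acquired; {len(confident)} carry a confident tag")

plan = st.plan_subset(spectra, tags, engine="xtandem", target_size=100)
subset = st.sample_subset(plan, spectra)
print(f"target subset size 100 -> {len(subset)} spectra selected")
for sec in plan.sections:
    print(
        f"  section {sec.index}: {len(sec.spectrum_ids)} spectra, "
        f"{len(sec.confident_ids)} confident, quota {sec.quota}, "
        f"every-n {sec.sampling_interval}"
    )
# Each section's quota mirrors its share of confident spectra, so the subset
# covers the whole run instead of its (often atypical) beginning.
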