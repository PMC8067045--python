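"""Predict miRNA target sites with the positional-mismatch + energy rules.

A site passes when it has at most one mismatch at miRNA positions 2-9,
none at 10-11, at most four from 12 to the end, fewer than three
consecutive mismatches, and a duplex free energy >= 70% of the perfectly
complementary duplex.
"""

from budmir import ScanRules, SynthConfig, predict_targets
from budmir.synth import gen_mirna_reference, gen_transcriptome_with_sites
from budmir.targets import sites_to_frame

cfg = SynthConfig(seed=1)
ref = gen_mirna_reference(cfg)
transcriptome, truth = gen_transcriptome_with_sites(cfg, ref)

sites = predict_targets(ref, transcriptome, ScanRules())
frame = sites_to_frame(sites)
print(frame.head(10).to_string(index=False))
print()
print(f"{len(sites)} passing sites predicted; "
      f"{int(truth['passes_positional'].sum())} planted sites satisfy the "
      "positional rules (sites planted to violate a rule are absent above).")
print("relative_mfe = site duplex energy / perfect-complement energy; "
      "1.0 means a perfectly complementary site.")
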