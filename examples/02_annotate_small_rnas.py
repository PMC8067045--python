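"""Annotate unique small-RNA reads against a mature-miRNA reference.

Reads matching a focal-species (vvi) entry with <= 2 substitutions are
"known in the focal species"; reads matching only other plant species are
"conserved"; everything else is unannotated and excluded downstream.
"""

from budmir import SynthConfig, build_catalog, load_mirna_reference
from budmir.catalog import catalog_to_frame
from budmir.io import read_tsv
from budmir.synth import generate_all

paths = generate_all(SynthConfig(seed=1), "scratch/example_inputs")
ref = load_mirna_reference(paths["mirna_fasta"], focal_species="vvi")
counts = read_tsv(paths["counts_tsv"])

records = build_catalog(counts, ref, max_mismatch=2)
frame = catalog_to_frame(records)

print(frame["status"].value_counts().to_string())
print()
print(frame.head(5).to_string(index=False))
print()
print("Each row is one unique read with its per-library counts, RPM values "
      "and the reference miRNAs it matched (id:mismatches).")
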