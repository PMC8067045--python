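"""Link differentially abundant miRNAs to oppositely regulated targets.

An inverse pair is a miRNA more abundant in one photoperiod whose
predicted target gene is expressed lower in that same photoperiod --
the expression signature of miRNA-mediated repression.
"""

from budmir import (SynthConfig, build_catalog, deg_intake,
                    family_stats_table, inverse_pairs, load_mirna_reference,
                    predict_targets)
from budmir.integrate import pairs_to_frame
from budmir.io import read_fasta, read_tsv
from budmir.pipeline import mirna_direction_table
from budmir.synth import generate_all

paths = generate_all(SynthConfig(seed=1), "scratch/example_inputs")
ref = load_mirna_reference(paths["mirna_fasta"])
records = build_catalog(read_tsv(paths["counts_tsv"]), ref)
fam_stats = family_stats_table(records)
mirna_dir = mirna_direction_table(fam_stats, ref)

sites = predict_targets(read_fasta(paths["mirna_fasta"]),
                        read_fasta(paths["transcriptome_fasta"]))
degs = deg_intake(read_tsv(paths["deg_tsv"]))

pairs = inverse_pairs(mirna_dir, sites, degs)
print(pairs_to_frame(pairs).to_string(index=False))
print()
print("Each row: a differential miRNA, its direction, the target gene, the "
      "gene's opposite DE status, and the supporting binding site.")
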