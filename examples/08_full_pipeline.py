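"""Run the whole pipeline end to end from one config.

Every stage writes a TSV (or graph file) into the output directory and the
manifest records each file's row count and checksum -- rerunning with the
same config reproduces identical checksums.
"""

from budmir import PipelineConfig, SynthConfig, run_pipeline
from budmir.synth import generate_all

paths = generate_all(SynthConfig(seed=1), "scratch/example_inputs")
cfg = PipelineConfig(
    mirna_fasta=paths["mirna_fasta"],
    counts_tsv=paths["counts_tsv"],
    transcriptome_fasta=paths["transcriptome_fasta"],
    deg_tsv=paths["deg_tsv"],
    genesets_gmt=paths["genesets_gmt"],
    tf_gmt=paths["tf_gmt"],
    ppi_tsv=paths["ppi_tsv"],
    expression_tsv=paths["expression_tsv"],
    out_dir="scratch/example_pipeline",
    seed=1,
)
manifest = run_pipeline(cfg)
print(manifest.to_string(index=False))
print()
print("catalog -> abundance -> target scan -> inverse pairs -> enrichment "
      "-> network; every intermediate is re-runnable from its inputs.")
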