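"""Configuration dataclasses shared across the pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass(frozen=True)
class ScanRules:
    """Positional-mismatch and energy rules for the target scanner.

    Positions are 1-based from the miRNA 5' end.  The defaults encode the
    classic plant-miRNA complementarity pattern: at most one mismatch in the
    5' seed-proximal window (positions 2-9), a perfectly paired central
    cleavage site (positions 10-11), up to four mismatches in the 3' half
    (position 12 to the end), fewer than three consecutive mismatches
    anywhere, and a duplex free energy of at least ``min_relative_mfe`` of
    the perfectly complementary duplex.  Position 1 carries no positional
    constraint but still counts toward the consecutive-mismatch run.
    """

    max_mm_2_9: int = 1
    mm_10_11_allowed: int = 0
    max_mm_12_end: int = 4
    max_consecutive_mm: int = 2  # "< 3 consecutive" == longest run <= 2
    min_relative_mfe: float = 0.70
    gu_wobble_is_match: bool = False

    def __post_init__(self) -> None:
        if self.max_mm_2_9 < 0 or self.mm_10_11_allowed < 0 or self.max_mm_12_end < 0:
            raise ValueError("mismatch allowances must be >= 0")
        if self.max_consecutive_mm < 0:
            raise ValueError("max_consecutive_mm must be >= 0")
        if not (0.0 < self.min_relative_mfe <= 1.0):
            raise ValueError("min_relative_mfe must lie in (0, 1]")


#: entry of SynthConfig.site_plan: (mirna_id, transcript_id, mismatch positions)
SitePlanEntry = tuple[str, str, tuple[int, ...]]


@dataclass
class SynthConfig:
    """Parameters of the synthetic-data generator.

    The generator emulates the study design: two pooled small-RNA libraries
    (an LD-like and an SD-like condition), a miRNA family structure with a
    planted subset of differentially abundant families, a toy transcriptome
    carrying planted complementary target sites, a DEG table with planted
    inverse miRNA-target pairs, and gene-set / PPI inputs with planted
    enrichment.  ``seed`` fixes every random draw; identical configs produce
    byte-identical outputs.
    """

    seed: int = 0
    n_families: int = 12
    members_per_family: int = 3
    mirna_len: int = 21
    n_background_seqs: int = 40
    library_depth: int = 100_000
    n_diff_families: int = 4
    planted_fold: float = 4.0
    dispersion: float = 0.05
    n_transcripts: int = 30
    transcript_len: int = 500
    site_plan: Optional[Sequence[SitePlanEntry]] = None
    n_genes_de: int = 40
    n_inverse_pairs: int = 4
    focal_species: str = "vvi"
    other_species: str = "ath"
    family_base_mean: float = 200.0

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.members_per_family <= 0:
            raise ValueError("n_families and members_per_family must be positive")
        if self.mirna_len < 12:
            raise ValueError("mirna_len must be >= 12 (positional rules undefined below)")
        if self.planted_fold < 2:
            raise ValueError(
                "planted_fold must be >= 2 so planted families are recoverable "
                "by the >=2-fold rule"
            )
        if self.n_diff_families > self.n_families:
            raise ValueError("n_diff_families cannot exceed n_families")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.transcript_len < self.mirna_len:
            raise ValueError("transcripts must be at least one miRNA long")

    def family_names(self) -> list[str]:
        """Numeric family stems, miRBase style (156, 157, ...)."""
        return [str(156 + i) for i in range(self.n_families)]

    def differential_families(self) -> dict[str, str]:
        """Planted direction per differential family, alternating LD/SD."""
        fams = self.family_names()[: self.n_diff_families]
        return {f: ("LD" if i % 2 == 0 else "SD") for i, f in enumerate(fams)}


@dataclass
class PipelineConfig:
    """Paths and thresholds for an end-to-end run.

    Every numeric constant of the analysis is surfaced here with the study's
    value as the default, so a run is fully described by one config file.
    """

    # inputs
    mirna_fasta: Path = Path("mirna_reference.fasta")
    counts_tsv: Path = Path("smallrna_counts.tsv")
    transcriptome_fasta: Path = Path("transcriptome.fasta")
    deg_tsv: Path = Path("deg_table.tsv")
    genesets_gmt: Path = Path("pathways.gmt")
    tf_gmt: Path = Path("tf_targets.gmt")
    ppi_tsv: Path = Path("ppi_edges.tsv")
    expression_tsv: Optional[Path] = None
    mapping_tsv: Optional[Path] = None
    out_dir: Path = Path("budmir_out")
    # thresholds
    focal_species: str = "vvi"
    max_mismatch: int = 2
    min_total: int = 20
    fold_threshold: float = 2.0
    scan_rules: ScanRules = field(default_factory=ScanRules)
    padj_max: float = 0.05
    min_abs_log2fc: float = 1.0
    min_fpkm: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 7
    ppi_min_score: int = 700
    network_hub: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, require_inputs: bool = True) -> None:
        """Check thresholds and (optionally) that all input paths exist."""
        if not (0 < self.padj_max <= 1):
            raise ValueError("padj_max must lie in (0, 1]")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.max_mismatch < 0 or self.min_total < 0:
            raise ValueError("max_mismatch and min_total must be >= 0")
        if require_inputs:
            required = [
                self.mirna_fasta,
                self.counts_tsv,
                self.transcriptome_fasta,
                self.deg_tsv,
                self.genesets_gmt,
                self.tf_gmt,
                self.ppi_tsv,
            ]
            missing = [str(p) for p in required if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(
                    "missing pipeline inputs: " + ", ".join(missing)
                )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scan_rules" in raw and isinstance(raw["scan_rules"], dict):
        raw["scan_rules"] = ScanRules(**raw["scan_rules"])
    path_fields = {
        "mirna_fasta", "counts_tsv", "transcriptome_fasta", "deg_tsv",
        "genesets_gmt", "tf_gmt", "ppi_tsv", "expression_tsv", "mapping_tsv",
        "out_dir",
    }
    for key in path_fields & raw.keys():
        if raw[key] is not None:
            raw[key] = Path(raw[key])
    return PipelineConfig(**raw)


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    for key, val in list(data.items()):
        if isinstance(val, Path):
            data[key] = str(val)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for reported folds)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
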