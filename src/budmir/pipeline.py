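"""End-to-end orchestration: catalog -> abundance -> targets -> integration
-> enrichment -> network, with a manifest of every stage output.

Each stage reads and writes plain TSV/FASTA/GMT files, so any stage can be
re-run in isolation from its persisted inputs.  A fixed config (including
the seed) yields byte-identical outputs and therefore identical manifest
checksums.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from budmir import abundance, catalog, enrich, integrate, network, targets
from budmir.config import PipelineConfig
from budmir.io import read_fasta, read_gmt, read_tsv, write_tsv

logger = logging.getLogger(__name__)

STAGES = ("catalog", "abundance", "scan", "integrate", "enrich", "network")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_row(name: str, path: Path) -> dict:
    n_rows = ""
    if path.suffix == ".tsv":
        with open(path) as fh:
            n_rows = sum(1 for _ in fh) - 1
    return {"output": name, "file": str(path), "rows": n_rows,
            "sha256": _checksum(path)}


def mirna_direction_table(family_stats: pd.DataFrame,
                          ref: list[catalog.MiRNARef]) -> pd.DataFrame:
    """Per-miRNA differential direction, inherited from the family call."""
    direction = dict(zip(family_stats.get("family", []),
                         family_stats.get("direction", [])))
    rows = [{
        "mirna_id": r.mirna_id,
        "family": r.family,
        "direction": direction.get(r.family, "unchanged"),
    } for r in ref]
    return pd.DataFrame(rows, columns=["mirna_id", "family", "direction"])


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage; returns the output manifest (also written to disk)."""
    config.validate(require_inputs=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    stage = "catalog"
    try:
        # --- catalog -----------------------------------------------------
        ref = catalog.load_mirna_reference(config.mirna_fasta,
                                           focal_species=config.focal_species)
        counts = read_tsv(config.counts_tsv,
                          required=("sequence", "count_ld", "count_sd"))
        records = catalog.build_catalog(counts, ref,
                                        max_mismatch=config.max_mismatch)
        cat_df = catalog.catalog_to_frame(records)
        cat_path = out / "catalog.tsv"
        write_tsv(cat_df, cat_path)
        manifest.append(_manifest_row("catalog", cat_path))
        logger.info("catalog: %d sequences, %d annotated", len(records),
                    sum(r.annotation.status != "unannotated" for r in records))

        # --- abundance ---------------------------------------------------
        stage = "abundance"
        abundant = catalog.filter_highly_abundant(records,
                                                  min_total=config.min_total)
        seq_stats = abundance.per_sequence_stats(abundant)
        fam_stats = abundance.family_stats_table(
            records, min_total=config.min_total,
            fold_threshold=config.fold_threshold)
        seq_path = out / "per_sequence_stats.tsv"
        fam_path = out / "family_stats.tsv"
        write_tsv(seq_stats, seq_path)
        write_tsv(fam_stats, fam_path)
        manifest.append(_manifest_row("per_sequence_stats", seq_path))
        manifest.append(_manifest_row("family_stats", fam_path))

        # --- target scan -------------------------------------------------
        stage = "scan"
        transcriptome = read_fasta(config.transcriptome_fasta)
        mirna_dir = mirna_direction_table(fam_stats, ref)
        differential_ids = set(
            mirna_dir.loc[mirna_dir["direction"] != "unchanged", "mirna_id"])
        ref_seqs = {r.mirna_id: r.sequence for r in ref}
        scan_set = {m: ref_seqs[m] for m in sorted(differential_ids)} \
            or ref_seqs
        sites = targets.predict_targets(scan_set, transcriptome,
                                        rules=config.scan_rules)
        sites_df = targets.sites_to_frame(sites)
        sites_path = out / "target_sites.tsv"
        write_tsv(sites_df, sites_path)
        manifest.append(_manifest_row("target_sites", sites_path))
        logger.info("scan: %d passing sites from %d differential miRNAs",
                    len(sites), len(scan_set))

        # --- integration -------------------------------------------------
        stage = "integrate"
        deg_table = read_tsv(config.deg_tsv,
                             required=integrate.REQUIRED_DEG_COLUMNS)
        degs = integrate.deg_intake(deg_table, padj_max=config.padj_max,
                                    min_abs_log2fc=config.min_abs_log2fc,
                                    min_fpkm=config.min_fpkm)
        mapping = None
        if config.mapping_tsv is not None:
            map_df = read_tsv(config.mapping_tsv,
                              required=("transcript_id", "gene_id"))
            mapping = dict(zip(map_df["transcript_id"].astype(str),
                               map_df["gene_id"].astype(str)))
        pairs = integrate.inverse_pairs(mirna_dir, sites, degs, mapping=mapping)
        pairs_df = integrate.pairs_to_frame(pairs)
        pairs_path = out / "inverse_pairs.tsv"
        write_tsv(pairs_df, pairs_path)
        manifest.append(_manifest_row("inverse_pairs", pairs_path))

        # --- enrichment --------------------------------------------------
        stage = "enrich"
        genesets = enrich.genesets_from_gmt(read_gmt(config.genesets_gmt))
        expressed = {d.gene_id for d in degs if d.status != "not_expressed"}
        down = {d.gene_id for d in degs if d.status == "down_in_SD"}
        hyper = enrich.hypergeometric_enrich(down, expressed, genesets) \
            if down else pd.DataFrame()
        hyper_path = out / "hypergeometric_enrichment.tsv"
        write_tsv(hyper, hyper_path)
        manifest.append(_manifest_row("hypergeometric_enrichment", hyper_path))

        if config.expression_tsv is not None:
            expr_df = read_tsv(config.expression_tsv, required=("gene_id",))
            expr = expr_df.set_index("gene_id")
            groups = ["LD" if c.startswith("LD") else "SD"
                      for c in expr.columns]
            gsea = enrich.gsea_permutation_test(
                expr, groups, genesets, n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size, seed=config.seed,
                positive_group="SD")
            gsea_path = out / "gsea_results.tsv"
            write_tsv(gsea, gsea_path)
            manifest.append(_manifest_row("gsea_results", gsea_path))

        # --- network -----------------------------------------------------
        stage = "network"
        tf_sets = read_gmt(config.tf_gmt)
        ppi_raw = read_tsv(config.ppi_tsv,
                           required=("protein_a", "protein_b", "score"))
        ppi = network.filter_ppi(ppi_raw, min_score=config.ppi_min_score)
        hub = config.network_hub or next(iter(sorted(tf_sets)))
        mirna_edges = pairs_df[["mirna_id", "gene_id"]] if len(pairs_df) \
            else pd.DataFrame(columns=["mirna_id", "gene_id"])
        net = network.assemble_network(hub, tf_sets, ppi, mirna_edges, degs)
        graphml_path = out / "network.graphml"
        sif_path = out / "network.sif"
        network.export_graph(net, graphml_path, fmt="graphml")
        network.export_graph(net, sif_path, fmt="sif")
        manifest.append(_manifest_row("network_graphml", graphml_path))
        manifest.append(_manifest_row("network_sif", sif_path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_df = pd.DataFrame(manifest)
    write_tsv(manifest_df, out / "manifest.tsv")
    return manifest_df
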