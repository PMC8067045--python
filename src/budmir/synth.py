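"""Synthetic pipeline inputs with planted ground truth.

Every generator is a deterministic function of a :class:`SynthConfig`
(independent RNG substreams per artifact, so the functions can be called in
any order).  The outputs emulate the statistical structure of the study's
real inputs:

* a mature-miRNA reference with numeric family stems, members in the focal
  species plus a second species (so known-vs-conserved classification is
  exercised) and one family present only in the other species;
* two pooled small-RNA libraries (LD-like and SD-like) with negative-
  binomial counts around family means, a planted subset of families whose
  between-library mean ratio equals ``planted_fold``, 1-2-mismatch variant
  reads, >2-mismatch near-miss reads, and random background sequences;
* a toy transcriptome carrying planted complementary target sites with
  controlled mismatch patterns;
* a DEG table with planted differentially expressed genes and planted
  inverse miRNA-target pairs;
* pathway / TF gene sets and a PPI edge table with planted enrichment and
  a planted hub node.

Each artifact comes with a plain-TSV truth table recording what was
planted.  Sequences use the DNA alphabet (ACGT); the downstream modules
treat T and U as equivalent.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from budmir.config import ScanRules, SynthConfig, SitePlanEntry
from budmir.io import write_fasta, write_gmt, write_tsv
from budmir.targets import check_positional_rules, _revcomp, _COMP

_NT = np.array(list("ACGT"))

# RNG substream salts, one per artifact
_SALT_REF, _SALT_LIBS, _SALT_TX, _SALT_DEG, _SALT_SETS, _SALT_EXPR = range(6)


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), salt])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _mutate(seq: str, positions: Sequence[int],
            rng: Optional[np.random.Generator] = None) -> str:
    """Substitute the bases at the given 0-based positions."""
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[0] if rng is None else str(rng.choice(choices))
    return "".join(out)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


# ---------------------------------------------------------------------------
# miRNA reference


def gen_mirna_reference(cfg: SynthConfig) -> dict[str, str]:
    """Mature-miRNA FASTA records as {id: sequence}.

    Families are numeric stems (156, 157, ...); members within a family
    differ by at most one substitution from the family base sequence.
    Every even-indexed family also has a member in ``cfg.other_species``;
    the last family exists only in the other species (reads annotating to
    it are "conserved", never "known in focal").
    """
    rng = _rng(cfg, _SALT_REF)
    letters = "abcdefghijklmnopqrstuvwxyz"
    records: dict[str, str] = {}
    for i, fam in enumerate(cfg.family_names()):
        base = _random_seq(rng, cfg.mirna_len)
        conserved_only = (i == cfg.n_families - 1 and cfg.n_families > 1)
        species = cfg.other_species if conserved_only else cfg.focal_species
        for j in range(cfg.members_per_family):
            seq = base if j == 0 else _mutate(
                base, [int(rng.integers(cfg.mirna_len))], rng)
            mirna_id = f"{species}-miR{fam}{letters[j]}"
            if mirna_id in records:
                raise ValueError(f"duplicate miRNA id generated: {mirna_id}")
            records[mirna_id] = seq
        if not conserved_only and i % 2 == 0:
            alt_id = f"{cfg.other_species}-miR{fam}a"
            if alt_id in records:
                raise ValueError(f"duplicate miRNA id generated: {alt_id}")
            records[alt_id] = _mutate(base, [int(rng.integers(cfg.mirna_len))],
                                      rng)
    return records


# ---------------------------------------------------------------------------
# small-RNA libraries


def gen_smallrna_libraries(cfg: SynthConfig, ref: dict[str, str],
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-library count table plus sequence- and family-level truth.

    Returns ``(counts, seq_truth, family_truth)``.  Counts are negative-
    binomial draws around per-member means; planted differential families
    have a between-library mean ratio of ``cfg.planted_fold`` in their
    planted direction.  The table also contains 1- and 2-mismatch variant
    reads (annotatable), 3-mismatch near-miss reads (not annotatable under
    the <=2-mismatch rule), and random background sequences.
    """
    if cfg.library_depth <= 0:
        raise ValueError("library_depth must be > 0")
    rng = _rng(cfg, _SALT_LIBS)
    diff = cfg.differential_families()

    from budmir.catalog import parse_mirna_id

    members: list[tuple[str, str, str]] = []  # (mirna_id, family, sequence)
    seen_seqs: set[str] = set()
    for mirna_id, seq in ref.items():
        _, fam = parse_mirna_id(mirna_id)
        if seq in seen_seqs:
            continue
        seen_seqs.add(seq)
        members.append((mirna_id, fam, seq))

    # calibrate the per-member mean so the expected totals track library_depth
    n_eff = len(members) * 1.15 + cfg.n_background_seqs * 0.3
    base_mean = cfg.library_depth / max(n_eff, 1.0)

    rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(seq: str, mean_ld: float, mean_sd: float, origin: str,
             family: str, mm_to_ref: int) -> None:
        rows.append({
            "sequence": seq,
            "count_ld": _nb_draw(rng, mean_ld, cfg.dispersion),
            "count_sd": _nb_draw(rng, mean_sd, cfg.dispersion),
        })
        truth_rows.append({
            "sequence": seq,
            "origin": origin,
            "family": family,
            "mm_to_nearest_ref": mm_to_ref,
            "annotatable": mm_to_ref <= 2,
        })

    first_of_family: set[str] = set()
    for mirna_id, fam, seq in members:
        member_mean = base_mean * rng.uniform(0.5, 1.5)
        direction = diff.get(fam)
        if direction == "LD":
            mean_ld, mean_sd = member_mean * cfg.planted_fold, member_mean
        elif direction == "SD":
            mean_ld, mean_sd = member_mean, member_mean * cfg.planted_fold
        else:
            mean_ld = mean_sd = member_mean
        emit(seq, mean_ld, mean_sd, mirna_id, fam, 0)
        if fam not in first_of_family:
            first_of_family.add(fam)
            # isoform-like variant reads sharing the family's fold structure
            v1 = _mutate(seq, [2], rng)
            emit(v1, mean_ld * 0.10, mean_sd * 0.10, f"{mirna_id}_variant1mm",
                 fam, 1)
            v2 = _mutate(seq, [4, 9], rng)
            emit(v2, mean_ld * 0.05, mean_sd * 0.05, f"{mirna_id}_variant2mm",
                 fam, 2)
            v3 = _mutate(seq, [1, 7, 13], rng)
            emit(v3, base_mean * 0.05, base_mean * 0.05,
                 f"{mirna_id}_nearmiss3mm", "", 3)

    ref_seqs = list(seen_seqs)
    for b in range(cfg.n_background_seqs):
        while True:
            seq = _random_seq(rng, cfg.mirna_len)
            # random 21-mers are essentially always >2 mismatches from every
            # reference; verify to keep the truth table exact
            near = min(sum(a != c for a, c in zip(seq, r)) for r in ref_seqs)
            if near > 3:
                break
        emit(seq, base_mean * 0.3, base_mean * 0.3, f"background_{b}", "", near)

    counts = pd.DataFrame(rows)
    dup = counts["sequence"].duplicated()
    counts = counts.loc[~dup].reset_index(drop=True)
    seq_truth = pd.DataFrame(truth_rows).loc[~dup.values].reset_index(drop=True)

    fam_rows = []
    for fam in cfg.family_names():
        direction = diff.get(fam, "")
        fam_rows.append({
            "family": fam,
            "is_differential": fam in diff,
            "direction": direction,
            "true_fold": cfg.planted_fold if fam in diff else 1.0,
        })
    family_truth = pd.DataFrame(fam_rows)
    return counts, seq_truth, family_truth


# ---------------------------------------------------------------------------
# transcriptome with planted target sites


def default_site_plan(cfg: SynthConfig, ref: dict[str, str],
                      ) -> list[SitePlanEntry]:
    """A site plan exercising pass and fail cases of the positional rules.

    Pattern cycle (miRNA 1-based positions): perfect site; one mismatch at
    15 (passes); one mismatch at 10 (fails: central window); mismatches at
    3 and 5 (fails: two in the 2-9 window); mismatches at 13,14,15 (fails:
    three consecutive).  Every planted differential family contributes at
    least one passing site so inverse pairs can be planted downstream.
    """
    patterns: list[tuple[int, ...]] = [(), (15,), (10,), (3, 5), (13, 14, 15)]
    mirna_ids = sorted(ref)
    diff = cfg.differential_families()
    from budmir.catalog import parse_mirna_id

    plan: list[SitePlanEntry] = []
    tx = 0
    # one passing (perfect) site per differential family, distinct transcripts
    for mid in mirna_ids:
        sp, fam = parse_mirna_id(mid)
        if fam in diff and sp == cfg.focal_species and mid.endswith("a"):
            plan.append((mid, f"TX{tx:04d}", ()))
            tx += 1
    # cycle the rule patterns over the remaining miRNAs/transcripts
    for k, mid in enumerate(mirna_ids):
        if tx >= cfg.n_transcripts:
            break
        pat = patterns[k % len(patterns)]
        if any(p > cfg.mirna_len for p in pat):
            continue
        plan.append((mid, f"TX{tx:04d}", pat))
        tx += 1
    return plan


def gen_transcriptome_with_sites(cfg: SynthConfig, ref: dict[str, str],
                                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random transcripts with planted (possibly mismatched) target sites.

    Each site-plan entry embeds the reverse complement of its miRNA with
    substitutions at exactly the stated miRNA positions (1-based from the
    miRNA 5' end); the substituted base is chosen to mismatch under both
    strict Watson-Crick and G:U-wobble pairing.  The truth table records
    the transcript, 1-based start, mismatch positions, and whether the
    site satisfies the positional rules.
    """
    rng = _rng(cfg, _SALT_TX)
    plan = list(cfg.site_plan) if cfg.site_plan is not None \
        else default_site_plan(cfg, ref)

    for mirna_id, transcript_id, positions in plan:
        if mirna_id not in ref:
            raise ValueError(f"site plan references unknown miRNA {mirna_id!r}")
        for p in positions:
            if not (1 <= p <= len(ref[mirna_id])):
                raise ValueError(
                    f"mismatch position {p} outside 1..{len(ref[mirna_id])}")

    tx_ids = sorted({t for _, t, _ in plan})
    extra = [f"TX{k:04d}" for k in range(cfg.n_transcripts)]
    tx_ids = sorted(set(tx_ids) | set(extra[:cfg.n_transcripts]))

    transcripts = {t: list(_random_seq(rng, cfg.transcript_len)) for t in tx_ids}
    next_slot: dict[str, int] = {t: 10 for t in tx_ids}
    truth_rows = []
    for mirna_id, transcript_id, positions in plan:
        mseq = ref[mirna_id]
        L = len(mseq)
        site = list(_revcomp(mseq))
        for p in positions:
            j = L - p  # 0-based site index pairing miRNA position p
            m_base = mseq[p - 1]
            forbidden = {_COMP[m_base]}
            if m_base == "G":
                forbidden.add("T")
            elif m_base == "T":
                forbidden.add("G")
            site[j] = next(b for b in "ACGT" if b not in forbidden)
        start0 = next_slot[transcript_id]
        if start0 + L > cfg.transcript_len:
            raise ValueError(
                f"transcript {transcript_id} too short for another site")
        next_slot[transcript_id] = start0 + L + 10
        transcripts[transcript_id][start0:start0 + L] = site
        vec = [False] * L
        for p in positions:
            vec[p - 1] = True
        truth_rows.append({
            "mirna_id": mirna_id,
            "transcript_id": transcript_id,
            "start": start0 + 1,
            "end": start0 + L,
            "mismatch_positions": ",".join(str(p) for p in sorted(positions)),
            "n_mismatches": len(positions),
            "passes_positional": check_positional_rules(vec, ScanRules()),
        })
    transcriptome = {t: "".join(s) for t, s in sorted(transcripts.items())}
    return transcriptome, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# DEG table with planted inverse pairs


def gen_deg_table(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG table plus truth, with planted inverse miRNA-target pairs.

    Gene ids equal transcript ids for planted targets (identity mapping)
    plus background genes.  Planted DE genes get |log2FC| >= 1 and adjusted
    p <= 0.05; inverse-pair genes get the direction opposite their miRNA's
    planted abundance; non-DE genes get adjusted p > 0.05; a few genes are
    below the FPKM floor in both conditions ("not expressed").
    """
    rng = _rng(cfg, _SALT_DEG)
    ref = gen_mirna_reference(cfg)
    _, site_truth = gen_transcriptome_with_sites(cfg, ref)
    diff = cfg.differential_families()
    from budmir.catalog import parse_mirna_id

    passing = site_truth[site_truth["passes_positional"]]
    candidates = []
    for row in passing.itertuples(index=False):
        _, fam = parse_mirna_id(row.mirna_id)
        if fam in diff:
            candidates.append((row.mirna_id, fam, diff[fam], row.transcript_id))
    # deduplicate on gene so each planted pair owns its gene's direction
    seen_genes: set[str] = set()
    unique_candidates = []
    for c in candidates:
        if c[3] not in seen_genes:
            seen_genes.add(c[3])
            unique_candidates.append(c)
    if cfg.n_inverse_pairs > len(unique_candidates):
        raise ValueError(
            f"n_inverse_pairs={cfg.n_inverse_pairs} exceeds the "
            f"{len(unique_candidates)} planted passing sites of differential "
            "miRNAs")
    inverse = unique_candidates[: cfg.n_inverse_pairs]
    inverse_genes = {gene: (mid, fam, direction)
                     for mid, fam, direction, gene in inverse}

    site_genes = set(site_truth["transcript_id"])
    all_tx = sorted(site_genes)
    n_extra = max(cfg.n_genes_de * 4, 50)
    background_genes = [f"G{k:05d}" for k in range(n_extra)]
    truth_rows = []
    rows = []

    def add_gene(gene_id: str, status: str, log2fc: float, padj: float,
                 fpkm_ld: float, mirna_id: str = "", family: str = "") -> None:
        fpkm_sd = fpkm_ld * (2.0 ** log2fc)
        rows.append({
            "gene_id": gene_id,
            "fpkm_ld": round(fpkm_ld, 4),
            "fpkm_sd": round(fpkm_sd, 4),
            "log2fc_sd_vs_ld": round(log2fc, 4),
            "adjusted_p": padj,
        })
        truth_rows.append({
            "gene_id": gene_id,
            "true_status": status,
            "planted_inverse": bool(mirna_id),
            "mirna_id": mirna_id,
            "family": family,
        })

    n_de_remaining = cfg.n_genes_de
    for gene in all_tx:
        if gene in inverse_genes:
            mid, fam, direction = inverse_genes[gene]
            # miRNA up in SD -> target down in SD, and vice versa
            log2fc = -2.0 if direction == "SD" else 2.0
            status = "down_in_SD" if direction == "SD" else "up_in_SD"
            add_gene(gene, status, log2fc + rng.uniform(-0.3, 0.3),
                     10.0 ** rng.uniform(-6, -2), rng.uniform(5, 50),
                     mirna_id=mid, family=fam)
            n_de_remaining -= 1
        else:
            # target transcripts stay non-DE so the planted inverse truth is
            # exactly the emitted pair set
            add_gene(gene, "not_DE", rng.uniform(-0.4, 0.4),
                     rng.uniform(0.2, 0.95), rng.uniform(2, 30))

    n_not_expressed = max(3, n_extra // 20)
    for k, gene in enumerate(background_genes):
        if k < n_de_remaining:
            sign = 1.0 if k % 2 == 0 else -1.0
            log2fc = sign * rng.uniform(1.0, 3.0)
            status = "up_in_SD" if sign > 0 else "down_in_SD"
            add_gene(gene, status, log2fc, 10.0 ** rng.uniform(-6, -2),
                     rng.uniform(2, 60))
        elif k < n_de_remaining + n_not_expressed:
            add_gene(gene, "not_expressed", rng.uniform(-0.5, 0.5),
                     rng.uniform(0.3, 0.95), rng.uniform(0.01, 0.4))
        else:
            add_gene(gene, "not_DE", rng.uniform(-0.4, 0.4),
                     rng.uniform(0.2, 0.95), rng.uniform(1.5, 30))

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# gene sets and PPI


def gen_genesets_and_ppi(cfg: SynthConfig,
                         ) -> tuple[dict, dict, pd.DataFrame, dict]:
    """Pathway GMT, TF->target GMT, PPI edges, and planting truth.

    One pathway of >= 7 genes is planted enriched among the genes
    downregulated in SD; the remaining pathways are random draws from the
    gene universe.  The PPI table carries integer confidence scores that
    span the 700 threshold (700 and 701 both occur), and a TF hub node
    ("MYB3R1") is planted with both transcriptional targets and protein
    interactors.
    """
    rng = _rng(cfg, _SALT_SETS)
    deg, deg_truth = gen_deg_table(cfg)
    universe = deg["gene_id"].tolist()
    down = deg_truth.loc[deg_truth["true_status"] == "down_in_SD",
                         "gene_id"].tolist()
    up = deg_truth.loc[deg_truth["true_status"] == "up_in_SD",
                       "gene_id"].tolist()
    if len(down) < 7:
        raise ValueError("need at least 7 downregulated genes to plant an "
                         "enriched set; increase n_genes_de")

    planted_size = min(max(10, 7), len(down))
    planted = sorted(str(g) for g in
                     rng.choice(down, size=planted_size, replace=False))
    pathways = {"planted_down_pathway": {
        "description": "planted: enriched among genes down in SD",
        "members": set(planted)}}
    for s in range(8):
        size = int(rng.integers(8, 16))
        members = {str(g) for g in
                   rng.choice(universe, size=size, replace=False)}
        pathways[f"random_pathway_{s}"] = {
            "description": "random draw from the gene universe",
            "members": members}

    hub = "MYB3R1"
    n_targets = min(5, len(down))
    hub_targets = sorted(str(g) for g in
                         rng.choice(down, size=n_targets, replace=False))
    tf_sets = {hub: {"description": "planted TF hub targets",
                     "members": set(hub_targets)}}

    interactors = ([f"G{k:05d}" for k in range(4)] + up[:2])[:5]
    ppi_rows = []
    scores = [950, 850, 701, 700, 650]
    for prot, score in zip(interactors, scores):
        ppi_rows.append({"protein_a": hub, "protein_b": prot, "score": score})
    pool = universe
    for _ in range(20):
        a, b = rng.choice(pool, size=2, replace=False)
        ppi_rows.append({"protein_a": str(a), "protein_b": str(b),
                         "score": int(rng.integers(300, 1000))})
    ppi = pd.DataFrame(ppi_rows)

    truth = {
        "enriched_set": "planted_down_pathway",
        "enriched_members": list(planted),
        "not_enriched_sets": [f"random_pathway_{s}" for s in range(8)],
        "hub": hub,
        "hub_targets": hub_targets,
        "hub_interactors_above_700": [p for p, s in zip(interactors, scores)
                                      if s > 700],
    }
    return pathways, tf_sets, ppi, truth


# ---------------------------------------------------------------------------
# replicate-level expression matrix (for GSEA)


def gen_expression_matrix(cfg: SynthConfig, n_reps: int = 3,
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Genes x replicates count matrix consistent with the DEG truth.

    Three LD and three SD replicates by default; planted DE genes carry
    their planted log2 fold change between the group means, everything
    else is null.  Returns ``(matrix, group labels)`` with columns
    LD_1..LD_n, SD_1..SD_n.
    """
    rng = _rng(cfg, _SALT_EXPR)
    deg, deg_truth = gen_deg_table(cfg)
    status = dict(zip(deg_truth["gene_id"], deg_truth["true_status"]))
    log2fc = dict(zip(deg["gene_id"], deg["log2fc_sd_vs_ld"]))
    genes = deg["gene_id"].tolist()
    cols = [f"LD_{r+1}" for r in range(n_reps)] + \
           [f"SD_{r+1}" for r in range(n_reps)]
    data = np.zeros((len(genes), 2 * n_reps))
    for i, g in enumerate(genes):
        base = rng.uniform(50, 500)
        fc = 2.0 ** log2fc[g] if status[g] in ("up_in_SD", "down_in_SD") else 1.0
        mean_ld, mean_sd = base, base * fc
        for r in range(n_reps):
            data[i, r] = _nb_draw(rng, mean_ld, max(cfg.dispersion, 0.01))
            data[i, n_reps + r] = _nb_draw(rng, mean_sd,
                                           max(cfg.dispersion, 0.01))
    expr = pd.DataFrame(data, index=genes, columns=cols)
    groups = ["LD"] * n_reps + ["SD"] * n_reps
    return expr, groups


# ---------------------------------------------------------------------------
# write everything to disk


def generate_all(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input (and its truth table) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ref = gen_mirna_reference(cfg)
    paths["mirna_fasta"] = outdir / "mirna_reference.fasta"
    write_fasta(ref, paths["mirna_fasta"])

    counts, seq_truth, fam_truth = gen_smallrna_libraries(cfg, ref)
    paths["counts_tsv"] = outdir / "smallrna_counts.tsv"
    write_tsv(counts, paths["counts_tsv"])
    paths["seq_truth"] = outdir / "truth_sequences.tsv"
    write_tsv(seq_truth, paths["seq_truth"])
    paths["family_truth"] = outdir / "truth_families.tsv"
    write_tsv(fam_truth, paths["family_truth"])

    transcriptome, site_truth = gen_transcriptome_with_sites(cfg, ref)
    paths["transcriptome_fasta"] = outdir / "transcriptome.fasta"
    write_fasta(transcriptome, paths["transcriptome_fasta"])
    paths["site_truth"] = outdir / "truth_sites.tsv"
    write_tsv(site_truth, paths["site_truth"])

    deg, deg_truth = gen_deg_table(cfg)
    paths["deg_tsv"] = outdir / "deg_table.tsv"
    write_tsv(deg, paths["deg_tsv"])
    paths["deg_truth"] = outdir / "truth_deg.tsv"
    write_tsv(deg_truth, paths["deg_truth"])

    pathways, tf_sets, ppi, set_truth = gen_genesets_and_ppi(cfg)
    paths["genesets_gmt"] = outdir / "pathways.gmt"
    write_gmt(pathways, paths["genesets_gmt"])
    paths["tf_gmt"] = outdir / "tf_targets.gmt"
    write_gmt(tf_sets, paths["tf_gmt"])
    paths["ppi_tsv"] = outdir / "ppi_edges.tsv"
    write_tsv(ppi, paths["ppi_tsv"])
    truth_rows = [{"key": k, "value": ";".join(v) if isinstance(v, list)
                   else str(v)} for k, v in set_truth.items()]
    paths["set_truth"] = outdir / "truth_sets.tsv"
    write_tsv(pd.DataFrame(truth_rows), paths["set_truth"])

    expr, groups = gen_expression_matrix(cfg)
    paths["expression_tsv"] = outdir / "expression_counts.tsv"
    expr_out = expr.reset_index(names="gene_id")
    write_tsv(expr_out, paths["expression_tsv"])

    return paths
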