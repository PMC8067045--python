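"""DEG intake filters and inverse miRNA-target expression association.

A gene is differentially expressed (DE) when its adjusted p-value is at
most 0.05 and |log2 fold change| is at least 1 (2-fold linear); genes with
FPKM < 1 in both dormancy phases are "not expressed".  An inverse pair
links a differentially abundant miRNA to a predicted target gene whose DE
direction is opposite in the condition of miRNA abundance: an SD-abundant
miRNA pairs with a gene down in SD, an LD-abundant miRNA with a gene up in
SD (i.e. down in LD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from budmir.targets import TargetSite

logger = logging.getLogger(__name__)

REQUIRED_DEG_COLUMNS = ("gene_id", "fpkm_ld", "fpkm_sd",
                        "log2fc_sd_vs_ld", "adjusted_p")


@dataclass
class DEGRecord:
    """One gene's expression contrast with its DE status."""

    gene_id: str
    fpkm_ld: float
    fpkm_sd: float
    log2fc_sd_vs_ld: float
    adjusted_p: float
    status: str  # up_in_SD | down_in_SD | not_DE | not_expressed


def _status(fpkm_ld: float, fpkm_sd: float, log2fc: float, padj: float,
            padj_max: float, min_abs_log2fc: float, min_fpkm: float) -> str:
    if fpkm_ld < min_fpkm and fpkm_sd < min_fpkm:
        return "not_expressed"
    if padj <= padj_max and abs(log2fc) >= min_abs_log2fc:
        return "up_in_SD" if log2fc > 0 else "down_in_SD"
    return "not_DE"


def deg_intake(table: pd.DataFrame, padj_max: float = 0.05,
               min_abs_log2fc: float = 1.0,
               min_fpkm: float = 1.0) -> list[DEGRecord]:
    """Classify every gene of a DEG table into the four status classes."""
    missing = [c for c in REQUIRED_DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing column(s): {', '.join(missing)}")
    if ((table["adjusted_p"] < 0) | (table["adjusted_p"] > 1)).any():
        raise ValueError("adjusted_p values must lie in [0, 1]")
    records = []
    for row in table.itertuples(index=False):
        records.append(DEGRecord(
            gene_id=str(row.gene_id),
            fpkm_ld=float(row.fpkm_ld),
            fpkm_sd=float(row.fpkm_sd),
            log2fc_sd_vs_ld=float(row.log2fc_sd_vs_ld),
            adjusted_p=float(row.adjusted_p),
            status=_status(float(row.fpkm_ld), float(row.fpkm_sd),
                           float(row.log2fc_sd_vs_ld), float(row.adjusted_p),
                           padj_max, min_abs_log2fc, min_fpkm),
        ))
    tally = pd.Series([r.status for r in records]).value_counts().to_dict()
    logger.info("DEG intake: %s", tally)
    return records


@dataclass
class InversePair:
    """A differential miRNA linked to an oppositely regulated target gene."""

    mirna_id: str
    family: str
    mirna_direction: str  # LD_abundant | SD_abundant
    gene_id: str
    gene_status: str      # up_in_SD | down_in_SD
    site: TargetSite


#: miRNA direction -> required opposite gene status (target is lower where
#: the miRNA is higher)
_OPPOSITE = {"SD_abundant": "down_in_SD", "LD_abundant": "up_in_SD"}


def inverse_pairs(mirna_stats: pd.DataFrame, sites: Sequence[TargetSite],
                  degs: Sequence[DEGRecord],
                  mapping: Optional[Mapping[str, str]] = None,
                  ) -> list[InversePair]:
    """Emit one pair per (miRNA, gene) with a passing site and inverse DE.

    ``mirna_stats`` needs columns mirna_id, family, direction (the
    per-miRNA differential classification).  ``mapping`` translates
    transcript ids to gene ids; identity is assumed when absent.
    Deduplicated on (mirna_id, gene_id); unmapped transcripts are skipped
    with a warning.
    """
    for col in ("mirna_id", "family", "direction"):
        if col not in mirna_stats.columns:
            raise ValueError(f"mirna_stats missing column {col!r}")
    direction = {
        str(r.mirna_id): str(r.direction)
        for r in mirna_stats.itertuples(index=False)
    }
    family = {
        str(r.mirna_id): str(r.family)
        for r in mirna_stats.itertuples(index=False)
    }
    deg_by_gene = {d.gene_id: d for d in degs}
    pairs: dict[tuple[str, str], InversePair] = {}
    n_unmapped = 0
    for site in sites:
        if not site.passed:
            continue
        mdir = direction.get(site.mirna_id)
        if mdir not in _OPPOSITE:
            continue
        if mapping is not None:
            gene_id = mapping.get(site.transcript_id)
            if gene_id is None:
                n_unmapped += 1
                logger.warning("no gene mapping for transcript %s; skipped",
                               site.transcript_id)
                continue
        else:
            gene_id = site.transcript_id
        deg = deg_by_gene.get(gene_id)
        if deg is None or deg.status != _OPPOSITE[mdir]:
            continue
        key = (site.mirna_id, gene_id)
        if key not in pairs:
            pairs[key] = InversePair(
                mirna_id=site.mirna_id,
                family=family.get(site.mirna_id, ""),
                mirna_direction=mdir,
                gene_id=gene_id,
                gene_status=deg.status,
                site=site,
            )
    if n_unmapped:
        logger.warning("%d site(s) skipped for missing gene mapping", n_unmapped)
    return sorted(pairs.values(), key=lambda p: (p.mirna_id, p.gene_id))


def pairs_to_frame(pairs: Sequence[InversePair]) -> pd.DataFrame:
    rows = [{
        "mirna_id": p.mirna_id,
        "family": p.family,
        "mirna_direction": p.mirna_direction,
        "gene_id": p.gene_id,
        "gene_status": p.gene_status,
        "transcript_id": p.site.transcript_id,
        "site_start": p.site.start,
        "site_end": p.site.end,
        "site_mm_count": p.site.mm_count,
        "site_relative_mfe": p.site.relative_mfe,
    } for p in pairs]
    return pd.DataFrame(rows, columns=[
        "mirna_id", "family", "mirna_direction", "gene_id", "gene_status",
        "transcript_id", "site_start", "site_end", "site_mm_count",
        "site_relative_mfe",
    ])
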