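"""Gene-set enrichment: hypergeometric over-representation and GSEA.

Two complementary procedures:

* ``hypergeometric_enrich`` — one-sided upper-tail hypergeometric test of a
  query gene list (e.g. the downregulated DEGs) against each gene set,
  Benjamini-Hochberg adjusted across sets.
* ``gsea_permutation_test`` — weighted Kolmogorov-Smirnov running-sum
  enrichment on a signal-to-noise ranked list, with a gene-set permutation
  null (random same-size sets).  With only three replicates per condition a
  phenotype permutation has just 20 distinct relabelings, so gene-set
  permutation is the default; phenotype permutation is available via
  ``permute="phenotype"``.

Sign convention: a positive enrichment score means the set is concentrated
among genes higher in the group passed as ``positive_group`` (the
endodormant SD condition in the dormancy analysis).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from budmir.abundance import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def genesets_from_gmt(gmt: dict[str, dict]) -> list[GeneSet]:
    return [
        GeneSet(name=name, members=frozenset(body["members"]),
                description=body.get("description", ""))
        for name, body in gmt.items()
    ]


def hypergeometric_enrich(query: set[str], background: set[str],
                          sets: Iterable[GeneSet],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    For each set, the overlap k of the query with the set (both restricted
    to the background universe) is tested against drawing |query| genes
    from the background without replacement.  Sets with no background
    overlap are skipped with a warning.
    """
    offenders = query - background
    if offenders:
        raise ValueError("query genes missing from background: "
                         + ", ".join(sorted(offenders)[:10]))
    N = len(background)
    n = len(query)
    rows = []
    for gs in sets:
        in_bg = gs.members & background
        K = len(in_bg)
        if K == 0:
            logger.warning("gene set %s has no overlap with background; skipped",
                           gs.name)
            continue
        k = len(query & in_bg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": gs.name, "set_size_in_background": K,
                     "k_overlap": k, "hyper_p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "set_size_in_background",
                                     "k_overlap", "hyper_p"])
    if not df.empty:
        df["adjusted_p"] = bh_fdr(df["hyper_p"].tolist())
        df["significant"] = df["adjusted_p"] <= alpha
        df = df.sort_values("hyper_p", kind="mergesort").reset_index(drop=True)
    return df


def rank_metric(expr: pd.DataFrame, groups: Sequence[str],
                positive_group: str | None = None) -> pd.DataFrame:
    """Signal-to-noise ranking of genes between two replicate groups.

    ``expr`` is genes x replicates; ``groups`` labels each column with one
    of two group names.  Score = (mean_pos - mean_neg) / (sd_pos + sd_neg),
    with each sd floored at max(0.2 * |its group mean|, 0.2).  Returns a
    DataFrame (gene_id, score) sorted by descending score, ties broken by
    gene id.
    """
    groups = list(groups)
    if len(groups) != expr.shape[1]:
        raise ValueError("one group label per expression column required")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    if positive_group is None:
        positive_group = labels[0]
    if positive_group not in labels:
        raise ValueError(f"positive_group {positive_group!r} not in labels")
    negative_group = labels[0] if positive_group == labels[1] else labels[1]
    pos_cols = [c for c, g in zip(expr.columns, groups) if g == positive_group]
    neg_cols = [c for c, g in zip(expr.columns, groups) if g == negative_group]
    if len(pos_cols) < 2 or len(neg_cols) < 2:
        raise ValueError("at least two replicates per group required")
    mu_p = expr[pos_cols].mean(axis=1)
    mu_n = expr[neg_cols].mean(axis=1)
    sd_p = expr[pos_cols].std(axis=1, ddof=1)
    sd_n = expr[neg_cols].std(axis=1, ddof=1)
    sd_p = np.maximum(sd_p, np.maximum(0.2 * mu_p.abs(), 0.2))
    sd_n = np.maximum(sd_n, np.maximum(0.2 * mu_n.abs(), 0.2))
    score = (mu_p - mu_n) / (sd_p + sd_n)
    out = pd.DataFrame({"gene_id": expr.index.astype(str), "score": score.values})
    out = out.sort_values(["score", "gene_id"],
                          ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def _es_from_hits(scores: np.ndarray, hit_mask: np.ndarray,
                  weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    N = scores.size
    n_hits = int(hit_mask.sum())
    w = np.abs(scores) ** weight
    denom_hit = float(w[hit_mask].sum())
    if denom_hit == 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        steps_hit = hit_mask / n_hits
    else:
        steps_hit = np.where(hit_mask, w / denom_hit, 0.0)
    steps_miss = np.where(hit_mask, 0.0, 1.0 / (N - n_hits))
    running = np.cumsum(steps_hit - steps_miss)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


def gsea_es(ranked: pd.DataFrame, gene_set: GeneSet,
            weight: float = 1.0) -> float:
    """Enrichment score of one gene set on a ranked list.

    ``ranked`` must have columns gene_id and score, ordered from the most
    positive to the most negative score.  Hits step the running sum up by
    |score|^weight (normalised over set members); misses step it down by
    1/(N - set size); the ES is the signed extremum.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(gene_set.members))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the list")
    if n_hits == genes.size:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole list")
    return _es_from_hits(scores, hit_mask, weight)


def gsea_permutation_test(expr: pd.DataFrame, groups: Sequence[str],
                          sets: Iterable[GeneSet], n_perm: int = 1000,
                          min_size: int = 7, seed: int | None = None,
                          weight: float = 1.0,
                          positive_group: str | None = None,
                          permute: str = "geneset") -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    The null for each set is ``n_perm`` random same-size gene sets drawn
    from the ranked list (``permute="geneset"``), or the ES under random
    relabelings of the replicate columns (``permute="phenotype"``).
    Nominal p = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1); FDR q by
    Benjamini-Hochberg across the tested sets.  Sets with fewer than
    ``min_size`` members present in the expression matrix are excluded.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-value resolution will be coarse",
                       n_perm)
    if permute not in ("geneset", "phenotype"):
        raise ValueError("permute must be 'geneset' or 'phenotype'")
    rng = np.random.default_rng(seed)
    ranked = rank_metric(expr, groups, positive_group=positive_group)
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}

    tested: list[tuple[GeneSet, np.ndarray]] = []
    n_excluded = 0
    for gs in sets:
        idx = np.array(sorted(gene_pos[g] for g in gs.members if g in gene_pos),
                       dtype=int)
        if idx.size < min_size:
            n_excluded += 1
            continue
        if idx.size == N:
            n_excluded += 1
            logger.warning("gene set %s covers the whole list; excluded", gs.name)
            continue
        tested.append((gs, idx))
    if n_excluded:
        logger.info("excluded %d gene set(s) below min_size=%d",
                    n_excluded, min_size)

    rows = []
    if permute == "phenotype":
        perms = _phenotype_permutations(expr, list(groups), n_perm, rng,
                                        positive_group)
    for gs, idx in tested:
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        es = _es_from_hits(scores, hit, weight)
        size = idx.size
        null = np.empty(n_perm)
        if permute == "geneset":
            for b in range(n_perm):
                rand_idx = rng.choice(N, size=size, replace=False)
                mask = np.zeros(N, dtype=bool)
                mask[rand_idx] = True
                null[b] = _es_from_hits(scores, mask, weight)
        else:
            for b, ranked_b in enumerate(perms):
                genes_b = ranked_b["gene_id"].to_numpy()
                scores_b = ranked_b["score"].to_numpy(dtype=float)
                mask = np.isin(genes_b, genes[idx])
                null[b] = _es_from_hits(scores_b, mask, weight)
        nominal_p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
        rows.append({
            "set_name": gs.name,
            "size": size,
            "es": es,
            "direction": "positive" if es >= 0 else "negative",
            "nominal_p": float(nominal_p),
        })
    df = pd.DataFrame(rows, columns=["set_name", "size", "es", "direction",
                                     "nominal_p"])
    if not df.empty:
        df["fdr_q"] = bh_fdr(df["nominal_p"].tolist())
    return df


def _phenotype_permutations(expr: pd.DataFrame, groups: list[str],
                            n_perm: int, rng: np.random.Generator,
                            positive_group: str | None) -> list[pd.DataFrame]:
    """Ranked lists under random relabelings of the replicate columns."""
    labels = sorted(set(groups))
    n_pos = groups.count(labels[0])
    cols = list(range(len(groups)))
    all_assignments = [set(c) for c in itertools.combinations(cols, n_pos)]
    out = []
    for _ in range(n_perm):
        chosen = all_assignments[rng.integers(len(all_assignments))]
        perm_groups = [labels[0] if i in chosen else labels[1] for i in cols]
        out.append(rank_metric(expr, perm_groups, positive_group=positive_group))
    return out
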