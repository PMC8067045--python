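"""RPM normalisation, differential abundance, and qPCR ddCt statistics.

Two pooled libraries (LD = long-day / paradormant, SD = short-day /
endodormant) are contrasted without replicate-level modelling.  Differential
abundance of a sequence is the log2 ratio of its RPM values; a family's
reported fold is the signed linear ratio of its mean member counts (the
convention of the study's family table: magnitude = larger/smaller mean,
sign positive when LD is higher, rounded half-away-from-zero to one
decimal).  Family-level significance uses a two-sided Wilcoxon rank-sum
test on the per-sequence counts of the family in the two libraries, with
Benjamini-Hochberg adjustment across families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from budmir.catalog import SeqAbundance
from budmir.config import round_half_away

LD_SPECIFIC = "LD_specific"
SD_SPECIFIC = "SD_specific"
ABSENT = "absent"
OK = "ok"


def rpm_normalize(count: int, library_total: int) -> float:
    """Reads-per-million: count / library total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if count < 0 or count > library_total:
        raise ValueError("count must lie in [0, library_total]")
    return count / library_total * 1e6


def seq_log2_fold(rpm_ld: float, rpm_sd: float) -> tuple[float, str]:
    """log2(RPM_LD / RPM_SD) with zero-handling flags.

    Returns ``(value, flag)``.  When both RPMs are positive the flag is
    "ok".  A sequence present in only one library has no numeric fold; it
    is flagged "LD_specific" / "SD_specific" (value NaN), and (0, 0) is
    flagged "absent".
    """
    if rpm_ld < 0 or rpm_sd < 0:
        raise ValueError("RPM values must be >= 0")
    if rpm_ld > 0 and rpm_sd > 0:
        return math.log2(rpm_ld / rpm_sd), OK
    if rpm_ld > 0:
        return math.nan, LD_SPECIFIC
    if rpm_sd > 0:
        return math.nan, SD_SPECIFIC
    return math.nan, ABSENT


def classify_differential(log2fc: float, threshold_linear: float = 2.0) -> str:
    """LD_abundant / SD_abundant / unchanged at a linear fold threshold."""
    if threshold_linear <= 1:
        raise ValueError("threshold_linear must exceed 1")
    if not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    cut = math.log2(threshold_linear)
    if log2fc >= cut:
        return "LD_abundant"
    if log2fc <= -cut:
        return "SD_abundant"
    return "unchanged"


def family_fold_from_means(mean_ld: float, mean_sd: float) -> float:
    """Signed linear family fold, rounded half-away-from-zero to 1 decimal.

    Magnitude is the larger mean over the smaller; the sign is positive when
    the LD mean is at least the SD mean, negative otherwise.
    """
    if mean_ld <= 0 or mean_sd <= 0:
        raise ValueError("means must be > 0 (zero means take the "
                         "specifically-abundant path)")
    magnitude = max(mean_ld, mean_sd) / min(mean_ld, mean_sd)
    signed = magnitude if mean_ld >= mean_sd else -magnitude
    return round_half_away(signed, 1)


def family_wilcoxon(counts_ld: Sequence[float],
                    counts_sd: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one family's member counts.

    Exact enumeration when the smaller sample has <= 8 observations and the
    pooled data are tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    ld = np.asarray(counts_ld, dtype=float)
    sd = np.asarray(counts_sd, dtype=float)
    if ld.size == 0 or sd.size == 0:
        raise ValueError("each sample needs at least one observation")
    pooled = np.concatenate([ld, sd])
    no_ties = np.unique(pooled).size == pooled.size
    if min(ld.size, sd.size) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(ld, sd, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def specifically_abundant(family_rpm_ld: float, family_rpm_sd: float,
                          fold_threshold: float = 2.0) -> str:
    """Flag families abundant in only one library: no / LD_only / SD_only."""
    if family_rpm_ld < 0 or family_rpm_sd < 0:
        raise ValueError("RPM values must be >= 0")
    if family_rpm_ld > 0 and family_rpm_sd == 0:
        return "LD_only"
    if family_rpm_sd > 0 and family_rpm_ld == 0:
        return "SD_only"
    # present in both libraries (possibly differential) or absent: not specific
    return "no"


@dataclass
class QpcrRecord:
    """Per-replicate qPCR cycle thresholds for one miRNA and the U6 control."""

    mirna_id: str
    ct_gene_ld: Sequence[float]
    ct_gene_sd: Sequence[float]
    ct_control_ld: Sequence[float]
    ct_control_sd: Sequence[float]

    def __post_init__(self) -> None:
        for vals in (self.ct_gene_ld, self.ct_gene_sd,
                     self.ct_control_ld, self.ct_control_sd):
            if any(v <= 0 for v in vals):
                raise ValueError("Ct values must be > 0")
        if len(self.ct_gene_ld) != len(self.ct_control_ld) or \
           len(self.ct_gene_sd) != len(self.ct_control_sd):
            raise ValueError("gene and control replicates must pair up")


def ddct_log_fold(rec: QpcrRecord) -> dict:
    """ddCt statistics: dCt = Ct_control - Ct_gene per replicate,
    ddCt = mean dCt_LD - mean dCt_SD (log2-scale fold), two-sided t-test
    on the dCt values.  With a single replicate per condition the fold is
    still returned and the p-value is NaN (unavailable).
    """
    dct_ld = [c - g for g, c in zip(rec.ct_gene_ld, rec.ct_control_ld)]
    dct_sd = [c - g for g, c in zip(rec.ct_gene_sd, rec.ct_control_sd)]
    ddct = float(np.mean(dct_ld) - np.mean(dct_sd))
    if len(dct_ld) >= 2 and len(dct_sd) >= 2:
        p = float(stats.ttest_ind(dct_ld, dct_sd).pvalue)
    else:
        p = math.nan
    return {
        "delta_ct_ld": dct_ld,
        "delta_ct_sd": dct_sd,
        "delta_delta_ct": ddct,
        "log_fold": ddct,
        "t_test_p": p,
    }


def per_sequence_stats(records: Iterable[SeqAbundance]) -> pd.DataFrame:
    """Per-sequence differential table: RPM fold, flag, and classification."""
    rows = []
    for r in records:
        fc, flag = seq_log2_fold(r.rpm_ld, r.rpm_sd)
        cls = classify_differential(fc) if flag == OK else flag
        rows.append({
            "sequence": r.sequence,
            "count_ld": r.count_ld,
            "count_sd": r.count_sd,
            "rpm_ld": r.rpm_ld,
            "rpm_sd": r.rpm_sd,
            "log2_fold_ld_vs_sd": fc,
            "fold_flag": flag,
            "class": cls,
            "status": r.annotation.status,
            "families": ",".join(sorted(r.annotation.families)),
        })
    return pd.DataFrame(rows)


def family_stats_table(records: Iterable[SeqAbundance],
                       min_total: int = 20,
                       fold_threshold: float = 2.0) -> pd.DataFrame:
    """Family-level differential-abundance table.

    For each miRNA family: arithmetic mean of member counts per library
    (members = annotated sequences passing the combined-count filter),
    signed linear fold, Wilcoxon rank-sum p on the member count vectors,
    BH-adjusted p across families, and the specifically-abundant flag on
    summed family RPM.
    """
    by_family: dict[str, list[SeqAbundance]] = {}
    for r in records:
        if r.annotation.status == "unannotated":
            continue
        if not r.is_highly_abundant(min_total):
            continue
        for fam in r.annotation.families:
            by_family.setdefault(fam, []).append(r)

    rows = []
    for fam in sorted(by_family):
        members = by_family[fam]
        counts_ld = [m.count_ld for m in members]
        counts_sd = [m.count_sd for m in members]
        mean_ld = float(np.mean(counts_ld))
        mean_sd = float(np.mean(counts_sd))
        rpm_ld = float(sum(m.rpm_ld for m in members))
        rpm_sd = float(sum(m.rpm_sd for m in members))
        if mean_ld > 0 and mean_sd > 0:
            fold = family_fold_from_means(mean_ld, mean_sd)
        else:
            fold = math.nan
        spec = specifically_abundant(rpm_ld, rpm_sd, fold_threshold)
        p = family_wilcoxon(counts_ld, counts_sd)
        rows.append({
            "family": fam,
            "mean_count_ld": mean_ld,
            "mean_count_sd": mean_sd,
            "fold_signed": fold,
            "p_value": p,
            "n_sequences_ge20": len(members),
            "rpm_ld": rpm_ld,
            "rpm_sd": rpm_sd,
            "specifically_abundant": spec,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr_adjusted_p"] = bh_fdr(df["p_value"].tolist())
        df["differential"] = df["fold_signed"].abs() >= fold_threshold
        df["direction"] = np.where(
            ~df["differential"], "unchanged",
            np.where(df["fold_signed"] > 0, "LD_abundant", "SD_abundant"),
        )
    return df
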