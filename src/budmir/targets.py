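"""Rule-based miRNA target-site prediction on transcript sense strands.

A candidate site is a transcript window of miRNA length, read 5'->3' on the
sense strand; the miRNA binds antiparallel, so miRNA position i (1-based
from the miRNA 5' end) pairs with window position L-i+1.  A position
matches when the pair is Watson-Crick (A-U/T, G-C); G:U wobble can
optionally be counted as a match.  Sites must satisfy the positional
mismatch pattern (ScanRules), contain fewer than three consecutive
mismatches, and retain at least 70% of the duplex free energy of the
perfectly complementary site.

The duplex energy is a deliberately simple nearest-neighbour model: the sum
of Watson-Crick stacking free energies (37 degC, kcal/mol) over consecutive
matched pair dyads; a mismatch breaks the helix with no loop penalty.  The
relative-MFE ratio used for filtering is robust to this simplification; a
perfectly complementary site always scores relative MFE 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from budmir.config import ScanRules

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Watson-Crick nearest-neighbour stacking free energies, RNA/RNA at 37 degC
# (kcal/mol), keyed by the 5'->3' dinucleotide on the miRNA strand; the
# opposing strand is its Watson-Crick complement.  Table is self-consistent
# under strand symmetry: dG(XY) == dG(revcomp(XY)).
STACK_DG = {
    "AA": -0.93, "AT": -1.10, "AC": -2.24, "AG": -2.08,
    "TA": -1.33, "TT": -0.93, "TC": -2.35, "TG": -2.11,
    "CA": -2.11, "CT": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GT": -2.24, "GC": -3.42, "GG": -3.26,
}


def _norm(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide character(s): {sorted(bad)!r}")
    return seq


def _pairs(m: str, s: str, gu_wobble_is_match: bool) -> bool:
    """Does miRNA base m pair with site base s (both DNA alphabet)?"""
    if _COMP[m] == s:
        return True
    if gu_wobble_is_match and ((m == "G" and s == "T") or (m == "T" and s == "G")):
        return True
    return False


def mismatch_vector(mirna: str, site: str,
                    gu_wobble_is_match: bool = False) -> list[bool]:
    """Boolean mismatch vector over miRNA positions 1..L (True = mismatch).

    ``site`` is the transcript window 5'->3' on the sense strand; the
    duplex is antiparallel, so miRNA position i is paired with site
    position L-i+1.
    """
    m = _norm(mirna)
    s = _norm(site)
    if len(m) != len(s):
        raise ValueError(f"length mismatch: miRNA {len(m)} vs site {len(s)}")
    L = len(m)
    return [not _pairs(m[i], s[L - 1 - i], gu_wobble_is_match) for i in range(L)]


def longest_run(vec: Sequence[bool]) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in vec:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def check_positional_rules(vec: Sequence[bool],
                           rules: ScanRules = ScanRules()) -> bool:
    """Apply the positional mismatch pattern to a mismatch vector.

    Windows (1-based miRNA coordinates): positions 2-9 allow at most
    ``max_mm_2_9`` mismatches, 10-11 allow ``mm_10_11_allowed``, 12..end
    allow ``max_mm_12_end``; the longest mismatch run anywhere must not
    exceed ``max_consecutive_mm``.  Position 1 has no window constraint but
    participates in the run rule.
    """
    vec = list(vec)
    if len(vec) < 12:
        raise ValueError("positional rules are undefined for vectors < 12 nt")
    if sum(vec[1:9]) > rules.max_mm_2_9:
        return False
    if sum(vec[9:11]) > rules.mm_10_11_allowed:
        return False
    if sum(vec[11:]) > rules.max_mm_12_end:
        return False
    if longest_run(vec) > rules.max_consecutive_mm:
        return False
    return True


def duplex_mfe(mirna: str, site: str, vec: Sequence[bool]) -> float:
    """Nearest-neighbour stacking energy of the (broken) duplex, kcal/mol.

    Sums the Watson-Crick stack term for every dyad of consecutive matched
    positions; returns 0.0 when no two consecutive positions pair.
    """
    m = _norm(mirna)
    if len(m) != len(_norm(site)):
        raise ValueError("length mismatch between miRNA and site")
    if len(vec) != len(m):
        raise ValueError("mismatch vector length must equal sequence length")
    energy = 0.0
    for i in range(len(m) - 1):
        if not vec[i] and not vec[i + 1]:
            energy += STACK_DG[m[i:i + 2]]
    return energy


def perfect_mfe(mirna: str) -> float:
    """Duplex energy of the perfectly complementary site."""
    m = _norm(mirna)
    return duplex_mfe(m, _revcomp(m), [False] * len(m))


def relative_mfe(duplex: float, perfect: float) -> float:
    """Fraction of the perfect-duplex energy retained by the site."""
    if perfect >= 0:
        raise ValueError("perfect duplex energy must be negative")
    return duplex / perfect


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class TargetSite:
    """One predicted miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive, sense strand
    end: int    # inclusive
    mismatch_vector: list[bool]
    mm_count: int
    duplex_mfe: float
    perfect_mfe: float
    relative_mfe: float
    passed: bool


def evaluate_site(mirna_id: str, mirna_seq: str, transcript_id: str,
                  window: str, start: int,
                  rules: ScanRules = ScanRules()) -> TargetSite:
    """Score one candidate window against every rule."""
    vec = mismatch_vector(mirna_seq, window, rules.gu_wobble_is_match)
    pos_ok = check_positional_rules(vec, rules)
    dup = duplex_mfe(mirna_seq, window, vec)
    perf = perfect_mfe(mirna_seq)
    rel = relative_mfe(dup, perf)
    return TargetSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=start,
        end=start + len(mirna_seq) - 1,
        mismatch_vector=vec,
        mm_count=sum(vec),
        duplex_mfe=dup,
        perfect_mfe=perf,
        relative_mfe=rel,
        passed=pos_ok and rel >= rules.min_relative_mfe,
    )


def _window_mismatch_counts(rc: str, transcript: str,
                            gu_site_allowed: str | None = None) -> np.ndarray:
    """Mismatch count of every window of len(rc) against rc (site coords)."""
    L = len(rc)
    tr = np.frombuffer(transcript.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(tr, L)
    rc_arr = np.frombuffer(rc.encode(), dtype="S1")
    match = windows == rc_arr
    if gu_site_allowed is not None:
        alt = np.frombuffer(gu_site_allowed.encode(), dtype="S1")
        match = match | ((windows == alt) & (alt != b"."))
    return (~match).sum(axis=1)


def predict_targets(mirnas: Mapping[str, str], transcriptome: Mapping[str, str],
                    rules: ScanRules = ScanRules()) -> list[TargetSite]:
    """Scan every miRNA against every transcript at every offset.

    Returns all sites with ``passed`` True, sorted by
    (mirna_id, transcript_id, start).  Overlapping passing sites are all
    reported.  A fast vectorised mismatch-count prefilter discards windows
    that cannot satisfy the positional budgets; surviving windows get the
    full per-position evaluation.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    if not mirnas:
        raise ValueError("no miRNAs to scan")
    # largest total mismatch load the positional windows can admit
    sites: list[TargetSite] = []
    for mirna_id in sorted(mirnas):
        mseq = _norm(mirnas[mirna_id])
        L = len(mseq)
        mm_budget = 1 + rules.max_mm_2_9 + rules.mm_10_11_allowed + rules.max_mm_12_end
        rc = _revcomp(mseq)
        if rules.gu_wobble_is_match:
            # per site position j, the wobble-allowed alternative base
            # (miRNA G pairs site T, miRNA T pairs site G); '.' = none
            alt = []
            for j in range(L):
                m = mseq[L - 1 - j]
                alt.append("T" if m == "G" else ("G" if m == "T" else "."))
            gu_alt = "".join(alt)
        else:
            gu_alt = None
        for tid in sorted(transcriptome):
            tseq = _norm(transcriptome[tid])
            if len(tseq) < L:
                continue
            counts = _window_mismatch_counts(rc, tseq, gu_alt)
            for off in np.nonzero(counts <= mm_budget)[0]:
                site = evaluate_site(mirna_id, mseq, tid,
                                     tseq[off:off + L], int(off) + 1, rules)
                if site.passed:
                    sites.append(site)
    sites.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start))
    return sites


def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    rows = [{
        "mirna_id": s.mirna_id,
        "transcript_id": s.transcript_id,
        "start": s.start,
        "end": s.end,
        "mm_count": s.mm_count,
        "mismatch_positions": ",".join(
            str(i + 1) for i, v in enumerate(s.mismatch_vector) if v),
        "duplex_mfe": s.duplex_mfe,
        "perfect_mfe": s.perfect_mfe,
        "relative_mfe": s.relative_mfe,
    } for s in sites]
    return pd.DataFrame(rows, columns=[
        "mirna_id", "transcript_id", "start", "end", "mm_count",
        "mismatch_positions", "duplex_mfe", "perfect_mfe", "relative_mfe",
    ])
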