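"""TE overlap of lncRNAs: masked fraction, superfamily calls, enrichment.

Sequence-similarity masking is represented by positional overlap between
transcript exons and the TE annotation.  Bases covered by more than one
superfamily are counted once toward the masked total, attributed to the
superfamily with the larger local (per-transcript) overlap; ties break
lexicographically.  The enrichment table compares the superfamily
composition of TE-lncRNA bases against the composition of all annotated TE
bases in the genome, per superfamily and per grouped class (retroelements,
DNA transposons, helitrons, unclassified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import TEAnnotation, TranscriptModel


@dataclass
class TEOverlapResult:
    transcript_id: str
    length: int
    masked_bp: int
    masked_fraction: float
    bp_by_superfamily: dict[str, int] = field(default_factory=dict)
    assigned_superfamily: str | None = None
    is_te_lncRNA: bool = False
    tie_broken: bool = False


def masked_fraction(t: TranscriptModel, te: TEAnnotation) -> TEOverlapResult:
    """Per-base TE coverage of a transcript's exons.

    Exact by construction: transcript bases are painted per superfamily in
    increasing priority (priority = raw overlap bp with this transcript,
    ties by reverse lexicographic name so the lexicographically smaller name
    wins contested bases).
    """
    exons = t.exons
    length = t.length
    offsets = []
    off = 0
    for e in exons:
        offsets.append(off)
        off += len(e)

    per_fam_hits: dict[str, list[tuple[int, int]]] = {}
    for iv, fam in te.by_chrom().get(t.chrom, []):
        for e, eo in zip(exons, offsets):
            lo, hi = max(iv.start, e.start), min(iv.end, e.end)
            if lo < hi:
                per_fam_hits.setdefault(fam, []).append(
                    (eo + lo - e.start, eo + hi - e.start)
                )
    raw_bp = {}
    for fam, segs in per_fam_hits.items():
        cover = np.zeros(length, dtype=bool)
        for s, e in segs:
            cover[s:e] = True
        raw_bp[fam] = int(cover.sum())

    paint = np.full(length, -1, dtype=np.int32)
    fams = sorted(raw_bp, key=lambda f: (raw_bp[f], tuple(-ord(c) for c in f)))
    for fi, fam in enumerate(fams):
        for s, e in per_fam_hits[fam]:
            paint[s:e] = fi
    bp_by_fam = {
        fam: int((paint == fi).sum()) for fi, fam in enumerate(fams)
    }
    bp_by_fam = {f: b for f, b in bp_by_fam.items() if b > 0}
    masked = int((paint >= 0).sum())
    return TEOverlapResult(
        transcript_id=t.transcript_id,
        length=length,
        masked_bp=masked,
        masked_fraction=masked / length,
        bp_by_superfamily=bp_by_fam,
    )


def call_te_lncRNA(
    result: TEOverlapResult, min_fraction: float = 0.0
) -> TEOverlapResult:
    """Flag a TE-lncRNA (masked fraction strictly above ``min_fraction``,
    default: any overlap) and assign the superfamily with the most bases."""
    result.is_te_lncRNA = result.masked_fraction > min_fraction
    if result.is_te_lncRNA and result.bp_by_superfamily:
        best = max(result.bp_by_superfamily.values())
        winners = sorted(
            f for f, b in result.bp_by_superfamily.items() if b == best
        )
        result.assigned_superfamily = winners[0]
        result.tie_broken = len(winners) > 1
    return result


def te_class_group(superfamily: str) -> str:
    if superfamily.startswith(("LTR", "LINE", "SINE")):
        return "Retroelements"
    if superfamily.startswith("DNA"):
        return "DNA transposons"
    if superfamily.startswith("Helitron"):
        return "Helitrons"
    return "Unclassified"


def superfamily_enrichment(
    results: list[TEOverlapResult], te: TEAnnotation
) -> pd.DataFrame:
    """Superfamily composition of TE-lncRNA bases vs genomic TE bases.

    One row per superfamily plus one per grouped class; columns: TE-lncRNA
    count, masked bp, percentage of all TE-lncRNA bases, percentage of all
    genomic TE bases, and their fold ratio.  Both percentage columns sum to
    100 over the superfamily rows.  A family seen in lncRNAs but absent from
    the genome annotation gets an infinite fold with a flag.
    """
    te_lnc = [r for r in results if r.is_te_lncRNA]
    if not te_lnc:
        raise ValueError("no TE-lncRNAs to tabulate")
    lnc_bp: dict[str, int] = {}
    lnc_count: dict[str, int] = {}
    for r in te_lnc:
        for fam, bp in r.bp_by_superfamily.items():
            lnc_bp[fam] = lnc_bp.get(fam, 0) + bp
        lnc_count[r.assigned_superfamily] = lnc_count.get(r.assigned_superfamily, 0) + 1
    genome_bp = te.total_bp_by_superfamily()
    fams = sorted(set(lnc_bp) | set(genome_bp))
    lnc_total = sum(lnc_bp.values())
    genome_total = sum(genome_bp.values())
    rows = []
    for fam in fams:
        p_lnc = 100.0 * lnc_bp.get(fam, 0) / lnc_total
        p_gen = 100.0 * genome_bp.get(fam, 0) / genome_total if genome_total else 0.0
        fold = p_lnc / p_gen if p_gen > 0 else math.inf
        rows.append(
            {
                "name": fam,
                "kind": "superfamily",
                "group": te_class_group(fam),
                "te_lnc_count": lnc_count.get(fam, 0),
                "te_lnc_bp": lnc_bp.get(fam, 0),
                "pct_of_te_lnc_bp": p_lnc,
                "pct_of_genomic_te_bp": p_gen,
                "fold_ratio": fold,
                "absent_from_genome": p_gen == 0.0 and p_lnc > 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    group_rows = []
    for group, sub in frame.groupby("group"):
        p_lnc = float(sub["pct_of_te_lnc_bp"].sum())
        p_gen = float(sub["pct_of_genomic_te_bp"].sum())
        group_rows.append(
            {
                "name": group,
                "kind": "group",
                "group": group,
                "te_lnc_count": int(sub["te_lnc_count"].sum()),
                "te_lnc_bp": int(sub["te_lnc_bp"].sum()),
                "pct_of_te_lnc_bp": p_lnc,
                "pct_of_genomic_te_bp": p_gen,
                "fold_ratio": p_lnc / p_gen if p_gen > 0 else math.inf,
                "absent_from_genome": p_gen == 0.0 and p_lnc > 0.0,
            }
        )
    return pd.concat([frame, pd.DataFrame(group_rows)], ignore_index=True)


def enrichment_fold(pct_of_te_lnc_bp: float, pct_of_genomic_te_bp: float) -> float:
    """Fold ratio between a class's share of TE-lncRNA bases and its share
    of genomic TE bases (the Table-2-style comparison)."""
    if pct_of_genomic_te_bp <= 0:
        return math.inf
    return pct_of_te_lnc_bp / pct_of_genomic_te_bp


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def masked_fraction_histogram(
    results: list[TEOverlapResult], bin_width: float = 0.1
) -> tuple[pd.Series, int]:
    """Right-closed histogram of masked fractions of TE-lncRNAs.

    Bins are ``(0, w], (w, 2w], ...``; also returns the count of TE-lncRNAs
    with fraction >= 0.9 (the "mostly TE-derived" statistic, which for the
    default width equals the last bin plus any exact 0.9 boundary cases).
    """
    n_bins = int(round(1.0 / bin_width))
    fractions = [r.masked_fraction for r in results if r.is_te_lncRNA]
    counts = np.zeros(n_bins, dtype=int)
    for f in fractions:
        b = min(n_bins - 1, int(math.ceil(f / bin_width)) - 1)
        counts[b] += 1
    labels = [
        f"({i * bin_width:.1f},{(i + 1) * bin_width:.1f}]" for i in range(n_bins)
    ]
    ge90 = sum(1 for f in fractions if f >= 0.9)
    return pd.Series(counts, index=labels, name="n_lncRNA"), ge90
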