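"""The lncRNA identification cascade.

A transcript is retained as a high-confidence lncRNA when it is >= 200 nt,
judged non-coding by the intersection of two external predictors (or by an
internal ORF-based stand-in), has no protein-family hit at e <= 1e-5, has no
ORF of >= 100 amino acids, lies in intergenic space (class code ``u``) or
wholly within an intron (class ``i``), and exceeds 1 FPKM in at least one
sample.  Each rejected transcript carries the list of filters it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    TranscriptModel,
    interval_overlap_bp,
    merge_intervals,
)

STOPS = {"TAA", "TAG", "TGA"}

CLASS_CODES = ("u", "i", "annotated_lnc_within", "annotated_lnc_overlap", "excluded")


@dataclass
class OrfResult:
    """ORF scan of one transcript strand (all three frames).

    ``orf_count`` counts ORFs of at least the configured minimum length;
    nested starts sharing a stop codon count once (the longest is kept).
    ``longest_orf_aa`` is over all ORFs regardless of the minimum and
    excludes the stop codon; its span is 0-based half-open on the transcript
    and includes the stop codon (``3*aa + 3`` nt).
    """

    orf_count: int
    longest_orf_aa: int
    longest_orf_span: tuple[int, int] | None


def find_orfs(sequence: str, min_aa: int = 30) -> OrfResult:
    """Scan ATG..stop ORFs on the given strand in all 3 frames."""
    seq = sequence.upper()
    n = len(seq)
    count = 0
    best_aa = 0
    best_span: tuple[int, int] | None = None
    for frame in range(3):
        start_atg = -1  # earliest ATG since the last stop in this frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOPS:
                if start_atg >= 0:
                    aa = (pos - start_atg) // 3
                    if aa >= min_aa:
                        count += 1
                    if aa > best_aa:
                        best_aa = aa
                        best_span = (start_atg, pos + 3)
                start_atg = -1
            elif codon == "ATG" and start_atg < 0:
                start_atg = pos
    return OrfResult(count, best_aa, best_span)


@dataclass
class CodingEvidence:
    """Ingested external predictor verdicts for one transcript."""

    cpc2_score: float | None = None
    cpc2_label: str | None = None
    cnci_label: str | None = None
    pfam_best_evalue: float | None = None


@dataclass
class DiscoveryConfig:
    min_length_nt: int = 200
    max_orf_aa: int = 100
    min_orf_aa_to_count: int = 30
    pfam_evalue_max: float = 1e-5
    min_fpkm: float = 1.0
    cpc2_noncoding_max_score: float = -1.0
    require_both_predictors: bool = True
    orf_coverage_max: float = 0.35  # internal stand-in: max ORF share of length


def coding_potential_verdict(
    orf: OrfResult, evidence: CodingEvidence, config: DiscoveryConfig,
    transcript_length: int | None = None,
) -> str:
    """``noncoding`` iff both external predictors agree; stand-in otherwise.

    With both verdicts present the rule is the intersection: CPC2 score below
    the noncoding threshold AND a noncoding CNCI label.  With evidence absent
    and ``require_both_predictors`` false, an internal ORF-based stand-in is
    used: noncoding iff the longest ORF is below ``max_orf_aa`` and covers
    less than ``orf_coverage_max`` of the transcript.
    """
    has_cpc = evidence.cpc2_score is not None
    has_cnci = evidence.cnci_label is not None
    if has_cpc and has_cnci:
        noncoding = (
            evidence.cpc2_score < config.cpc2_noncoding_max_score
            and evidence.cnci_label == "noncoding"
        )
        return "noncoding" if noncoding else "coding"
    if config.require_both_predictors:
        raise ValueError(
            "coding-potential evidence missing and require_both_predictors is set"
        )
    if transcript_length is None or transcript_length <= 0:
        raise ValueError("transcript_length needed for the internal stand-in")
    coverage = (3 * orf.longest_orf_aa + 3) / transcript_length if orf.longest_orf_aa else 0.0
    noncoding = orf.longest_orf_aa < config.max_orf_aa and coverage < config.orf_coverage_max
    return "noncoding" if noncoding else "coding"


def classify_locus(
    t: TranscriptModel,
    ann: GeneAnnotation,
    known_lnc: GeneAnnotation | None = None,
) -> str:
    """gffcompare-style class code against the gene annotation.

    ``u``: the transcript span overlaps no gene span; ``i``: every transcript
    base lies within the introns of a single gene and touches no exon;
    ``excluded``: any exon overlap, or a partial gene-span overlap that is
    not fully intron-contained.  Candidates overlapping a known-lncRNA
    annotation are relabelled ``annotated_lnc_within``/``_overlap``.
    """
    span = t.span
    genes = ann.by_chrom().get(span.chrom, [])
    code = None
    touching = [g for g in genes if g.span.overlaps(span)]
    if not touching:
        code = "u"
    else:
        exonic = any(
            interval_overlap_bp(t.exons, g.exons) > 0 for g in touching
        )
        if exonic:
            code = "excluded"
        else:
            code = "excluded"
            for g in touching:
                if g.introns and interval_overlap_bp(t.exons, g.introns) == t.length:
                    code = "i"
                    break
    if code in {"u", "i"} and known_lnc is not None:
        for lg in known_lnc.by_chrom().get(span.chrom, []):
            if lg.span.contains(span):
                return "annotated_lnc_within"
        for lg in known_lnc.by_chrom().get(span.chrom, []):
            if lg.span.overlaps(span):
                return "annotated_lnc_overlap"
    return code


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library_size/1e6)).

    ``library_sizes`` defaults to per-sample column sums (mapped fragments).
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("all transcript lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("all library sizes must be positive")
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return pd.DataFrame(
        counts.to_numpy() / denom, index=counts.index, columns=counts.columns
    )


def assign_polyA_origin(
    fpkm_row: pd.Series, samples: pd.DataFrame, min_fpkm: float = 1.0
) -> tuple[str, bool]:
    """polyA origin of one transcript from its FPKM profile.

    ``polyA_minus`` iff expressed above ``min_fpkm`` in at least one
    total-RNA sample and in no polyA+ sample; otherwise ``polyA_plus``.
    A transcript expressed nowhere defaults to ``polyA_plus`` and is flagged
    (second return value) — the FPKM filter rejects it anyway.
    """
    lib = samples["library_type"]
    total_ids = lib.index[lib == "total"]
    polya_ids = lib.index[lib == "polyA"]
    if len(total_ids) == 0 or len(polya_ids) == 0:
        raise ValueError("sample sheet needs both polyA and total libraries")
    in_total = bool((fpkm_row[total_ids] > min_fpkm).any())
    in_polya = bool((fpkm_row[polya_ids] > min_fpkm).any())
    if in_total and not in_polya:
        return "polyA_minus", False
    if not in_total and not in_polya:
        return "polyA_plus", True
    return "polyA_plus", False


@dataclass
class LncRNARecord:
    """Verdict trail of one candidate through the cascade."""

    transcript_id: str
    passed: bool
    rejection_reasons: list[str]
    class_code: str
    polyA_origin: str
    length_nt: int
    orf: OrfResult
    max_fpkm: float
    flagged_unexpressed: bool = False


def run_discovery(
    transcripts: list[TranscriptModel],
    evidence: dict[str, CodingEvidence],
    ann: GeneAnnotation,
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    config: DiscoveryConfig | None = None,
    known_lnc: GeneAnnotation | None = None,
) -> list[LncRNARecord]:
    """Run the full cascade; every transcript gets a record with its fate.

    Filter order (length, coding potential, protein-family hit, ORF size,
    class code, FPKM) affects only the recorded rejection reasons, never
    membership: all filters are always evaluated.
    """
    config = config or DiscoveryConfig()
    records = []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.transcript_id}: sequence required for ORF scan")
        ev = evidence.get(t.transcript_id, CodingEvidence())
        orf = find_orfs(t.sequence, min_aa=config.min_orf_aa_to_count)
        reasons: list[str] = []
        if t.length < config.min_length_nt:
            reasons.append("length")
        verdict = coding_potential_verdict(orf, ev, config, t.length)
        if verdict != "noncoding":
            reasons.append("coding_potential")
        if ev.pfam_best_evalue is not None and ev.pfam_best_evalue <= config.pfam_evalue_max:
            reasons.append("pfam")
        if orf.longest_orf_aa >= config.max_orf_aa:
            reasons.append("orf")
        code = classify_locus(t, ann, known_lnc)
        if code == "excluded":
            reasons.append("class_code")
        if t.transcript_id in fpkm.index:
            row = fpkm.loc[t.transcript_id]
            max_fpkm = float(row.max())
            origin, flagged = assign_polyA_origin(row, samples, config.min_fpkm)
        else:
            max_fpkm, origin, flagged = 0.0, "polyA_plus", True
        if max_fpkm <= config.min_fpkm:
            reasons.append("fpkm")
        records.append(
            LncRNARecord(
                transcript_id=t.transcript_id,
                passed=not reasons,
                rejection_reasons=reasons,
                class_code=code,
                polyA_origin=origin,
                length_nt=t.length,
                orf=orf,
                max_fpkm=max_fpkm,
                flagged_unexpressed=flagged,
            )
        )
    return records


SUMMARY_CATEGORIES = ("lincRNA", "intronic", "annotated_lnc_within", "annotated_lnc_overlap")
_CODE_TO_CATEGORY = {
    "u": "lincRNA",
    "i": "intronic",
    "annotated_lnc_within": "annotated_lnc_within",
    "annotated_lnc_overlap": "annotated_lnc_overlap",
}


def summary_table(
    records: list[LncRNARecord],
    te_flags: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Category accounting of passed lncRNAs: polyA origin x class code.

    Rows ``polyA_minus``, ``polyA_plus`` and ``Total``; columns ``total``,
    the four genomic categories, and (when TE flags are supplied)
    ``te_lncRNA`` and ``pct_te``.  Row totals equal the sum of the four
    category columns by construction.
    """
    passed = [r for r in records if r.passed]
    rows = {}
    for origin in ("polyA_minus", "polyA_plus"):
        sub = [r for r in passed if r.polyA_origin == origin]
        row = {cat: 0 for cat in SUMMARY_CATEGORIES}
        for r in sub:
            row[_CODE_TO_CATEGORY[r.class_code]] += 1
        row["total"] = len(sub)
        if te_flags is not None:
            n_te = sum(1 for r in sub if te_flags.get(r.transcript_id, False))
            row["te_lncRNA"] = n_te
            row["pct_te"] = round(100.0 * n_te / len(sub), 2) if sub else 0.0
        rows[origin] = row
    total = {
        k: rows["polyA_minus"][k] + rows["polyA_plus"][k]
        for k in rows["polyA_minus"]
        if k != "pct_te"
    }
    if te_flags is not None:
        total["pct_te"] = (
            round(100.0 * total["te_lncRNA"] / total["total"], 2) if total["total"] else 0.0
        )
    rows["Total"] = total
    cols = ["total"] + list(SUMMARY_CATEGORIES)
    if te_flags is not None:
        cols += ["te_lncRNA", "pct_te"]
    return pd.DataFrame(rows).T[cols]


def category_accounting(table: pd.DataFrame) -> dict[str, int]:
    """Check the row-sum property of a summary table.

    Returns ``{"category_sum": ..., "total": ...}`` where ``category_sum``
    adds the per-origin category counts (eight cells for two origins) and
    ``total`` is the declared grand total; the two must agree.
    """
    origins = [ix for ix in table.index if ix != "Total"]
    cat_sum = int(table.loc[origins, list(SUMMARY_CATEGORIES)].to_numpy().sum())
    total = int(table.loc["Total", "total"])
    return {"category_sum": cat_sum, "total": total}


def load_evidence_tables(
    cpc2_path=None, cnci_path=None, pfam_path=None
) -> dict[str, CodingEvidence]:
    """Merge CPC2/CNCI/Pfam TSVs into per-transcript evidence records."""
    out: dict[str, CodingEvidence] = {}

    def ev(tid: str) -> CodingEvidence:
        return out.setdefault(tid, CodingEvidence())

    if cpc2_path is not None:
        for _, row in pd.read_csv(cpc2_path, sep="\t").iterrows():
            e = ev(row["transcript_id"])
            e.cpc2_score = float(row["score"])
            e.cpc2_label = str(row["label"])
    if cnci_path is not None:
        for _, row in pd.read_csv(cnci_path, sep="\t").iterrows():
            ev(row["transcript_id"]).cnci_label = str(row["label"])
    if pfam_path is not None:
        for _, row in pd.read_csv(pfam_path, sep="\t").iterrows():
            ev(row["transcript_id"]).pfam_best_evalue = float(row["best_evalue"])
    return out
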