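"""The lncRNA filter cascade: ORF scanning, verdicts, class codes, FPKM."""

import numpy as np
import pandas as pd
import pytest

from telncrna.discovery import (
    CodingEvidence,
    DiscoveryConfig,
    assign_polyA_origin,
    category_accounting,
    classify_locus,
    coding_potential_verdict,
    compute_fpkm,
    find_orfs,
    run_discovery,
    summary_table,
)
from telncrna.intervals import Gene, GeneAnnotation, GenomicInterval, TranscriptModel

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq, min_aa):
    """All ATG..stop ORFs (longest per stop) by direct enumeration."""
    orfs = []
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        stops_seen = set()
        for si, codon in enumerate(codons):
            if codon not in STOPS or si in stops_seen:
                continue
            # longest ORF ending at this stop: earliest ATG after previous stop
            prev_stop = max(
                (sj for sj in range(si) if codons[sj] in STOPS), default=-1
            )
            starts = [sj for sj in range(prev_stop + 1, si) if codons[sj] == "ATG"]
            if starts:
                orfs.append(si - starts[0])  # aa count incl. Met, excl. stop
            stops_seen.add(si)
    count = sum(1 for aa in orfs if aa >= min_aa)
    return count, max(orfs, default=0)


class TestFindOrfs:
    def test_minimal_orf(self):
        res = find_orfs("ATGAAATAG", min_aa=1)
        assert res.longest_orf_aa == 2
        assert res.longest_orf_span == (0, 9)

    def test_no_atg(self):
        res = find_orfs("CCCCCC")
        assert res.orf_count == 0 and res.longest_orf_aa == 0

    def test_empty(self):
        assert find_orfs("").longest_orf_aa == 0

    def test_span_length_invariant(self):
        res = find_orfs("GGATGAAACCCTGAGG", min_aa=1)
        s, e = res.longest_orf_span
        assert e - s == 3 * res.longest_orf_aa + 3

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(9, 600))))
            res = find_orfs(seq, min_aa=10)
            count, longest = brute_force_orfs(seq, 10)
            assert (res.orf_count, res.longest_orf_aa) == (count, longest), seq


class TestCodingPotentialVerdict:
    CFG = DiscoveryConfig()

    def test_both_noncoding(self):
        ev = CodingEvidence(cpc2_score=-2.0, cnci_label="noncoding")
        orf = find_orfs("CCCCCC")
        assert coding_potential_verdict(orf, ev, self.CFG) == "noncoding"

    def test_intersection_rule(self):
        ev = CodingEvidence(cpc2_score=-2.0, cnci_label="coding")
        orf = find_orfs("CCCCCC")
        assert coding_potential_verdict(orf, ev, self.CFG) == "coding"

    def test_cpc2_threshold_is_strict(self):
        ev = CodingEvidence(cpc2_score=-1.0, cnci_label="noncoding")
        assert coding_potential_verdict(find_orfs("CCC"), ev, self.CFG) == "coding"

    def test_missing_evidence_strict_mode_errors(self):
        with pytest.raises(ValueError, match="require_both_predictors"):
            coding_potential_verdict(find_orfs("CCC"), CodingEvidence(), self.CFG)

    def test_internal_stand_in(self):
        cfg = DiscoveryConfig(require_both_predictors=False)
        # longest ORF 40 aa in a 600-nt transcript: coverage (3*40+3)/600=0.205
        orf = find_orfs("ATG" + "GCT" * 39 + "TAA", min_aa=1)
        assert orf.longest_orf_aa == 40
        assert (
            coding_potential_verdict(orf, CodingEvidence(), cfg, transcript_length=600)
            == "noncoding"
        )
        # same ORF in a 300-nt transcript covers 41% -> coding
        assert (
            coding_potential_verdict(orf, CodingEvidence(), cfg, transcript_length=300)
            == "coding"
        )


def _ann_one_gene():
    return GeneAnnotation(
        [
            Gene(
                "g1",
                GenomicInterval("chr1", 1000, 5000, "+"),
                [
                    GenomicInterval("chr1", 1000, 1500, "+"),
                    GenomicInterval("chr1", 3000, 5000, "+"),
                ],
            )
        ]
    )


def _single_exon(tid, start, end):
    return TranscriptModel(tid, tid, [GenomicInterval("chr1", start, end, "+")])


class TestClassifyLocus:
    def test_intronic(self):
        assert classify_locus(_single_exon("t", 2000, 2500), _ann_one_gene()) == "i"

    def test_intergenic(self):
        assert classify_locus(_single_exon("t", 15000, 15400), _ann_one_gene()) == "u"

    def test_one_bp_exon_overlap_excluded(self):
        assert classify_locus(_single_exon("t", 1499, 2000), _ann_one_gene()) == "excluded"

    def test_known_lnc_relabel(self):
        known = GeneAnnotation(
            [Gene("k1", GenomicInterval("chr1", 14000, 16000, "+"))]
        )
        assert (
            classify_locus(_single_exon("t", 15000, 15400), _ann_one_gene(), known)
            == "annotated_lnc_within"
        )
        assert (
            classify_locus(_single_exon("t", 13000, 15000), _ann_one_gene(), known)
            == "annotated_lnc_overlap"
        )

    def test_matches_per_base_oracle_on_random_placements(self):
        ann = _ann_one_gene()
        gene = ann.genes[0]
        exon_bases = set()
        for e in gene.exons:
            exon_bases.update(range(e.start, e.end))
        intron_bases = set()
        for i in gene.introns:
            intron_bases.update(range(i.start, i.end))
        span_bases = set(range(gene.span.start, gene.span.end))
        rng = np.random.default_rng(6)
        for _ in range(500):
            s = int(rng.integers(0, 8000))
            e = s + int(rng.integers(50, 900))
            t = _single_exon("t", s, e)
            bases = set(range(s, e))
            if bases & exon_bases:
                expected = "excluded"
            elif bases <= intron_bases:
                expected = "i"
            elif not (bases & span_bases):
                expected = "u"
            else:
                expected = "excluded"
            assert classify_locus(t, ann) == expected, (s, e)


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 500})
        fpkm = compute_fpkm(counts, lengths, pd.Series({"s1": 1e6}))
        assert fpkm.loc["a", "s1"] == 100.0
        assert fpkm.loc["b", "s1"] == 0.0

    def test_formula(self):
        counts = pd.DataFrame({"s1": [250]}, index=["a"])
        fpkm = compute_fpkm(counts, pd.Series({"a": 500}), pd.Series({"s1": 2e7}))
        assert fpkm.loc["a", "s1"] == pytest.approx(25.0)

    def test_zero_library_size_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"a": 100}), pd.Series({"s1": 0}))


class TestPolyAOrigin:
    SAMPLES = pd.DataFrame(
        {"library_type": ["polyA", "polyA", "total"]},
        index=["p1", "p2", "t1"],
    )

    def test_total_only(self):
        row = pd.Series({"p1": 0.0, "p2": 0.0, "t1": 5.0})
        assert assign_polyA_origin(row, self.SAMPLES) == ("polyA_minus", False)

    def test_polya_detected(self):
        row = pd.Series({"p1": 5.0, "p2": 0.0, "t1": 5.0})
        assert assign_polyA_origin(row, self.SAMPLES) == ("polyA_plus", False)

    def test_unexpressed_flagged(self):
        row = pd.Series({"p1": 0.0, "p2": 0.0, "t1": 0.0})
        origin, flagged = assign_polyA_origin(row, self.SAMPLES)
        assert origin == "polyA_plus" and flagged

    def test_missing_library_type_errors(self):
        samples = pd.DataFrame({"library_type": ["polyA"]}, index=["p1"])
        with pytest.raises(ValueError):
            assign_polyA_origin(pd.Series({"p1": 1.0}), samples)


class TestRunDiscovery:
    """Single-filter rejections on hand-built transcripts."""

    def _base_inputs(self, t, fpkm_value=5.0):
        samples = pd.DataFrame(
            {"library_type": ["polyA", "total"]}, index=["s1", "s2"]
        )
        fpkm = pd.DataFrame(
            {"s1": [fpkm_value], "s2": [0.0]}, index=[t.transcript_id]
        )
        ev = {
            t.transcript_id: CodingEvidence(
                cpc2_score=-2.0, cnci_label="noncoding", pfam_best_evalue=None
            )
        }
        ann = GeneAnnotation([Gene("g", GenomicInterval("chr1", 900000, 901000, "+"))])
        return ev, ann, fpkm, samples

    def _noncoding_transcript(self, tid="t1", length=300, start=0):
        rng = np.random.default_rng(7)
        from telncrna.simulate import random_noncoding_sequence

        seq = random_noncoding_sequence(rng, length)
        return TranscriptModel(
            tid, tid, [GenomicInterval("chr1", start, start + length, "+")], seq
        )

    def test_short_transcript_rejected_for_length(self):
        t = self._noncoding_transcript(length=150)
        ev, ann, fpkm, samples = self._base_inputs(t)
        (rec,) = run_discovery([t], ev, ann, fpkm, samples)
        assert not rec.passed and rec.rejection_reasons == ["length"]

    def test_long_orf_rejected(self):
        seq = "ATG" + "GCT" * 119 + "TAA"
        pad = "C" * (0)
        t = TranscriptModel(
            "t1", "t1", [GenomicInterval("chr1", 0, len(seq), "+")], seq
        )
        ev, ann, fpkm, samples = self._base_inputs(t)
        (rec,) = run_discovery([t], ev, ann, fpkm, samples)
        assert rec.orf.longest_orf_aa == 120
        assert "orf" in rec.rejection_reasons

    def test_pfam_boundary(self):
        t = self._noncoding_transcript()
        ev, ann, fpkm, samples = self._base_inputs(t)
        ev[t.transcript_id].pfam_best_evalue = 1e-6
        (rec,) = run_discovery([t], ev, ann, fpkm, samples)
        assert "pfam" in rec.rejection_reasons
        ev[t.transcript_id].pfam_best_evalue = 1e-4
        (rec,) = run_discovery([t], ev, ann, fpkm, samples)
        assert rec.passed

    def test_fpkm_filter_strict(self):
        t = self._noncoding_transcript()
        ev, ann, fpkm, samples = self._base_inputs(t, fpkm_value=1.0)
        (rec,) = run_discovery([t], ev, ann, fpkm, samples)
        assert rec.rejection_reasons == ["fpkm"]


class TestSummaryAccounting:
    def test_row_sums_conserved_on_synthetic_run(self, default_run):
        table = default_run["summary"]
        acc = category_accounting(table)
        assert acc["category_sum"] == acc["total"]
        # per-origin rows also sum across categories
        for origin in ("polyA_minus", "polyA_plus"):
            row = table.loc[origin]
            cats = row[["lincRNA", "intronic", "annotated_lnc_within",
                        "annotated_lnc_overlap"]].sum()
            assert cats == row["total"]


class TestPlantedRecovery:
    def test_every_planted_coding_transcript_rejected(self, default_run):
        truth = default_run["truth"]
        passed = {r.transcript_id for r in default_run["records"] if r.passed}
        coding = {t for t, c in truth.true_class.items() if c == "coding"}
        assert not (passed & coding)

    def test_planted_lncRNA_recall(self, default_run):
        truth = default_run["truth"]
        passed = {r.transcript_id for r in default_run["records"] if r.passed}
        lnc = {t for t, c in truth.true_class.items() if c != "coding"}
        assert len(passed & lnc) / len(lnc) >= 0.95

    def test_polyA_origin_recovered(self, default_run):
        truth = default_run["truth"]
        minus = set(truth.polyA_minus_ids)
        for r in default_run["records"]:
            if r.passed:
                expected = "polyA_minus" if r.transcript_id in minus else "polyA_plus"
                assert r.polyA_origin == expected

    def test_intronic_class_recovered(self, default_run):
        truth = default_run["truth"]
        by_id = {r.transcript_id: r for r in default_run["records"]}
        for tid in truth.intronic_ids:
            assert by_id[tid].class_code == "i"
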