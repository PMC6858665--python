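#!/usr/bin/env python
"""TE masking of discovered lncRNAs and superfamily enrichment.

Computes per-lncRNA masked fractions against the TE annotation, calls
TE-lncRNAs, tabulates superfamily composition of TE-lncRNA bases vs all
genomic TE bases (with fold ratios), tests the polyA- vs polyA+ TE-overlap
contrast by chi-squared, and bins masked fractions.
"""

import argparse
from pathlib import Path

from telncrna.pipeline import PipelineConfig, run_pipeline
from telncrna.te_overlap import chisq_2x2, masked_fraction_histogram

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "te")
    args = ap.parse_args()

    bundle = run_pipeline(
        PipelineConfig(dataset_dir=str(args.dataset), results_dir=str(args.out)),
        stages=("discover", "te"),
    )
    results = bundle["te_results"]
    n_te = sum(1 for r in results if r.is_te_lncRNA)
    print(f"{n_te} of {len(results)} lncRNAs overlap TEs "
          f"({100 * n_te / len(results):.1f}%)")

    hist, ge90 = masked_fraction_histogram(results)
    print(f"{ge90} TE-lncRNAs are >= 90% TE-covered "
          f"({100 * ge90 / max(n_te, 1):.0f}% of TE-lncRNAs)")
    print(hist.to_string())

    by_origin = {"polyA_minus": [0, 0], "polyA_plus": [0, 0]}
    origin = {r.transcript_id: r.polyA_origin for r in bundle["records"]}
    for r in results:
        row = by_origin[origin[r.transcript_id]]
        row[0 if r.is_te_lncRNA else 1] += 1
    stat, p = chisq_2x2([by_origin["polyA_minus"], by_origin["polyA_plus"]])
    print(f"TE overlap by polyA origin {by_origin}: chi2={stat:.2f}, p={p:.3g}")

    enr = bundle["enrichment"]
    groups = enr[enr["kind"] == "group"][
        ["name", "pct_of_te_lnc_bp", "pct_of_genomic_te_bp", "fold_ratio"]
    ]
    print("grouped enrichment (share of TE-lncRNA bases vs genomic TE bases):")
    print(groups.to_string(index=False))


if __name__ == "__main__":
    main()
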