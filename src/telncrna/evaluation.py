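"""Recovery benchmarks and worked-example arithmetic.

Two kinds of checks live here.  The worked examples run the package's
accounting and enrichment operations on published summary counts from a
large maize lncRNA survey (category counts by polyA origin, TE superfamily
composition of lncRNA vs genomic TE bases).  The recovery benchmarks
re-generate synthetic data with planted truth and measure how well each
analysis stage recovers it: type-I error and effect recovery of the NB
test, module/hub recovery of the network stage, cis-correlation recovery,
and discovery recall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import diffexpr, network
from .downstream import cis_correlation
from .simulate import SimulationConfig, simulate_dataset
from .te_overlap import chisq_2x2, enrichment_fold

#: Published worked-example counts for a maize lncRNA catalogue:
#: per-origin category counts (intergenic / intronic / within known lncRNA
#: loci / overlapping known lncRNA loci), TE-overlap tallies, and the
#: DNA-transposon base-pair shares among TE-lncRNAs vs genomic TEs.
REFERENCE_SUMMARY = {
    "categories": {
        "polyA_minus": {"lincRNA": 9153, "intronic": 29,
                        "annotated_lnc_within": 189, "annotated_lnc_overlap": 116},
        "polyA_plus": {"lincRNA": 11346, "intronic": 156,
                       "annotated_lnc_within": 1201, "annotated_lnc_overlap": 1119},
    },
    "row_totals": {"polyA_minus": 9487, "polyA_plus": 13822},
    "total_lncRNA": 23309,
    "total_lincRNA": 20499,
    "n_te_lncRNA": 15312,
    "n_te_lncRNA_ge90_masked": 9341,
    "te_pct_by_origin": {"polyA_minus": 79.26, "polyA_plus": 56.37},
    "dna_pct_of_te_lnc_bp": 12.10,
    "dna_pct_of_genomic_te_bp": 5.96,
}


def table1_accounting() -> dict[str, int]:
    """Sum the eight per-category worked-example counts and compare with the
    declared catalogue total."""
    cats = REFERENCE_SUMMARY["categories"]
    cat_sum = sum(v for row in cats.values() for v in row.values())
    return {"category_sum": cat_sum, "total": REFERENCE_SUMMARY["total_lncRNA"]}


def polyA_minus_lincRNA_share_pct() -> float:
    """Share of intergenic lncRNAs discovered only in total-RNA libraries."""
    r = REFERENCE_SUMMARY
    return 100.0 * r["categories"]["polyA_minus"]["lincRNA"] / r["total_lincRNA"]


def te_lncRNA_share_pct() -> float:
    r = REFERENCE_SUMMARY
    return 100.0 * r["n_te_lncRNA"] / r["total_lncRNA"]


def ge90_masked_share_pct() -> float:
    r = REFERENCE_SUMMARY
    return 100.0 * r["n_te_lncRNA_ge90_masked"] / r["n_te_lncRNA"]


def dna_transposon_fold() -> float:
    r = REFERENCE_SUMMARY
    return enrichment_fold(r["dna_pct_of_te_lnc_bp"], r["dna_pct_of_genomic_te_bp"])


def polyA_te_enrichment_p() -> float:
    """Chi-squared p for the higher TE-overlap rate among total-RNA-only
    lncRNAs, at the worked-example row sizes."""
    r = REFERENCE_SUMMARY
    table = []
    for origin in ("polyA_minus", "polyA_plus"):
        n = r["row_totals"][origin]
        k = round(r["te_pct_by_origin"][origin] / 100.0 * n)
        table.append([k, n - k])
    _stat, p = chisq_2x2(table)
    return p


def _nb(rng: np.random.Generator, mu, alpha: float, shape):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=shape)


def nb_type1_error(seed: int, n: int = 2000, per_arm: int = 3,
                   alpha: float = 0.1, level: float = 0.05) -> float:
    """Fraction of null transcripts with p below ``level``."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(100), 1.0, size=n)[:, None]
    cols = [f"T{i}" for i in range(per_arm)] + [f"C{i}" for i in range(per_arm)]
    counts = pd.DataFrame(_nb(rng, mu, alpha, (n, 2 * per_arm)),
                          index=[f"t{i}" for i in range(n)], columns=cols)
    spec = diffexpr.ContrastSpec("null", cols[:per_arm], cols[per_arm:])
    res = diffexpr.nb_wald_test(
        counts, spec, diffexpr.median_ratio_size_factors(counts)
    )
    return float((res["p"] < level).mean())


def lfc_recovery(seed: int, n: int = 2000, per_arm: int = 6,
                 mu: float = 100.0, lfc: float = 2.0, alpha: float = 0.1) -> float:
    """Mean estimated log2FC at a planted effect of ``lfc``."""
    rng = np.random.default_rng(seed)
    cols = [f"T{i}" for i in range(per_arm)] + [f"C{i}" for i in range(per_arm)]
    treat = _nb(rng, mu * 2**lfc, alpha, (n, per_arm))
    ctrl = _nb(rng, mu, alpha, (n, per_arm))
    counts = pd.DataFrame(np.hstack([treat, ctrl]),
                          index=[f"t{i}" for i in range(n)], columns=cols)
    spec = diffexpr.ContrastSpec("fc", cols[:per_arm], cols[per_arm:])
    res = diffexpr.nb_wald_test(counts, spec, pd.Series(1.0, index=cols))
    return float(res["log2FC"].mean())


def module_hub_recovery(seed: int) -> tuple[float, float]:
    """(ARI vs planted modules, planted-hub recall) for one default dataset."""
    cfg = SimulationConfig(seed=seed)
    _tr, _ann, _te, counts, sheet, truth, _fa = simulate_dataset(cfg)
    samples = sheet.frame
    polya = samples.index[samples["library_type"] == "polyA"]
    factors = diffexpr.median_ratio_size_factors(counts[polya])
    expressed = counts.index[(counts[polya] > 0).any(axis=1)]
    net = network.build_network(counts.loc[expressed, polya], factors)
    t_lab = [truth.module_labels.get(t, 0) for t in net.modules.index]
    i_lab = [0 if m == "grey" else int(m[1:]) for m in net.modules]
    ari = adjusted_rand_score(t_lab, i_lab)
    traits = network.trait_indicators(samples.loc[polya])
    mt = network.module_trait_correlation(net.eigengenes, traits, net.expr)
    hubs = network.find_hubs(
        net.modules, net.kme, net.kim, mt, network.NetworkConfig()
    )
    found = set(hubs["transcript_id"])
    recall = len(found & set(truth.hub_ids)) / len(truth.hub_ids)
    return float(ari), float(recall)


def cis_recovery(seed: int, n_pairs: int = 90) -> tuple[float, int]:
    """(estimated pooled cis correlation, number of pairs) at planted r=0.5."""
    cfg = SimulationConfig(
        seed=seed, frac_te_derived=0.0, frac_intronic=0.0, n_modules=0,
        de_fraction=0.0, n_cis_pairs=n_pairs, frac_total_rna_only=0.0,
        genome_length=2_400_000, n_genes=260,
    )
    _tr, _ann, _te, counts, sheet, truth, _fa = simulate_dataset(cfg)
    samples = sheet.frame
    factors = diffexpr.median_ratio_size_factors(
        counts[samples.index[samples["library_type"] == "polyA"]]
    )
    tables = {
        s.name: diffexpr.nb_wald_test(counts, s, factors)
        for s in diffexpr.contrasts_from_samples(samples)
    }
    r, _p, paired = cis_correlation(truth.cis_pairs, tables)
    return float(r), len(paired)


def discovery_recall(bundle: dict, truth) -> tuple[float, int]:
    """Fraction of planted lncRNAs retained by the filter cascade."""
    passed = {r.transcript_id for r in bundle["records"] if r.passed}
    lnc = {t for t, c in truth.true_class.items() if c != "coding"}
    return len(passed & lnc) / len(lnc), len(lnc)
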