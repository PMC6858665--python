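"""Downstream characterization: cis effects, expression summaries, term
enrichment and qPCR fold-change utilities."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneAnnotation, GenomicInterval


@dataclass
class NearestGeneLink:
    lncRNA_id: str | None
    gene_id: str
    distance: int  # gap bp between spans; 0 when touching/overlapping
    side: str      # upstream / downstream / overlapping
    tie: bool = False


def nearest_gene(locus: GenomicInterval, ann: GeneAnnotation, lncRNA_id: str | None = None) -> NearestGeneLink:
    """Closest gene to a lncRNA locus by span-to-span gap distance.

    Overlapping genes (e.g. the host of an intronic lncRNA) have distance 0.
    An exact distance tie between an upstream and a downstream flank picks
    the upstream gene and flags the tie.
    """
    genes = ann.by_chrom().get(locus.chrom, [])
    if not genes:
        raise ValueError(f"no genes on {locus.chrom}")
    best: tuple[int, int, Gene] | None = None  # (distance, side_rank, gene)
    tie = False
    for g in genes:
        if g.span.overlaps(locus):
            d, side = 0, "overlapping"
        elif g.span.end <= locus.start:
            d, side = locus.start - g.span.end, "upstream"
        else:
            d, side = g.span.start - locus.end, "downstream"
        rank = {"overlapping": 0, "upstream": 1, "downstream": 2}[side]
        if best is None or (d, rank) < (best[0], best[1]):
            tie = best is not None and d == best[0]
            best = (d, rank, g, side)
        elif d == best[0]:
            tie = True
    d, _rank, g, side = best
    return NearestGeneLink(lncRNA_id, g.gene_id, d, side, tie)


def cis_correlation(
    pairs: list[tuple[str, str]],
    lfc_tables: dict[str, pd.DataFrame],
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of (lncRNA log2FC, nearest-gene log2FC) pairs
    pooled across contrasts; p from the t distribution with df n-2."""
    rows = []
    for contrast, table in lfc_tables.items():
        for lnc, gene in pairs:
            if lnc in table.index and gene in table.index:
                a = float(table.loc[lnc, "log2FC"])
                b = float(table.loc[gene, "log2FC"])
                if math.isfinite(a) and math.isfinite(b):
                    rows.append({"contrast": contrast, "lncRNA": lnc, "gene": gene,
                                 "lnc_log2FC": a, "gene_log2FC": b})
    paired = pd.DataFrame(rows)
    if len(paired) < 3:
        raise ValueError("need >= 3 finite (lncRNA, gene) log2FC pairs")
    r, p = stats.pearsonr(paired["lnc_log2FC"], paired["gene_log2FC"])
    return float(r), float(p), paired


def expression_summary(fpkm: pd.DataFrame, classes: dict[str, str]) -> pd.DataFrame:
    """Per-class mean of each transcript's maximum FPKM over samples, with
    ratios to the highest class mean."""
    max_fpkm = fpkm.max(axis=1)
    rows = {}
    for cls in sorted(set(classes.values())):
        ids = [t for t in fpkm.index if classes.get(t) == cls]
        if ids:
            rows[cls] = {"n": len(ids), "mean_max_fpkm": float(max_fpkm[ids].mean())}
    frame = pd.DataFrame(rows).T
    top = frame["mean_max_fpkm"].max()
    ref = frame["mean_max_fpkm"].idxmax()
    frame["ratio_vs_" + str(ref)] = top / frame["mean_max_fpkm"]
    return frame


def shannon_entropy(group_means) -> float:
    """Shannon entropy (bits) of a transcript's mean expression across
    condition groups; NaN when all means are zero."""
    m = np.asarray(group_means, dtype=float)
    if (m < 0).any():
        raise ValueError("group means must be nonnegative")
    total = m.sum()
    if total <= 0:
        return float("nan")
    p = m / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_by_class(
    expr: pd.DataFrame, samples: pd.DataFrame, classes: dict[str, str],
    group_cols: tuple[str, ...] = ("condition", "stage"),
) -> pd.DataFrame:
    """Mean per-transcript entropy by class over (condition x stage) group
    means (the expression-breadth comparison between coding RNAs and
    lncRNAs)."""
    key = samples[list(group_cols)].astype(str).agg("_".join, axis=1)
    group_mean = expr.T.groupby(key).mean().T
    ent = group_mean.apply(lambda row: shannon_entropy(row.to_numpy()), axis=1)
    rows = {}
    for cls in sorted(set(classes.values())):
        ids = [t for t in ent.index if classes.get(t) == cls and math.isfinite(ent[t])]
        if ids:
            rows[cls] = {"n": len(ids), "mean_entropy_bits": float(ent[ids].mean())}
    return pd.DataFrame(rows).T


def fisher_enrichment(
    selected: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per term with Bonferroni
    adjustment over the tested terms.

    ``selected`` must be a subset of ``universe``; term members outside the
    universe are ignored.  Terms sharing no member with the selection get
    p = 1 (the upper tail from overlap 0 is the whole distribution).
    """
    stray = selected - universe
    if stray:
        raise ValueError(f"selected ids outside universe: {sorted(stray)[:5]}")
    n_terms = len(term_map)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & universe
        k = len(selected & members)
        # hypergeometric upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(selected)))
        p_bonf = min(1.0, p * n_terms)
        rows.append(
            {
                "term": term,
                "term_size": len(members),
                "selected_in_term": k,
                "p": p,
                "p_bonferroni": p_bonf,
                "enriched": p_bonf < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def ddct_fold_change(ct: pd.DataFrame) -> tuple[float, float, float]:
    """Comparative 2^(-ddCt) fold change from replicate Ct values.

    ``ct`` needs columns ``role`` (target/reference), ``arm``
    (treated/control) and ``Ct``.  ddCt = (target - reference) under
    treatment minus the same under control; fold = 2**(-ddCt); the SE is
    propagated from the four cell variances and mapped to the fold scale as
    ``fold * ln2 * SE(ddCt)``.
    """
    cells = {}
    for role in ("target", "reference"):
        for arm in ("treated", "control"):
            sub = ct[(ct["role"] == role) & (ct["arm"] == arm)]["Ct"]
            if len(sub) == 0:
                raise ValueError(f"missing Ct replicates for {role}/{arm}")
            var = float(sub.var(ddof=1)) if len(sub) > 1 else 0.0
            cells[(role, arm)] = (float(sub.mean()), var / len(sub))
    ddct = (
        cells[("target", "treated")][0] - cells[("reference", "treated")][0]
    ) - (
        cells[("target", "control")][0] - cells[("reference", "control")][0]
    )
    se_ddct = math.sqrt(sum(v for _m, v in cells.values()))
    fold = 2.0 ** (-ddct)
    return ddct, fold, fold * math.log(2.0) * se_ddct
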