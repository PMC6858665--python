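"""Negative-binomial differential expression for stress-vs-control contrasts.

The stage defines its own NB Wald test rather than wrapping an external DE
package: median-of-ratios size factors, per-transcript method-of-moments
dispersion pooled across the two arms, shrinkage-free log2 fold changes on
pseudo-counted normalized means, a delta-method standard error and a
two-sided normal p-value, followed by Benjamini-Hochberg adjustment and the
call rule |log2FC| > 1 with adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ContrastSpec:
    """One stress-vs-control comparison with >= 2 replicates per arm."""

    name: str
    treatment: list[str]
    control: list[str]

    def __post_init__(self) -> None:
        if set(self.treatment) & set(self.control):
            raise ValueError(f"{self.name}: arms must be disjoint")
        if len(self.treatment) < 2 or len(self.control) < 2:
            raise ValueError(f"{self.name}: each arm needs >= 2 replicates")


def contrasts_from_samples(samples: pd.DataFrame) -> list[ContrastSpec]:
    """Build stress-vs-same-stage-control contrasts from a sample sheet.

    Only polyA+ libraries enter contrasts (total-RNA samples serve lncRNA
    discovery, not differential testing).
    """
    polya = samples[samples["library_type"] == "polyA"]
    specs = []
    for (cond, stage), sub in polya.groupby(["condition", "stage"], sort=True):
        if bool(sub["is_control"].iloc[0]):
            continue
        ctrl = polya[(polya["stage"] == stage) & polya["is_control"]]
        if len(ctrl) >= 2 and len(sub) >= 2:
            specs.append(
                ContrastSpec(f"{cond}_{stage}", list(sub.index), list(ctrl.index))
            )
    return specs


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Falls back to library-size ratios (with the same rescaling) when no
    transcript is nonzero in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    else:
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("empty sample column; cannot normalize")
        factors = lib
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    spec: ContrastSpec,
    factors: pd.Series,
    pseudo: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-transcript NB Wald test for one contrast.

    Dispersion alpha (variance mu + alpha mu^2) is estimated by method of
    moments from within-arm residuals of the normalized counts, floored at
    ``dispersion_floor``.  log2FC uses group means with a pseudo-count; its
    SE comes from the NB variance via the delta method.  The Wald statistic
    is referred to a t distribution with the pooled residual degrees of
    freedom (n_T + n_C - 2), which keeps the test calibrated at the small
    replicate numbers typical of stress experiments; with many replicates
    this converges to the normal reference.  All-zero transcripts get
    log2FC 0 and p 1.
    """
    t_ids, c_ids = spec.treatment, spec.control
    q = counts[t_ids + c_ids].to_numpy(dtype=float) / factors[t_ids + c_ids].to_numpy()
    nt, nc = len(t_ids), len(c_ids)
    qt, qc = q[:, :nt], q[:, nt:]
    mt, mc = qt.mean(axis=1), qc.mean(axis=1)

    # pooled within-arm method-of-moments dispersion
    ss = ((qt - mt[:, None]) ** 2).sum(axis=1) + ((qc - mc[:, None]) ** 2).sum(axis=1)
    s2 = ss / max(nt + nc - 2, 1)
    m_pool = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m_pool) / np.square(m_pool)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    log2fc = np.log2(mt + pseudo) - np.log2(mc + pseudo)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        (mt + alpha * mt**2) / (nt * np.square(mt + pseudo))
        + (mc + alpha * mc**2) / (nc * np.square(mc + pseudo))
    ) / ln2sq
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    df = max(nt + nc - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    all_zero = (q == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "baseMean": m_pool,
            "log2FC": log2fc,
            "se": se,
            "p": p,
            "padj": benjamini_hochberg(pd.Series(p, index=counts.index)),
        },
        index=counts.index,
    )


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """Step-up FDR adjustment, monotone and capped at 1; NaNs propagate and
    are excluded from the ranking."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return pd.Series(out, index=p.index if isinstance(p, pd.Series) else None, name="padj")


def call_de(
    result: pd.DataFrame, lfc_min: float = 1.0, padj_max: float = 0.05
) -> pd.Series:
    """``up``/``down``/``ns`` per transcript: |log2FC| > lfc_min and
    padj < padj_max."""
    sig = result["padj"] < padj_max
    up = sig & (result["log2FC"] > lfc_min)
    down = sig & (result["log2FC"] < -lfc_min)
    calls = pd.Series("ns", index=result.index, name="call")
    calls[up] = "up"
    calls[down] = "down"
    return calls


def de_overlap_summary(
    results: dict[str, pd.DataFrame],
    classes: dict[str, str],
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> dict:
    """Cross-contrast DE accounting.

    Returns per-contrast up/down counts split by transcript class
    (coding / lncRNA / TE_lncRNA), pairwise DE-set intersections, and the
    non-redundant union size per class.
    """
    calls = {
        name: call_de(res, lfc_min, padj_max) for name, res in results.items()
    }
    de_sets = {
        name: set(c.index[c != "ns"]) for name, c in calls.items()
    }
    class_names = sorted(set(classes.values()))
    table_rows = []
    for name, c in calls.items():
        for cls in class_names:
            ids = [t for t in c.index if classes.get(t) == cls]
            sub = c[ids]
            table_rows.append(
                {
                    "contrast": name,
                    "class": cls,
                    "up": int((sub == "up").sum()),
                    "down": int((sub == "down").sum()),
                }
            )
    names = sorted(de_sets)
    intersections = {
        f"{a}&{b}": len(de_sets[a] & de_sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    union_by_class = {
        cls: len(
            {t for s in de_sets.values() for t in s if classes.get(t) == cls}
        )
        for cls in class_names
    }
    return {
        "counts": pd.DataFrame(table_rows),
        "de_sets": de_sets,
        "intersections": intersections,
        "union_by_class": union_by_class,
        "union_total": len(set().union(*de_sets.values())) if de_sets else 0,
    }
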