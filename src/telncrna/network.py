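"""Unsigned weighted co-expression network with TOM modules and hub calls.

Adjacency is ``|pearson|**beta`` (default soft threshold beta = 12), module
structure comes from average-linkage clustering of TOM dissimilarity with a
flat cut, eigengenes are first principal components of standardized module
expression, and hubs are module members in the top 10 % of intramodular
connectivity with module membership (kME) > 0.9 and gene-trait significance
p < 0.01 against the module's best-correlated trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GREY = "grey"


@dataclass
class NetworkConfig:
    beta: float = 12.0
    prefilter_min_r2: float | None = None  # optional pairwise r^2 retention
    min_module_size: int = 20
    cut_height: float = 0.9
    hub_kim_top_frac: float = 0.10
    hub_kme_min: float = 0.9
    hub_gs_p_max: float = 0.01

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.hub_kim_top_frac <= 1:
            raise ValueError("hub_kim_top_frac must be in (0, 1]")


def vst_transform(
    counts: pd.DataFrame, factors: pd.Series
) -> tuple[pd.DataFrame, pd.Index]:
    """``log2(count/size_factor + 1)``; returns the matrix and the index of
    zero-variance rows (flagged, to be excluded from correlations)."""
    norm = counts.to_numpy(dtype=float) / factors[counts.columns].to_numpy()
    expr = pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)
    flat = expr.index[expr.std(axis=1, ddof=0) == 0.0]
    return expr, flat


def prefilter_correlated(expr: pd.DataFrame, min_r2: float) -> pd.DataFrame:
    """Keep transcripts having >= 1 partner with squared Pearson >= min_r2."""
    r = np.corrcoef(expr.to_numpy())
    np.fill_diagonal(r, 0.0)
    keep = (r**2 >= min_r2).any(axis=1)
    return expr.loc[keep]


def soft_adjacency(expr: pd.DataFrame, beta: float = 12.0) -> pd.DataFrame:
    """Unsigned adjacency ``|r|**beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    r = np.corrcoef(expr.to_numpy())
    if np.isnan(r).any():
        raise ValueError("zero-variance rows must be removed before adjacency")
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: ``(sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu`` and unit diagonal."""
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # u = i and u = j terms vanish with zero diagonal
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Average-linkage clustering on 1 - TOM, flat cut at ``cut_height``.

    Clusters below ``min_module_size`` become ``grey``; surviving modules
    are labelled ``M1, M2, ...`` by decreasing size (ties broken by the
    lexicographically smallest member id), so labels do not depend on the
    input row order.
    """
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=config.cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= config.min_module_size].index
    ordered = sorted(
        keep,
        key=lambda c: (-sizes[c], min(labels.index[labels == c])),
    )
    rename = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    return labels.map(lambda c: rename.get(c, GREY)).rename("module")


def module_eigengene(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of row-standardized member expression.

    Unit-normalized over samples; the sign is chosen so the eigengene
    correlates non-negatively with the members' mean standardized profile.
    A single-member module returns that member's z-scored profile.
    """
    if not members:
        raise ValueError("module has no members")
    sub = expr.loc[members].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True, ddof=0)
    sd[sd == 0] = 1.0
    zs = (sub - mu) / sd
    if len(members) == 1:
        return pd.Series(zs[0], index=expr.columns, name="eigengene")
    _u, _s, vt = np.linalg.svd(zs, full_matrices=False)
    eig = vt[0]
    mean_profile = zs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    names = sorted(m for m in modules.unique() if m != GREY)
    return pd.DataFrame(
        {m: module_eigengene(expr, list(modules.index[modules == m])) for m in names}
    ).T


def _cor_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t distribution, df n-2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def trait_indicators(samples: pd.DataFrame) -> pd.DataFrame:
    """One-hot (condition x stage) indicators per sample."""
    key = samples["condition"].astype(str) + "_" + samples["stage"].astype(str)
    return pd.get_dummies(key).astype(float)


@dataclass
class ModuleTraitResult:
    r: pd.DataFrame          # module x trait
    p: pd.DataFrame
    gs_r: pd.DataFrame       # transcript x trait
    gs_p: pd.DataFrame
    dropped_traits: list[str] = field(default_factory=list)

    def best_trait(self, module: str) -> str:
        return self.r.loc[module].abs().idxmax()


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    expr: pd.DataFrame | None = None,
) -> ModuleTraitResult:
    """Pearson r and t-distribution p per (module, trait); the same machinery
    yields per-transcript gene significance when ``expr`` is given.
    Constant traits are dropped and reported."""
    n = traits.shape[0]
    keep = [c for c in traits.columns if traits[c].std(ddof=0) > 0]
    dropped = [c for c in traits.columns if c not in keep]
    tmat = traits[keep].to_numpy(dtype=float)

    def cor_block(x: np.ndarray) -> np.ndarray:
        xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True, ddof=0)
        tz = (tmat - tmat.mean(axis=0)) / tmat.std(axis=0, ddof=0)
        return (xz @ tz) / n

    r_mod = cor_block(eigengenes.to_numpy(dtype=float))
    res = ModuleTraitResult(
        r=pd.DataFrame(r_mod, index=eigengenes.index, columns=keep),
        p=pd.DataFrame(_cor_p(r_mod, n), index=eigengenes.index, columns=keep),
        gs_r=pd.DataFrame(columns=keep),
        gs_p=pd.DataFrame(columns=keep),
        dropped_traits=dropped,
    )
    if expr is not None:
        r_gs = cor_block(expr.to_numpy(dtype=float))
        res.gs_r = pd.DataFrame(r_gs, index=expr.index, columns=keep)
        res.gs_p = pd.DataFrame(_cor_p(r_gs, n), index=expr.index, columns=keep)
    return res


def kme_kim(
    expr: pd.DataFrame,
    adjacency: pd.DataFrame,
    modules: pd.Series,
    eigengenes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """kME(t, M) = cor(expr_t, eigengene_M); kIM(t) = within-module adjacency
    row sum (absent for grey transcripts)."""
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True, ddof=0)
    e = eigengenes.to_numpy(dtype=float)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True, ddof=0)
    kme = pd.DataFrame(
        (xz @ ez.T) / x.shape[1], index=expr.index, columns=eigengenes.index
    )
    kim = pd.Series(np.nan, index=expr.index, name="kIM")
    a = adjacency.to_numpy(dtype=float)
    idx = {t: i for i, t in enumerate(adjacency.index)}
    for m in eigengenes.index:
        members = list(modules.index[modules == m])
        rows = [idx[t] for t in members]
        sub = a[np.ix_(rows, rows)]
        np.fill_diagonal(sub, 0.0)
        kim[members] = sub.sum(axis=1)
    return kme, kim


def find_hubs(
    modules: pd.Series,
    kme: pd.DataFrame,
    kim: pd.Series,
    module_trait: ModuleTraitResult,
    config: NetworkConfig,
    classes: dict[str, str] | None = None,
    tf_families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hub table: top-``hub_kim_top_frac`` kIM within the module, own-module
    kME above ``hub_kme_min``, and gene significance p below
    ``hub_gs_p_max`` against the module's best-correlated trait."""
    rows = []
    for m in kme.columns:
        members = list(modules.index[modules == m])
        if not members:
            continue
        n_top = int(np.ceil(config.hub_kim_top_frac * len(members)))
        ranked = kim[members].sort_values(ascending=False)
        top = set(ranked.index[:n_top])
        trait = module_trait.best_trait(m)
        for t in members:
            if t not in top:
                continue
            if kme.loc[t, m] <= config.hub_kme_min:
                continue
            gs_p = float(module_trait.gs_p.loc[t, trait]) if t in module_trait.gs_p.index else np.nan
            if not (gs_p < config.hub_gs_p_max):
                continue
            rows.append(
                {
                    "transcript_id": t,
                    "module": m,
                    "kIM": float(kim[t]),
                    "kME": float(kme.loc[t, m]),
                    "best_trait": trait,
                    "gs_p": gs_p,
                    "class": (classes or {}).get(t, "coding"),
                    "tf_family": (tf_families or {}).get(t, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "module", "kIM", "kME", "best_trait", "gs_p",
            "class", "tf_family",
        ],
    )


@dataclass
class CoexpressionNetwork:
    """All derived network layers for one expression matrix."""

    expr: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    kim: pd.Series
    config: NetworkConfig


def build_network(
    counts: pd.DataFrame,
    factors: pd.Series,
    config: NetworkConfig | None = None,
) -> CoexpressionNetwork:
    """counts -> VST -> adjacency -> TOM -> modules -> eigengenes/kME/kIM."""
    config = config or NetworkConfig()
    expr, flat = vst_transform(counts, factors)
    expr = expr.drop(index=flat)
    if config.prefilter_min_r2 is not None:
        expr = prefilter_correlated(expr, config.prefilter_min_r2)
    adjacency = soft_adjacency(expr, config.beta)
    tom = tom_similarity(adjacency)
    modules = detect_modules(tom, config)
    eigengenes = module_eigengenes(expr, modules)
    if len(eigengenes):
        kme, kim = kme_kim(expr, adjacency, modules, eigengenes)
    else:
        kme = pd.DataFrame(index=expr.index)
        kim = pd.Series(np.nan, index=expr.index, name="kIM")
    return CoexpressionNetwork(expr, adjacency, tom, modules, eigengenes, kme, kim, config)
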