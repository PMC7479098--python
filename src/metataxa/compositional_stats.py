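"""Compositional analysis of the SLP table.

Counts are treated as compositions: zeros are replaced by a
count-zero-multiplicative estimate, samples are centered-log-ratio (CLR)
transformed, and all downstream geometry (Aitchison distance, Ward
clustering with silhouette validation, ordination, perMANOVA) lives in CLR
space. Differential abundance follows the Dirichlet Monte-Carlo scheme:
posterior compositions are drawn per sample, Welch and Wilcoxon tests are
run per instance, p-values are averaged across instances and BH-adjusted,
and a robust standardized effect size is computed. Co-occurrence structure
uses the proportionality coefficient rho with greedy modularity modules.

All stochastic operations take an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .opu_slp import AbundanceTable


def from_table(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """SLP x sample counts -> samples x SLP orientation used here."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    return counts.T


# ---------------------------------------------------------------------------
# zero replacement and CLR geometry


def replace_zeros(counts: pd.DataFrame, delta_factor: float = 0.65) -> pd.DataFrame:
    """Count-zero-multiplicative replacement on the proportion scale.

    Zeros in sample *s* become ``delta_factor / total_s``; non-zero
    proportions are multiplicatively shrunk so each row still sums to 1.
    Rows are samples.
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if (X.sum(axis=1) == 0).any():
        bad = counts.index[X.sum(axis=1) == 0]
        raise ValueError(f"all-zero sample row(s): {list(bad)}")
    if (X.sum(axis=0) == 0).any():
        bad = counts.columns[X.sum(axis=0) == 0]
        raise ValueError(f"all-zero SLP column(s): {list(bad)}")
    totals = X.sum(axis=1, keepdims=True)
    P = X / totals
    delta = delta_factor / totals
    nz = (X == 0).sum(axis=1, keepdims=True)
    out = np.where(X == 0, delta, P * (1.0 - nz * delta))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def clr(props: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform, row-wise: ln(x) - mean(ln(x))."""
    X = props.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("CLR requires strictly positive entries")
    L = np.log(X)
    return pd.DataFrame(L - L.mean(axis=1, keepdims=True),
                        index=props.index, columns=props.columns)


def aitchison_distance(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CLR rows (the Aitchison distance)."""
    D = squareform(pdist(clr_matrix.to_numpy(), metric="euclidean"))
    return pd.DataFrame(D, index=clr_matrix.index, columns=clr_matrix.index)


# ---------------------------------------------------------------------------
# sample typing


@dataclass
class TypingResult:
    linkage: np.ndarray
    labels: pd.Series  # 1..k per sample
    mean_silhouette: float
    silhouettes: pd.Series


def ward_cluster(dist: pd.DataFrame, k: int = 2) -> TypingResult:
    """Ward clustering of a distance matrix (the ward.D2 convention:
    squared distances inside the Lance-Williams update, heights reported
    back on the distance scale), cut at ``k`` clusters, with silhouettes
    computed from the same distance matrix."""
    n = dist.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    Z = sch.linkage(squareform(dist.to_numpy(), checks=False), method="ward")
    labels = pd.Series(sch.fcluster(Z, t=k, criterion="maxclust"), index=dist.index)
    if k == n:
        sil = pd.Series(0.0, index=dist.index)  # degenerate: defined as 0
    else:
        sil = pd.Series(
            silhouette_samples(dist.to_numpy(), labels.to_numpy(), metric="precomputed"),
            index=dist.index,
        )
    return TypingResult(Z, labels, float(sil.mean()), sil)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coords: pd.DataFrame
    proportion_explained: pd.Series
    method: str


def ordinate(
    dist: pd.DataFrame | None = None,
    clr_matrix: pd.DataFrame | None = None,
    n_axes: int = 2,
) -> OrdinationResult:
    """PCoA of a distance matrix, or PCA of a CLR matrix.

    PCoA is classical metric scaling (eigendecomposition of the
    double-centered Gram matrix); on Aitchison distances its coordinates
    match PCA scores of the CLR matrix up to sign. A warning is raised when
    negative eigenvalue mass exceeds 5% (non-Euclidean input).
    """
    if (dist is None) == (clr_matrix is None):
        raise ValueError("provide exactly one of dist or clr_matrix")
    if dist is not None:
        D2 = np.asarray(dist, dtype=float) ** 2
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        neg = -vals[vals < 0].sum()
        if vals.max() > 0 and neg / np.abs(vals).sum() > 0.05:
            warnings.warn(f"negative eigenvalue mass {neg:.3g} exceeds 5% of total")
        keep = min(n_axes, int((vals > 1e-12).sum()))
        coords = vecs[:, :keep] * np.sqrt(np.maximum(vals[:keep], 0.0))
        total = vals[vals > 0].sum()
        expl = vals[:keep] / total if total > 0 else np.zeros(keep)
        idx = dist.index
        method = "PCoA"
    else:
        X = clr_matrix.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = min(n_axes, S.size)
        coords = U[:, :keep] * S[:keep]
        var = S**2
        expl = var[:keep] / var.sum() if var.sum() > 0 else np.zeros(keep)
        idx = clr_matrix.index
        method = "PCA"
    cols = [f"axis{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coords=pd.DataFrame(coords, index=idx, columns=cols),
        proportion_explained=pd.Series(expl, index=cols),
        method=method,
    )


# ---------------------------------------------------------------------------
# perMANOVA


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def permanova(
    dist: pd.DataFrame, factor: pd.Series, n_perm: int = 1000, seed: int = 0
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F follows the between/within sums-of-squared-distances
    formulation; the permutation p-value uses the +1 correction
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    f = factor.loc[dist.index]
    levels, codes = np.unique(f.to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("factor must have at least two levels")
    D2 = np.asarray(dist, dtype=float) ** 2
    N = D2.shape[0]
    a = len(levels)
    ss_total = D2.sum() / (2.0 * N)

    def ss_within(code_rows: np.ndarray) -> np.ndarray:
        # code_rows: (P, N) integer labels; returns SS_W per permutation
        out = np.zeros(code_rows.shape[0])
        for g in range(a):
            U = (code_rows == g).astype(float)
            n_g = U.sum(axis=1)
            out += np.einsum("pi,ij,pj->p", U, D2, U) / (2.0 * n_g)
        return out

    ssw_obs = ss_within(codes[None, :])[0]
    ssa_obs = ss_total - ssw_obs
    f_obs = (ssa_obs / (a - 1)) / (ssw_obs / (N - a))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])
    ssw_perm = ss_within(perms)
    ssa_perm = ss_total - ssw_perm
    f_perm = (ssa_perm / (a - 1)) / (ssw_perm / (N - a))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        r2=float(ssa_obs / ss_total), pseudo_f=float(f_obs),
        p_value=float(p), n_permutations=n_perm,
    )


def permanova_table(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One perMANOVA per factor; p-values BH-adjusted across factors."""
    rows = {}
    for i, fac in enumerate(factors):
        res = permanova(dist, metadata[fac], n_perm=n_perm, seed=seed + i)
        rows[fac] = {"r2": res.r2, "pseudo_f": res.pseudo_f, "p": res.p_value}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Dirichlet Monte-Carlo differential abundance


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per-SLP statistics
    group_levels: tuple[str, str]
    n_mc: int

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def dirichlet_mc_da(
    counts: pd.DataFrame,
    groups: pd.Series,
    n_mc: int = 256,
    seed: int = 0,
    fdr: float = 0.05,
    effect_cut: float = 1.0,
) -> DifferentialResult:
    """ALDEx2-style differential abundance between two groups.

    Per sample, ``n_mc`` posterior compositions are drawn from
    Dirichlet(counts + 0.5) and CLR-transformed. Per SLP and instance,
    Welch's t and the Wilcoxon rank-sum test compare the groups; p-values
    are averaged over instances and then BH-adjusted. The effect size is
    the median over instances of (between-group median CLR difference) /
    (larger within-group IQR); the reported difference is level2 - level1
    in sorted label order. An SLP is flagged when both adjusted p-values
    fall below ``fdr`` or |effect| >= ``effect_cut``.
    """
    g = groups.loc[counts.index]
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    ia = np.flatnonzero((g == levels[0]).to_numpy())
    ib = np.flatnonzero((g == levels[1]).to_numpy())
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least two samples")
    X = counts.to_numpy(dtype=float) + 0.5
    rng = np.random.default_rng(seed)
    # Dirichlet via normalized gammas: (n_mc, n_samples, n_slps)
    G = rng.standard_gamma(np.broadcast_to(X, (n_mc,) + X.shape))
    G /= G.sum(axis=2, keepdims=True)
    C = np.log(G)
    C -= C.mean(axis=2, keepdims=True)
    A, B = C[:, ia, :], C[:, ib, :]

    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    nA, nB = len(ia), len(ib)
    se2 = vA / nA + vB / nB
    tstat = (mB - mA) / np.sqrt(np.maximum(se2, 1e-300))
    dof = se2**2 / np.maximum(
        (vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1), 1e-300
    )
    tp = 2.0 * sps.t.sf(np.abs(tstat), dof)
    wres = sps.mannwhitneyu(A, B, axis=1, method="asymptotic")
    wp = wres.pvalue

    medA, medB = np.median(A, axis=1), np.median(B, axis=1)
    iqrA = np.percentile(A, 75, axis=1) - np.percentile(A, 25, axis=1)
    iqrB = np.percentile(B, 75, axis=1) - np.percentile(B, 25, axis=1)
    disp = np.maximum(np.maximum(iqrA, iqrB), 1e-9)
    effect = np.median((medB - medA) / disp, axis=0)

    tp_bar, wp_bar = tp.mean(axis=0), wp.mean(axis=0)
    tq = multipletests(tp_bar, method="fdr_bh")[1]
    wq = multipletests(wp_bar, method="fdr_bh")[1]
    tab = pd.DataFrame(
        {
            f"clr_{levels[0]}": mA.mean(axis=0),
            f"clr_{levels[1]}": mB.mean(axis=0),
            "t_stat": tstat.mean(axis=0),
            "t_p": tp_bar,
            "t_q": tq,
            "w_stat": wres.statistic.mean(axis=0),
            "w_p": wp_bar,
            "w_q": wq,
            "effect": effect,
        },
        index=counts.columns,
    )
    if not ((tab["t_q"] >= tab["t_p"] - 1e-12).all() and (tab["w_q"] >= tab["w_p"] - 1e-12).all()):
        raise AssertionError("BH adjustment must not decrease p-values")
    tab["significant"] = ((tab["t_q"] < fdr) & (tab["w_q"] < fdr)) | (
        tab["effect"].abs() >= effect_cut
    )
    return DifferentialResult(table=tab, group_levels=(levels[0], levels[1]), n_mc=n_mc)


# ---------------------------------------------------------------------------
# proportionality network


def proportionality_rho(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """rho(x, y) = 1 - var(x - y) / (var x + var y) over samples.

    SLPs with zero variance across samples yield NaN rows/columns
    (proportionality undefined); the diagonal is 1.
    """
    if clr_matrix.shape[0] < 3:
        raise ValueError("need at least three samples")
    X = clr_matrix.to_numpy(dtype=float)
    V = X.var(axis=0, ddof=1)
    Cov = np.cov(X.T, ddof=1)
    # var(x - y) = var x + var y - 2 cov(x, y)
    denom = V[:, None] + V[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, 2.0 * Cov / denom, np.nan)
    zero = V <= 0
    rho[zero, :] = np.nan
    rho[:, zero] = np.nan
    np.fill_diagonal(rho, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(rho, index=clr_matrix.columns, columns=clr_matrix.columns)


@dataclass
class ProportionalityNetwork:
    graph: nx.Graph
    modules: list[frozenset]
    modularity_q: float
    cutoff: float


def build_network(
    rho: pd.DataFrame, abundance: pd.Series, cutoff: float = 0.3
) -> ProportionalityNetwork:
    """Edges where rho > cutoff or rho < -cutoff; modules by greedy
    modularity maximization on absolute edge weights."""
    G = nx.Graph()
    for slp in rho.index:
        G.add_node(slp, abundance=float(abundance.get(slp, 0.0)))
    vals = rho.to_numpy()
    ids = list(rho.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        r = vals[i, j]
        if np.isfinite(r) and abs(r) > cutoff:
            G.add_edge(ids[i], ids[j], weight=float(r), abs_weight=abs(float(r)))
    connected = [n for n in G if G.degree(n) > 0]
    sub = G.subgraph(connected)
    if sub.number_of_edges() == 0:
        return ProportionalityNetwork(G, [], float("nan"), cutoff)
    comms = list(
        nx.algorithms.community.greedy_modularity_communities(sub, weight="abs_weight")
    )
    q = nx.algorithms.community.modularity(sub, comms, weight="abs_weight")
    return ProportionalityNetwork(G, [frozenset(c) for c in comms], float(q), cutoff)
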