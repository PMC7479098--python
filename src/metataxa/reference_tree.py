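"""Reference phylogeny construction and query placement.

Stages: progressive profile alignment of the reference type strains, query
alignment against the fixed reference profile, a 30% conservational column
filter, Jukes-Cantor distances on masked columns, canonical neighbor
joining rooted at a designated outgroup, and least-squares insertion of
query (OTU representative) leaves into the fixed reference topology.

The alignment engine is a profile-profile Needleman-Wunsch with affine gap
costs matching the pipeline's pairwise identity scoring (match +1,
mismatch -1, gap open -2, gap extend -1). Queries never perturb the
reference topology: each query is aligned to the finished reference
profile, and placement subdivides a single reference edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from . import _seq
from .reads_to_otus import pairwise_identity

GAP = ord("-")

_MATCH, _MISMATCH, _OPEN, _EXTEND = 1.0, -1.0, -2.0, -1.0


class SaturationError(ValueError):
    """A pairwise mismatch fraction at or beyond the Jukes-Cantor pole."""


@dataclass
class AlignedMatrix:
    """A multiple alignment with a boolean column mask."""

    ids: list[str]
    data: np.ndarray  # (n, L) uint8; gap = ord('-')
    mask: np.ndarray  # (L,) bool; True = column participates in distances
    n_references: int  # rows [0, n_references) are reference sequences

    def __post_init__(self):
        if self.data.ndim != 2 or len(self.ids) != self.data.shape[0]:
            raise ValueError("ids/data shape mismatch")
        if self.mask.shape != (self.data.shape[1],):
            raise ValueError("mask length must equal column count")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.data[self.ids.index(name)]


# ---------------------------------------------------------------------------
# affine-gap profile alignment


def _profile_scores(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Expected column-vs-column substitution score between two profiles."""
    nA, nB = A.shape[0], B.shape[0]
    CA = np.stack([(A == b).sum(axis=0) for b in _seq.BASES], axis=1).astype(np.float32)
    CB = np.stack([(B == b).sum(axis=0) for b in _seq.BASES], axis=1).astype(np.float32)
    ngA, ngB = CA.sum(axis=1), CB.sum(axis=1)
    same = CA @ CB.T
    # match +1, mismatch -1, residue-vs-gap 0 => 2*same - nonGapPairs
    return (2.0 * same - ngA[:, None] * ngB[None, :]) / float(nA * nB)


def _affine_dp(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns the three state matrices (M, X, Y) where X consumes a row
    (gap in the column sequence) and Y consumes a column. The horizontal
    recurrence is vectorized with a running-maximum transform.
    """
    LA, LB = S.shape
    NEG = np.float32(-1e30)
    M = np.full((LA + 1, LB + 1), NEG, dtype=np.float32)
    X = np.full((LA + 1, LB + 1), NEG, dtype=np.float32)
    Y = np.full((LA + 1, LB + 1), NEG, dtype=np.float32)
    M[0, 0] = 0.0
    X[1:, 0] = _OPEN + _EXTEND * np.arange(LA, dtype=np.float32)
    Y[0, 1:] = _OPEN + _EXTEND * np.arange(LB, dtype=np.float32)
    j = np.arange(LB + 1, dtype=np.float32)
    for i in range(1, LA + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = np.maximum(np.maximum(prevM[:-1], prevX[:-1]), prevY[:-1]) + S[i - 1]
        X[i] = np.maximum(np.maximum(prevM, prevY) + _OPEN, prevX + _EXTEND)
        # Y[i, j] = max_{k<j} max(M,X)[i, k] + OPEN + (j-k-1)*EXTEND
        base = np.maximum(M[i], X[i]) - _EXTEND * j
        run = np.maximum.accumulate(base[:-1])
        Y[i, 1:] = run + _OPEN - _EXTEND + _EXTEND * j[1:]
    return M, X, Y


def _traceback(S, M, X, Y) -> list[str]:
    """Recover the operation string ('M' both, 'X' row only, 'Y' col only)."""
    LA, LB = S.shape
    tol = 1e-4
    i, j = LA, LB
    scores = {"M": M[i, j], "X": X[i, j], "Y": Y[i, j]}
    state = max(scores, key=lambda s: scores[s])
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            ops.append("M")
            for cand in ("M", "X", "Y"):
                v = {"M": M, "X": X, "Y": Y}[cand][i, j]
                if abs(v - prev) <= tol:
                    state = cand
                    break
        elif state == "X":
            val = X[i, j]
            ops.append("X")
            if i >= 1 and abs(X[i - 1, j] + _EXTEND - val) <= tol:
                i, state = i - 1, "X"
            elif abs(M[i - 1, j] + _OPEN - val) <= tol:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "Y"
        else:
            val = Y[i, j]
            ops.append("Y")
            nxt = "Y"
            if abs(M[i, j - 1] + _OPEN - val) <= tol:
                nxt = "M"
            elif abs(X[i, j - 1] + _OPEN - val) <= tol:
                nxt = "X"
            j, state = j - 1, nxt
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    return ops[::-1]


def _merge_profiles(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = _profile_scores(A, B)
    ops = _traceback(S, *_affine_dp(S))
    L = len(ops)
    outA = np.full((A.shape[0], L), GAP, dtype=np.uint8)
    outB = np.full((B.shape[0], L), GAP, dtype=np.uint8)
    ia = ib = 0
    for k, op in enumerate(ops):
        if op in ("M", "X"):
            outA[:, k] = A[:, ia]
            ia += 1
        if op in ("M", "Y"):
            outB[:, k] = B[:, ib]
            ib += 1
    return outA, outB


def _align_query_to_profile(profile: np.ndarray, seq: str) -> tuple[np.ndarray, int]:
    """Align one query to a fixed profile; returns (row in profile columns,
    number of dropped query insertions)."""
    q = _seq.encode(seq).reshape(1, -1)
    S = _profile_scores(profile, q)
    ops = _traceback(S, *_affine_dp(S))
    row = np.full(profile.shape[1], GAP, dtype=np.uint8)
    ip = iq = dropped = 0
    for op in ops:
        if op == "M":
            row[ip] = q[0, iq]
            ip += 1
            iq += 1
        elif op == "X":
            ip += 1
        else:  # query insertion relative to the reference profile
            iq += 1
            dropped += 1
    return row, dropped


def align_profiles(
    references: dict[str, str],
    queries: dict[str, str] | None = None,
    assume_collinear: bool | str = "auto",
) -> AlignedMatrix:
    """Progressively align references, then add queries to the fixed profile.

    References are merged following a UPGMA guide tree built from pairwise
    identities. Each query is then aligned to the finished reference
    profile without altering reference columns; query residues that would
    require new (all-reference-gap) columns are dropped and counted — such
    columns could never pass the gappy-column filter downstream.

    When every reference has the same length (``assume_collinear='auto'``)
    the reference alignment is the trivial gapless stack, matching the
    substitution-only synthetic generator.
    """
    queries = queries or {}
    if len(references) < 2:
        raise ValueError("need at least two references")
    for name, s in list(references.items()) + list(queries.items()):
        if not _seq.is_acgt(s):
            raise ValueError(f"{name}: sequences must be non-empty A/C/G/T")
    ref_ids = list(references)
    lengths = {len(s) for s in references.values()}
    if assume_collinear == "auto":
        assume_collinear = len(lengths) == 1
    if assume_collinear:
        if len(lengths) != 1:
            raise ValueError("collinear mode requires equal-length references")
        profile = _seq.encode_block([references[r] for r in ref_ids])
        order = ref_ids
    else:
        enc = {r: _seq.encode(references[r]) for r in ref_ids}
        n = len(ref_ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = enc[ref_ids[i]], enc[ref_ids[j]]
                if a.size == b.size:
                    ident = _seq.hamming_identity(a, b)
                else:
                    ident = pairwise_identity(references[ref_ids[i]], references[ref_ids[j]])
                D[i, j] = D[j, i] = 1.0 - ident
        Z = linkage(squareform(D, checks=False), method="average")
        profiles: dict[int, tuple[list[str], np.ndarray]] = {
            i: ([ref_ids[i]], enc[ref_ids[i]].reshape(1, -1)) for i in range(n)
        }
        for k, (a, b, _, _) in enumerate(Z):
            idsA, profA = profiles.pop(int(a))
            idsB, profB = profiles.pop(int(b))
            mA, mB = _merge_profiles(profA, profB)
            profiles[n + k] = (idsA + idsB, np.vstack([mA, mB]))
        order, profile = profiles.popitem()[1]
        # restore the caller's reference order
        perm = [order.index(r) for r in ref_ids]
        profile = profile[perm]
        order = ref_ids
    rows = [profile]
    for qname, qseq in queries.items():
        if assume_collinear and len(qseq) == profile.shape[1]:
            row = _seq.encode(qseq)  # collinear data: gapless is the optimum
        else:
            row, _ = _align_query_to_profile(profile, qseq)
        rows.append(row.reshape(1, -1))
    data = np.vstack(rows)
    ids = order + list(queries)
    mask = np.ones(data.shape[1], dtype=bool)
    return AlignedMatrix(ids=ids, data=data, mask=mask, n_references=len(ref_ids))


# ---------------------------------------------------------------------------
# conservation filter


def conservation_mask(
    aln: AlignedMatrix,
    min_conservation: float = 0.30,
    min_nongap_fraction: float = 0.5,
) -> AlignedMatrix:
    """Keep columns whose modal residue frequency (among non-gap entries)
    reaches ``min_conservation`` and whose non-gap fraction reaches
    ``min_nongap_fraction``. Data are unchanged; only the mask is updated.
    """
    if aln.data.size == 0:
        raise ValueError("empty alignment")
    n = aln.data.shape[0]
    counts = np.stack([(aln.data == b).sum(axis=0) for b in _seq.BASES])
    nongap = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        modal = np.where(nongap > 0, counts.max(axis=0) / np.maximum(nongap, 1), 0.0)
    mask = (modal >= min_conservation) & (nongap / n >= min_nongap_fraction)
    if not mask.any():
        raise ValueError("conservation filter masked all columns")
    return AlignedMatrix(ids=list(aln.ids), data=aln.data, mask=mask,
                         n_references=aln.n_references)


# ---------------------------------------------------------------------------
# distances


def jc_distance(p_mismatch):
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3)."""
    p = np.asarray(p_mismatch, dtype=float)
    if np.any(p < 0) or np.any(p >= 0.75):
        raise SaturationError(f"mismatch fraction outside [0, 0.75): {p}")
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return float(d) if np.isscalar(p_mismatch) else d


def distance_matrix(aln: AlignedMatrix) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances over masked, mutually non-gap columns."""
    data = aln.data[:, aln.mask]
    nongap = data != GAP
    n = data.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap
        shared = both.sum(axis=1)
        mism = ((data[i] != data) & both).sum(axis=1)
        if np.any(shared[np.arange(n) != i] == 0):
            j = int(np.nonzero((shared == 0) & (np.arange(n) != i))[0][0])
            raise ValueError(f"no shared columns between {aln.ids[i]} and {aln.ids[j]}")
        p = mism / np.maximum(shared, 1)
        bad = p >= 0.75
        if bad.any():
            j = int(np.nonzero(bad)[0][0])
            raise SaturationError(
                f"saturated pair ({aln.ids[i]}, {aln.ids[j]}): p = {p[j]:.3f}"
            )
        D[i] = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=aln.ids, columns=aln.ids)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: pd.DataFrame, outgroup_id: str, max_nj_taxa: int = 1000) -> TreeNode:
    """Canonical neighbor joining (Saitou-Nei), rooted on the outgroup edge.

    Negative branch lengths are clamped to zero. Ties in the Q criterion
    are broken by the smallest (row, column) index pair, making the result
    deterministic for a given input ordering.
    """
    ids = list(dist.index)
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or len(ids) < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if outgroup_id not in ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in distance matrix")
    if len(ids) > max_nj_taxa:
        warnings.warn(
            f"{len(ids)} taxa exceeds max_nj_taxa={max_nj_taxa}; "
            "neighbor joining cost grows as O(n^3)"
        )

    # adjacency over node keys; leaves are their label strings
    adj: dict[object, list[tuple[object, float]]] = {t: [] for t in ids}
    active: list[object] = list(ids)
    Dm = D.copy()
    next_internal = 0

    def connect(a, b, w):
        w = max(0.0, float(w))
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    while len(active) > 2:
        m = len(active)
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * Dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = Dm[i, j] - li
        node = f"__nj{next_internal}"
        next_internal += 1
        connect(node, active[i], li)
        connect(node, active[j], lj)
        dnew = 0.5 * (Dm[i] + Dm[j] - Dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        Dm = np.vstack([
            np.hstack([[0.0], dnew[keep]]),
            np.hstack([dnew[keep][:, None], Dm[np.ix_(keep, keep)]]),
        ])
        active = [node] + [active[k] for k in keep]
    connect(active[0], active[1], Dm[0, 1])

    return _root_at_leaf_edge(adj, outgroup_id)


def _root_at_leaf_edge(adj, leaf) -> TreeNode:
    """Build a rooted TreeNode splitting the given leaf's pendant edge."""
    (nbr, w), = adj[leaf]
    root = TreeNode()
    out = TreeNode(name=str(leaf), length=max(0.0, w / 2.0))
    root.append(out)

    def build(node, parent) -> TreeNode:
        children = [(n, d) for n, d in adj[node] if n != parent]
        if not children:
            return TreeNode(name=str(node))
        t = TreeNode(name=None)
        for n, d in children:
            c = build(n, node)
            c.length = max(0.0, d)
            t.append(c)
        return t

    rest = build(nbr, leaf)
    rest.length = max(0.0, w / 2.0)
    root.append(rest)
    return root


# ---------------------------------------------------------------------------
# query insertion


def _node_leaf_distances(tree: TreeNode) -> dict[int, dict[str, float]]:
    """Distances from every node (by id) to every leaf, via two passes."""
    down: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            down[id(node)] = {node.name: 0.0}
        else:
            d: dict[str, float] = {}
            for c in node.children:
                for leaf, dist in down[id(c)].items():
                    d[leaf] = dist + (c.length or 0.0)
            down[id(node)] = d
    full: dict[int, dict[str, float]] = {}
    for node in tree.preorder():
        if node.is_root():
            full[id(node)] = dict(down[id(node)])
        else:
            p = node.parent
            d = dict(down[id(node)])
            w = node.length or 0.0
            for leaf, dist in full[id(p)].items():
                if leaf not in down[id(node)]:
                    d[leaf] = dist + w
            full[id(node)] = d
    return full


def parsimony_insert(
    tree: TreeNode,
    query_name: str,
    dist_to_leaves: dict[str, float],
) -> TreeNode:
    """Attach a query leaf on the edge minimizing least-squares added distance.

    Every tree edge (parent, child) is scanned; the attachment point along
    the edge and the pendant length are solved by constrained least squares
    against the query's distances to all current leaves. The reference
    topology is otherwise unchanged. The tree is modified in place and
    returned.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in dist_to_leaves]
    if missing:
        raise ValueError(f"query {query_name!r} lacks distances to leaves {missing[:5]}")
    q = np.array([dist_to_leaves[l] for l in leaves])
    full = _node_leaf_distances(tree)
    best = None  # (sse, preorder_idx, node, x, t)
    for idx, node in enumerate(tree.preorder()):
        if node.is_root():
            continue
        l_edge = node.length or 0.0
        dv = np.array([full[id(node)][l] for l in leaves])
        below = set(node.subset()) if not node.is_tip() else {node.name}
        s = np.array([1.0 if l in below else -1.0 for l in leaves])
        # model: q ~ t + dv + s*x  with t >= 0, 0 <= x <= l_edge
        resid = q - dv
        n = len(leaves)
        sum_s, sum_s2 = s.sum(), n  # s in {-1, +1}
        det = n * sum_s2 - sum_s**2
        if det > 1e-12:
            t_hat = (sum_s2 * resid.sum() - sum_s * (s * resid).sum()) / det
            x_hat = (n * (s * resid).sum() - sum_s * resid.sum()) / det
        else:
            t_hat, x_hat = resid.mean(), 0.0
        x_hat = float(np.clip(x_hat, 0.0, l_edge))
        t_hat = max(0.0, float(resid.mean() - x_hat * s.mean()))
        sse = float(((resid - t_hat - s * x_hat) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, idx, node, x_hat, t_hat)
    _, _, node, x, t = best
    parent = node.parent
    l_edge = node.length or 0.0
    attach = TreeNode(name=None, length=max(0.0, l_edge - x))
    attach._orig_child_length = node.length  # lossless undo for remove_query
    pos = parent.children.index(node)  # keep sibling order stable
    parent.remove(node)
    node.length = x
    attach.append(node)
    attach.append(TreeNode(name=query_name, length=t))
    parent.children.insert(pos, attach)
    attach.parent = parent
    tree.clear_caches()
    return tree


def remove_query(tree: TreeNode, query_name: str) -> TreeNode:
    """Remove a previously inserted query leaf, restoring the original tree."""
    leaf = tree.find(query_name)
    attach = leaf.parent
    attach.remove(leaf)
    if len(attach.children) == 1 and attach.parent is not None:
        child = attach.children[0]
        orig = getattr(attach, "_orig_child_length", None)
        child.length = orig if orig is not None else (
            (child.length or 0.0) + (attach.length or 0.0)
        )
        parent = attach.parent
        pos = parent.children.index(attach)
        parent.remove(attach)
        parent.children.insert(pos, child)
        child.parent = parent
    tree.clear_caches()
    return tree


def place_queries(
    tree: TreeNode,
    dist: pd.DataFrame,
    order: list[str],
) -> TreeNode:
    """Insert queries one at a time (caller supplies the size-descending
    order); each insertion sees previously inserted queries as leaves."""
    for qname in order:
        leaves = [t.name for t in tree.tips()]
        parsimony_insert(tree, qname, dist.loc[qname, leaves].to_dict())
    return tree


def select_support(
    identities: pd.Series, is_type_strain: dict[str, bool], n_support: int = 3
) -> list[str]:
    """Pick the highest-identity non-type references as supporting sequences."""
    ranked = identities.sort_values(ascending=False)
    return [r for r in ranked.index if not is_type_strain.get(r, True)][:n_support]
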