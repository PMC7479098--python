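"""Independent reference implementations used only to validate the package.

Everything here is written directly from definitions (DP recurrences,
exhaustive enumeration, replayed greedy insertion) and stays independent of
the code paths it checks.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, OPEN, EXTEND = 1.0, -1.0, -2.0, -1.0


def affine_dp_score_identity(a: str, b: str) -> tuple[float, float]:
    """Plain O(nm) affine-gap global DP; returns (optimal score, identity of
    one optimal traceback, terminal gap columns excluded)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = OPEN + EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = OPEN + EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + OPEN, X[i - 1, j] + EXTEND, Y[i - 1, j] + OPEN)
            Y[i, j] = max(M[i, j - 1] + OPEN, Y[i, j - 1] + EXTEND, X[i, j - 1] + OPEN)
    score = max(M[n, m], X[n, m], Y[n, m])
    # traceback (prefer M, then X, then Y on ties)
    i, j = n, m
    state = ["M", "X", "Y"][int(np.argmax([M[n, m], X[n, m], Y[n, m]]))]
    cols = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            prev = M[i, j] - s
            cols.append(("M", a[i - 1] == b[j - 1]))
            i, j = i - 1, j - 1
            for cand, Mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(Mat[i, j] - prev) <= tol:
                    state = cand
                    break
        elif state == "X":
            val = X[i, j]
            cols.append(("X", False))
            if i > 1 and abs(X[i - 1, j] + EXTEND - val) <= tol:
                state = "X"
            elif abs(M[i - 1, j] + OPEN - val) <= tol:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            val = Y[i, j]
            cols.append(("Y", False))
            if j > 1 and abs(Y[i, j - 1] + EXTEND - val) <= tol:
                state = "Y"
            elif abs(M[i, j - 1] + OPEN - val) <= tol:
                state = "M"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    cols.reverse()
    # strip terminal gap columns
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo][0] != "M":
        lo += 1
    while hi > lo and cols[hi - 1][0] != "M":
        hi -= 1
    core = cols[lo:hi]
    matches = sum(1 for op, eq in core if op == "M" and eq)
    return score, matches / len(core) if core else 0.0


def replay_greedy(seqs_with_mult: list[tuple[str, int]], threshold: float, identity_fn):
    """Greedy centroid clustering replayed naively from the definition."""
    order = sorted(seqs_with_mult, key=lambda t: (-t[1], t[0]))
    centroids: list[str] = []
    assign: dict[str, int] = {}
    for s, _ in order:
        for ci, c in enumerate(centroids):
            if identity_fn(s, c) >= threshold:
                assign[s] = ci
                break
        else:
            assign[s] = len(centroids)
            centroids.append(s)
    return assign


# ---------------------------------------------------------------------------
# random trees and clade enumeration


def random_tree(rng: np.random.Generator, n_leaves: int, n_refs: int):
    """Random rooted binary tree as nested tuples with leaf names.

    Returns (tree, ref_names, query_names); leaves R* are references and
    Q* queries. Structure: node = (left, right) | leaf name.
    """
    names = [f"R{i}" for i in range(n_refs)] + [f"Q{i}" for i in range(n_leaves - n_refs)]
    perm = [names[i] for i in rng.permutation(n_leaves)]
    nodes = list(perm)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    refs = [n for n in names if n.startswith("R")]
    queries = [n for n in names if n.startswith("Q")]
    return nodes[0], refs, queries


def tree_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return f"({tree_to_newick(node[0])},{tree_to_newick(node[1])})"


def enumerate_clades(node, out=None):
    """All (node-id-path, leafset) clades of a nested-tuple tree."""
    if out is None:
        out = []
    if isinstance(node, str):
        out.append(frozenset([node]))
        return frozenset([node]), out
    l, _ = enumerate_clades(node[0], out)
    r, _ = enumerate_clades(node[1], out)
    s = l | r
    out.append(s)
    return s, out


def brute_force_anchored_leafset(tree, query: str, refs: set[str]) -> frozenset:
    """Leaf set of the smallest clade containing the query and >= 1 reference,
    found by exhaustive enumeration of all clades."""
    _, clades = enumerate_clades(tree)
    candidates = [c for c in clades if query in c and c & refs]
    return min(candidates, key=len)


def brute_force_delineate(tree, queries: list[str], refs: set[str]):
    """Partition queries by the reference content of their minimal anchored
    clades (independent route: leafset enumeration, no tree traversal)."""
    groups: dict[frozenset, list[str]] = {}
    for q in queries:
        anchored = brute_force_anchored_leafset(tree, q, refs)
        groups.setdefault(frozenset(anchored & refs), []).append(q)
    return {frozenset(v): k for k, v in groups.items()}


# ---------------------------------------------------------------------------
# random additive trees


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with random branch lengths; returns
    (nested-tuple tree with (child, length) edges, leaf names)."""
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [(nm, float(rng.uniform(0.05, 1.0))) for nm in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), float(rng.uniform(0.05, 1.0))))
    return nodes[0][0], names


def additive_distances(tree, names: list[str]) -> np.ndarray:
    """Path-length matrix of a ((childA, lenA), (childB, lenB)) tree."""

    def leaf_depths(node):
        if isinstance(node, str):
            return {node: 0.0}
        out = {}
        for child, ln in node:
            for leaf, d in leaf_depths(child).items():
                out[leaf] = d + ln
        return out

    n = len(names)
    D = np.zeros((n, n))

    def recurse(node):
        if isinstance(node, str):
            return {node: 0.0}
        sides = []
        for child, ln in node:
            d = recurse(child)
            sides.append({leaf: dist + ln for leaf, dist in d.items()})
        for a, da in sides[0].items():
            for b, db in sides[1].items():
                i, j = names.index(a), names.index(b)
                D[i, j] = D[j, i] = da + db
        return {**sides[0], **sides[1]}

    recurse(tree)
    return D
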