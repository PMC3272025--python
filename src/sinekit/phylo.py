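"""Distance-based phylogeny of family members: p-distances, neighbor joining,
bootstrap support, Newick output.

The distance input is the p-distance (proportion of differing sites among
mutually ungapped columns). Tree construction is the Saitou–Nei neighbor
joining algorithm with deterministic tie-breaking (the lowest index pair is
joined when Q ties); it is exact on additive matrices. Bootstrap support for
each internal bipartition of the full-data tree is the percentage of
column-resampled replicates whose NJ tree contains that bipartition.
Trees are :class:`skbio.TreeNode` objects, so Newick round-trips through
scikit-bio's parser.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .consensus import MultipleAlignment
from .seqcore import SequenceError


def p_distance_matrix(
    msa: MultipleAlignment, missing_value: float | None = None
) -> DistanceMatrix:
    """Pairwise p-distances over mutually ungapped columns.

    A pair with zero comparable columns raises unless *missing_value* is
    given (used by bootstrap replicates, where resampling can drop every
    shared column of a sparse pair).
    """
    rows = msa.rows
    if len(rows) < 3:
        raise SequenceError("need at least 3 rows for a distance matrix")
    labels = [name for name, _ in rows]
    arrs = [np.frombuffer(g.encode(), dtype="S1") for _, g in rows]
    good = [np.isin(a, [b"A", b"C", b"G", b"T"]) for a in arrs]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = good[i] & good[j]
            m = int(both.sum())
            if m == 0:
                if missing_value is None:
                    raise SequenceError(
                        f"no comparable columns between {labels[i]} and {labels[j]}"
                    )
                d[i, j] = d[j, i] = missing_value
                continue
            diff = int((arrs[i][both] != arrs[j][both]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; unrooted tree with branch lengths.

    Ties in the Q criterion break to the lowest (i, j) index pair, so the
    output is deterministic. Negative branch lengths are clamped to zero
    with a warning, as is standard practice.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise SequenceError("need at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise SequenceError("distance matrix is not symmetric")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-12:
                warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[ai], nodes[aj]
        ci.length = clamp(li)
        cj.length = clamp(lj)
        parent.extend([ci, cj])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d[ai, :] = new_row
        d[:, ai] = new_row
        d[ai, ai] = 0.0
        nodes[ai] = parent
        active.remove(aj)
    # resolve the final three into an unrooted (trifurcating) root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = TreeNode()
    nodes[a].length = clamp(0.5 * (dab + dac - dbc))
    nodes[b].length = clamp(0.5 * (dab + dbc - dac))
    nodes[c].length = clamp(0.5 * (dac + dbc - dab))
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Internal-edge bipartitions of an unrooted tree, orientation-free."""
    tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            parts.add(frozenset({side, tips - side}))
    return parts


def bootstrap_support(
    msa: MultipleAlignment, n_reps: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree from the full alignment with per-internal-node bootstrap support.

    Columns are resampled with replacement; replicate r draws from a
    generator seeded deterministically by (seed, r), so supports are
    reproducible and independent of evaluation order. Support is attached to
    each internal node as ``node.support`` (percent) and mirrored into the
    node name for Newick output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(p_distance_matrix(msa))
    tips_all = frozenset(t.name for t in full.tips())
    counts: dict[frozenset[frozenset[str]], int] = {}
    width = msa.width
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, width, size=width)
        rows = [(name, "".join(g[c] for c in cols)) for name, g in msa.rows]
        rep_dm = p_distance_matrix(MultipleAlignment(rows), missing_value=0.75)
        rep_tree = neighbor_joining(rep_dm)
        for part in _bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips_all) - 1:
            part = frozenset({side, tips_all - side})
            node.support = 100.0 * counts.get(part, 0) / n_reps
        else:
            node.support = None
    return full


def write_newick(
    tree: TreeNode, include_support: bool = False, min_support: float = 50.0
) -> str:
    """Standard Newick with branch lengths.

    With *include_support*, internal nodes are labelled with their bootstrap
    percentage; values below *min_support* are omitted (the usual display
    convention for NJ figures).
    """
    t = tree.copy()
    for node in t.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if include_support and sup is not None and sup >= min_support:
            node.name = f"{sup:g}"
        else:
            node.name = None
    buf = io.StringIO()
    t.write(buf)
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def write_support_tsv(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_tips\tsupport_pct\n")
        for node in tree.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            if sup is None:
                continue
            tipset = ",".join(sorted(t.name for t in node.tips()))
            fh.write(f"{tipset}\t{sup:g}\n")
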