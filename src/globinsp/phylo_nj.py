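"""Distance-based protein phylogenetics: Poisson distances, NJ, bootstrap.

Pairwise distances are observed proportions of differing sites computed
with pairwise deletion (gap or unknown columns are excluded per pair, not
alignment-wide), corrected for superimposed substitutions with the Poisson
formula d = -ln(1 - p). Trees are built by Saitou–Nei neighbor joining,
which recovers additive distance matrices exactly; branch support comes
from bootstrap resampling of alignment columns, and several trees can be
summarised by majority-rule consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import PhyloTree, SequenceRecord, TreeNode

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class DistanceMatrix:
    """Symmetric non-negative distance matrix; NaN marks missing entries."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.values[finite], self.values.T[finite]
        ):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be non-negative")

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites over comparable columns (pairwise deletion).

    Columns with a gap or an X in either row are excluded. Returns NaN when
    no column is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    a = np.frombuffer(row_a.encode(), dtype="S1")
    b = np.frombuffer(row_b.encode(), dtype="S1")
    usable = ~np.isin(a, (b"-", b"X")) & ~np.isin(b, (b"-", b"X"))
    n = int(usable.sum())
    if n == 0:
        return float("nan")
    diff = int(((a != b) & usable).sum())
    return diff / n


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for 0 <= p < 1."""
    if np.isnan(p):
        return float("nan")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"saturated distance: p = {p} is not in [0, 1)")
    return float(-np.log1p(-p))


def distance_matrix_from_msa(msa: list[SequenceRecord],
                             correction: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion distances between MSA rows, optionally corrected."""
    if correction not in ("poisson", "none"):
        raise ValueError(f"unknown correction: {correction!r}")
    if len(msa) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(msa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(msa[i].sequence, msa[j].sequence)
            d = poisson_correct(p) if correction == "poisson" else p
            values[i, j] = values[j, i] = d
    return DistanceMatrix([r.id for r in msa], values)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion go to the lexicographically lowest index pair.
    Negative branch-length estimates are clamped to zero with the deficit
    logged. The result is unrooted (trifurcating root node).
    """
    missing = matrix.missing_pairs()
    if missing:
        raise ValueError(f"missing distance for pair {missing[0]}")
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [TreeNode(name) for name in matrix.ids]
    d = matrix.values.astype(float).copy()

    def clamp(value: float, context: str) -> float:
        if value < 0:
            logger.info("clamped negative branch length %.6g at %s", value, context)
            return 0.0
        return value

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li, f"join({child_i.name},{child_j.name})")
        child_j.length = clamp(lj, f"join({child_i.name},{child_j.name})")
        new_node = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([
            np.hstack([d[np.ix_(keep, keep)], new_row[keep][:, None]]),
            np.hstack([new_row[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [new_node]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0, "final join")
    b.length = clamp((dab + dbc - dac) / 2.0, "final join")
    c.length = clamp((dac + dbc - dab) / 2.0, "final join")
    return PhyloTree(TreeNode(children=[a, b, c]))


def _tree_from_msa(msa: list[SequenceRecord]) -> PhyloTree:
    return nj_tree(distance_matrix_from_msa(msa))


def bootstrap_support(msa: list[SequenceRecord], replicates: int = 1000,
                      seed: int = 1234) -> PhyloTree:
    """NJ tree with bootstrap percentages on its internal branches.

    Alignment columns are resampled with replacement per replicate and the
    whole p-distance / Poisson / NJ pipeline is rerun; supports are the
    percentage of valid replicates containing each bipartition of the
    full-data tree. Replicates with a saturated (p = 1) or empty pairwise
    comparison are dropped and counted in the log.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    full_dm = distance_matrix_from_msa(msa)
    if np.nanmax(full_dm.values) == 0.0:
        raise ValueError("no variation: all sequences are identical")
    full_tree = nj_tree(full_dm)
    target_splits = set(full_tree.bipartitions())

    rng = np.random.default_rng(seed)
    length = len(msa[0].sequence)
    rows = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in msa]
    counts = {split: 0 for split in target_splits}
    valid = 0
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, length, size=length)
        sample = [
            SequenceRecord(rec.id, row[idx].tobytes().decode())
            for rec, row in zip(msa, rows)
        ]
        try:
            rep_tree = _tree_from_msa(sample)
        except ValueError:
            dropped += 1
            continue
        valid += 1
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    if dropped:
        logger.warning("dropped %d of %d bootstrap replicates", dropped, replicates)
    if valid == 0:
        raise ValueError("all bootstrap replicates were degenerate")

    all_leaves = set(full_tree.leaf_names())
    ref = min(all_leaves)
    for node in full_tree.root.walk():
        if node is full_tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = frozenset(all_leaves - side)
        if side in counts:
            node.support = 100.0 * counts[side] / valid
    return full_tree


def majority_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Majority-rule consensus: bipartitions in more than half of the trees.

    Splits above 50% frequency are mutually compatible by construction.
    Supports carry the frequency percent; branch lengths are left at zero.
    """
    if not trees:
        raise ValueError("empty tree list")
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees have different leaf sets")
    leaves = sorted(leaf_sets.pop())

    counts: dict[frozenset, int] = {}
    for tree in trees:
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    majority = {
        split: 100.0 * c / len(trees)
        for split, c in counts.items()
        if c / len(trees) > 0.5
    }

    leaf_nodes = {name: TreeNode(name) for name in leaves}
    root = TreeNode(children=[leaf_nodes[name] for name in leaves])
    clusters: dict[int, frozenset] = {
        id(node): frozenset([name]) for name, node in leaf_nodes.items()
    }
    ref = leaves[0]
    clusters[id(root)] = frozenset(leaves)

    # insert splits smallest-last so parents exist before their children
    for split, support in sorted(majority.items(), key=lambda kv: -len(kv[0])):
        assert ref not in split
        # locate the smallest node whose cluster contains the split
        host = root
        descended = True
        while descended:
            descended = False
            for child in host.children:
                cl = clusters[id(child)]
                if split < cl:
                    host = child
                    descended = True
                    break
        grouped = [c for c in host.children if clusters[id(c)] <= split]
        union = frozenset().union(*(clusters[id(c)] for c in grouped)) \
            if grouped else frozenset()
        if union != split:
            # incompatible with an already inserted split; cannot occur for
            # strict-majority splits but guards rounding of ties
            continue
        new_node = TreeNode(support=support, children=grouped)
        clusters[id(new_node)] = split
        host.children = [c for c in host.children if c not in grouped]
        host.children.append(new_node)
    return PhyloTree(root)
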