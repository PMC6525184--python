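"""Neighbor-joining trees, bootstrap supports, cluster extraction, monophyly.

The agglomeration follows Saitou-Nei with the Studier-Keppler criterion
``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (``r_i`` the row sum over active
nodes).  The construction is deterministic: ties in Q are broken by the
lexicographically smallest (representative-label) pair, where an internal
node is represented by the smallest leaf label beneath it.  Negative branch
length estimates are clamped to zero for output (the pre-clamp estimate is
retained on each node and the clamp count logged).  The unrooted result is
represented rooted at the final three-way join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .abgd import Partition, relabel_groups
from .errors import DistanceError, TreeError
from .records import BarcodeAlignment, DistanceMatrix
from .tree import Node, Tree

logger = logging.getLogger(__name__)


def nj(dmat: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a fully defined distance matrix.

    Requires n >= 3.  On additive matrices the generating topology and branch
    lengths are recovered exactly (NJ is consistent there).
    """
    if dmat.has_undefined:
        pairs = sorted(tuple(sorted(p)) for p in dmat.undefined_pairs)
        raise DistanceError(
            f"distance matrix has undefined pairs {pairs[:5]}...; "
            "exclude or impute those records before building a tree"
        )
    n = dmat.n
    if n < 3:
        raise TreeError("neighbor-joining needs at least 3 taxa")
    d = dmat.values.copy()
    nodes = [Node(label=lab) for lab in dmat.labels]
    reps = list(dmat.labels)  # representative (min) leaf label per active node
    active = list(range(n))
    n_clamped = 0

    def _clamp(node: Node, length: float):
        nonlocal n_clamped
        node.raw_length = float(length)
        if length < 0:
            n_clamped += 1
            node.length = 0.0
        else:
            node.length = float(length)

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        # (r_i + r_j) keeps Q exactly symmetric in floating point
        q = (m - 2) * sub - (r[:, None] + r[None, :])
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((reps[idx[a]], reps[idx[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        ai, bi = best[1], best[2]
        i, j = idx[ai], idx[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node(children=[nodes[i], nodes[j]])
        _clamp(nodes[i], li)
        _clamp(nodes[j], lj)
        # new node reuses slot i
        new_d = 0.5 * (d[i, idx] + d[j, idx] - dij)
        d[i, idx] = new_d
        d[idx, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        _clamp(node, length)
    if n_clamped:
        logger.info("clamped %d negative branch lengths to 0", n_clamped)
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: BarcodeAlignment,
    model: str = "K2P",
    replicates: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree of the alignment with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``replicates`` times from
    one seeded generator (replicate r consumes the r-th block of draws, so the
    result is reproducible regardless of evaluation order).  Each internal
    edge of the tree built from the original alignment is annotated with the
    percentage of replicate trees containing the same bipartition, rounded to
    the nearest integer.  Replicates whose resampled matrix has an undefined
    pair are discarded; more than 10% discards is an error.
    """
    from .distances import distance_matrix

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base_dmat = distance_matrix(aln, model)
    tree = nj(base_dmat)
    edges = tree.bipartitions()
    counts = {bip: 0 for bip in edges}

    rng = np.random.default_rng(seed)
    n_cols = aln.length
    draws = rng.integers(0, n_cols, size=(replicates, n_cols))
    encoded = aln.encoded()
    labels = aln.ids
    n_discarded = 0
    for r in range(replicates):
        cols = draws[r]
        rep_dmat = _distance_from_encoded(encoded[:, cols], labels, model)
        if rep_dmat is None:
            n_discarded += 1
            logger.warning("bootstrap replicate %d discarded (undefined pair)", r)
            continue
        rep_bips = nj(rep_dmat).bipartition_set()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    if n_discarded > 0.1 * replicates:
        raise DistanceError(
            f"{n_discarded}/{replicates} bootstrap replicates had undefined "
            "distances; data too saturated for bootstrap under this model"
        )
    n_used = replicates - n_discarded
    for bip, node in edges.items():
        node.support = int(round(100.0 * counts[bip] / n_used))
    return tree


def _distance_from_encoded(encoded, labels, model):
    """Distance matrix from a pre-encoded (resampled) alignment; None if any
    pair is undefined."""
    from .distances import _pattern_arrays

    ts, tv, n = _pattern_arrays(encoded)
    if np.any(n[np.triu_indices(len(labels), k=1)] == 0):
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / n
        q = tv / n
        np.fill_diagonal(p, 0.0)
        np.fill_diagonal(q, 0.0)
        if model == "P_DIST":
            values = p + q
        else:
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            if np.any(w1 <= 0.0) or np.any(w2 <= 0.0):
                return None
            values = -0.5 * np.log(w1 * np.sqrt(w2))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(labels), values, model)


# ---------------------------------------------------------------------------
# Cluster extraction and monophyly
# ---------------------------------------------------------------------------

def extract_nj_clusters(
    tree: Tree,
    dmat: DistanceMatrix,
    support_min: int = 97,
    intra_max: float = 0.02,
) -> Partition:
    """Read OTU-like clusters off a bootstrapped NJ tree.

    Clusters are the maximal unrooted clades (either side of an internal
    edge) whose edge support is at least ``support_min`` and whose maximum
    within-clade pairwise distance is at most ``intra_max`` (proportion).
    Working with edge sides rather than rooted subtrees keeps the extraction
    invariant to where the final NJ join happened to place the root.
    Qualifying clades are accepted largest-first, skipping any that overlaps
    an accepted one; remaining leaves become singletons.
    """
    index = {lab: i for i, lab in enumerate(dmat.labels)}
    all_leaves = tree.leaf_label_set

    def _tight(side: frozenset) -> bool:
        idx = [index[lab] for lab in side]
        vals = dmat.values[np.ix_(idx, idx)]
        if np.any(np.isnan(vals)):
            return False
        return bool(np.all(vals <= intra_max))

    candidates = []
    # the whole leaf set is a clade with no stem edge, hence no bootstrap
    # evidence; it can qualify only when no support is demanded
    if support_min <= 0 and _tight(all_leaves):
        candidates.append(all_leaves)
    for node in tree.bipartitions().values():
        if node.support is None or node.support < support_min:
            continue
        side = node.leaf_labels()
        for clade in (side, all_leaves - side):
            if len(clade) >= 2 and _tight(clade):
                candidates.append(clade)
    candidates.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    assignment: dict[str, int] = {}
    next_group = 0
    for clade in candidates:
        if any(lab in assignment for lab in clade):
            continue
        for lab in clade:
            assignment[lab] = next_group
        next_group += 1
    for lab in sorted(all_leaves - set(assignment)):
        assignment[lab] = next_group
        next_group += 1
    return relabel_groups(
        Partition(
            method="NJ",
            prior_p=None,
            threshold_found=None,
            assignment=assignment,
            n_groups=len(set(assignment.values())),
        ),
        order=list(dmat.labels),
    )


@dataclass
class MonophylyRecord:
    taxon: str
    n_leaves: int
    monophyletic: bool


def monophyly_report(tree: Tree, taxonomy, rank: str) -> list[MonophylyRecord]:
    """Assess monophyly of every taxon at ``rank`` on the (unrooted) tree.

    A taxon with two or more leaves is monophyletic iff some edge of the
    unrooted tree bipartitions exactly its leaf set; single-leaf taxa are
    trivially monophyletic.
    """
    rank_col = {"species": "species", "genus": "genus", "family": "family"}.get(rank)
    if rank_col is None:
        raise ValueError(f"rank must be species/genus/family, not {rank!r}")
    labels = sorted(tree.leaf_label_set)
    groups: dict[str, set] = {}
    for lab in labels:
        groups.setdefault(taxonomy.loc[lab, rank_col], set()).add(lab)
    # every edge (trivial and internal) as a canonical bipartition side
    sides = set()
    for node in tree.preorder():
        if node is tree.root:
            continue
        sides.add(tree._canonical(frozenset(node.leaf_labels())))
    out = []
    for taxon in sorted(groups):
        leafset = frozenset(groups[taxon])
        if len(leafset) == 1 or len(leafset) == len(labels):
            mono = True
        else:
            mono = tree._canonical(leafset) in sides
        out.append(MonophylyRecord(taxon, len(leafset), mono))
    return out
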