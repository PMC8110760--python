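"""Desk-scale distance trees and clan assignment by clade membership.

CYP families group into *clans* — families that repeatedly form one clade in
metazoan phylogenies (clan 2, clan 3, clan 4, the mitochondrial clan, ...).
Production CYPome studies infer maximum-likelihood trees; here a
neighbor-joining tree on Kimura-corrected protein distances is the in-repo
stand-in (external ML trees in Newick are ingested as first-class input),
because the clan logic — walking from a query leaf to the smallest supported
clade containing clan-labeled references — is the procedure of interest, not
the tree engine.

Support conventions follow common practice: bootstraps below 50 are treated
as unreliable and skipped during the upward walk; trees without support
annotations are treated as fully supported, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import PhyloTree, ProteinRecord, TreeNode


@dataclass
class PhyloConfig:
    bootstrap_reps: int = 100
    support_threshold: float = 50.0
    max_distance_cap: float = 5.0
    trim_max_gap_fraction: float = 0.5

    def __post_init__(self):
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must be in [0, 100]")


@dataclass
class ClanAssignment:
    id: str
    clan: str  # e.g. "clan 2" or "unplaced"
    support: float = 0.0
    defining_clade_size: int = 0


# ---------------------------------------------------------------------------
# Alignment trimming and distances
# ---------------------------------------------------------------------------

def trim_columns(msa: list[ProteinRecord], config: PhyloConfig | None = None,
                 ) -> tuple[list[ProteinRecord], list[int]]:
    """Remove columns whose gap fraction exceeds the configured threshold.

    Returns (trimmed rows in input order, removed 0-based column indices).
    Poorly aligned gappy regions — typically the termini — carry uncertain
    homology and only add noise to distances.
    """
    if config is None:
        config = PhyloConfig()
    if not msa:
        return [], []
    L = len(msa[0].residues)
    if any(len(r.residues) != L for r in msa):
        raise ValueError("ragged alignment: rows differ in length")
    arr = np.array([list(r.residues) for r in msa])
    gap_frac = (arr == "-").mean(axis=0)
    removed = [int(i) for i in np.nonzero(gap_frac > config.trim_max_gap_fraction)[0]]
    keep = gap_frac <= config.trim_max_gap_fraction
    out = []
    for rec, row in zip(msa, arr):
        trimmed = "".join(row[keep])
        if not trimmed.replace("-", ""):
            warnings.warn(f"{rec.id}: all informative columns removed by trimming")
        out.append(ProteinRecord(id=rec.id, residues=trimmed or "-",
                                 species=rec.species, has_start=rec.has_start,
                                 has_stop=rec.has_stop,
                                 evidence=dict(rec.evidence)))
    return out, removed


def protein_distance(a_aligned: str, b_aligned: str,
                     config: PhyloConfig | None = None) -> float:
    """Kimura-corrected protein distance d = -ln(1 - p - 0.2 p^2) where p is
    the mismatch fraction over mutually non-gap columns; saturated pairs
    (argument <= 0) return the distance cap."""
    if config is None:
        config = PhyloConfig()
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned rows must have equal length")
    both = mism = 0
    for x, y in zip(a_aligned, b_aligned):
        if x != "-" and y != "-":
            both += 1
            if x != y:
                mism += 1
    if both == 0:
        raise ValueError("zero mutually non-gap overlap")
    p = mism / both
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return config.max_distance_cap
    return min(-float(np.log(arg)), config.max_distance_cap)


def distance_matrix(msa: list[ProteinRecord],
                    config: PhyloConfig | None = None,
                    columns: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, list[str]]:
    """Pairwise Kimura distances over an alignment (optionally restricted to
    a resampled column index vector, for bootstrapping)."""
    if config is None:
        config = PhyloConfig()
    labels = [r.id for r in msa]
    arr = np.array([np.frombuffer(r.residues.encode(), dtype=np.uint8)
                    for r in msa])
    if columns is not None:
        arr = arr[:, columns]
    gap = ord("-")
    n = len(msa)
    D = np.zeros((n, n))
    nongap = arr != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            tot = int(both.sum())
            if tot == 0:
                raise ValueError(f"zero overlap between {labels[i]} and {labels[j]}")
            p = int((arr[i][both] != arr[j][both]).sum()) / tot
            a = 1.0 - p - 0.2 * p * p
            d = config.max_distance_cap if a <= 0 else min(-np.log(a),
                                                           config.max_distance_cap)
            D[i, j] = D[j, i] = d
    return D, labels


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Ties break to the smallest (row, column) label pair; negative branch
    lengths are clamped to zero with the deficit transferred to the sister
    branch.  Returns an unrooted tree (trifurcating root).
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    D = D.astype(float).copy()
    nodes = [TreeNode(name=lab) for lab in labels]
    # sort key per working node: smallest leaf label underneath
    keys = list(labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    ia, ib = active[a], active[b]
                    pair_key = tuple(sorted((keys[ia], keys[ib])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        d_ab = sub[a, b]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2 * (m - 2))
        lb = d_ab - la
        la, lb = _clamp_pair(la, lb)
        parent = TreeNode()
        ca, cb = nodes[ia], nodes[ib]
        ca.length, cb.length = la, lb
        parent.add(ca)
        parent.add(cb)
        # new row
        new_idx = D.shape[0]
        newd = np.zeros(new_idx + 1)
        for c in active:
            if c in (ia, ib):
                continue
            newd[c] = 0.5 * (D[ia, c] + D[ib, c] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, :new_idx] = newd[:new_idx]
        D[:new_idx, new_idx] = newd[:new_idx]
        nodes.append(parent)
        keys.append(min(keys[ia], keys[ib]))
        active = [c for c in active if c not in (ia, ib)] + [new_idx]

    # final three-point join
    i, j, k = active
    root = TreeNode()
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max(0.0, 0.5 * (dij + dik - djk))
    lj = max(0.0, 0.5 * (dij + djk - dik))
    lk = max(0.0, 0.5 * (dik + djk - dij))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = ln
        root.add(nodes[idx])
    return PhyloTree(root, rooted=False)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def outgroup_root(tree: PhyloTree, outgroup_labels: set[str] | list[str],
                  ) -> PhyloTree:
    """Root on the edge separating the outgroup from the rest.

    Supports stay attached to their bipartitions.  A non-monophyletic
    outgroup triggers a warning and roots on the edge maximizing the
    outgroup fraction on the outgroup side.
    """
    out = set(outgroup_labels)
    tree = tree.copy()
    all_leaves = tree.leaf_names()
    if not out <= all_leaves:
        raise ValueError(f"outgroup labels missing from tree: {sorted(out - all_leaves)}")
    if out == all_leaves:
        raise ValueError("outgroup cannot be the whole tree")

    best = None  # (frac, |O∩S|, det_key, node)
    exact = None
    for node in tree.root.traverse():
        if node is tree.root:
            continue
        side = node.leaf_names()
        for s in (side, all_leaves - side):
            inter = len(out & s)
            if inter == 0:
                continue
            if s == out:
                exact = node
            frac = inter / len(s)
            key = (frac, inter, tuple(sorted(s)))
            if best is None or key > best[0]:
                best = (key, node)
        if exact is not None:
            break
    if exact is None:
        warnings.warn("outgroup is not monophyletic; rooting on the edge with "
                      "the highest outgroup fraction")
        node = best[1]
    else:
        node = exact
    return _reroot_on_edge(tree, node)


def _reroot_on_edge(tree: PhyloTree, v: TreeNode) -> PhyloTree:
    """Place a degree-2 root in the middle of the edge above ``v``."""
    u = v.parent
    if u is None:
        raise ValueError("cannot root on the root's own edge")
    elen = v.length
    esup = v.support
    path = []
    node = u
    while node is not None:
        path.append(node)
        node = node.parent
    old_attrs = [(p.length, p.support) for p in path]

    u.children.remove(v)
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
    new_root = TreeNode()
    half = None if elen is None else elen / 2
    new_root.add(v)
    v.length, v.support = half, esup
    new_root.add(u)
    u.length, u.support = half, esup
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        a.add(b)
        b.length, b.support = old_attrs[i]
    # the old root may now be a degree-2 pass-through; splice it out
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        child = old_root.children[0]
        parent = old_root.parent
        parent.children[parent.children.index(old_root)] = child
        child.parent = parent
        if old_root.length is not None or child.length is not None:
            child.length = (old_root.length or 0.0) + (child.length or 0.0)
        if child.support is None:
            child.support = old_root.support
    for n in new_root.traverse():
        for c in n.children:
            c.parent = n
    return PhyloTree(new_root, rooted=True)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: list[ProteinRecord],
                      config: PhyloConfig | None = None,
                      seed: int | None = None) -> PhyloTree:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate (seeded); support is
    the percentage of replicate trees containing each original bipartition.
    """
    if config is None:
        config = PhyloConfig()
    if config.bootstrap_reps < 1:
        raise ValueError("bootstrap_reps must be >= 1")
    rng = np.random.default_rng(seed)
    D, labels = distance_matrix(msa, config)
    tree = nj_tree(D, labels)
    L = len(msa[0].residues)
    counts: dict[frozenset, int] = {}
    for _ in range(config.bootstrap_reps):
        cols = rng.integers(0, L, size=L)
        Db, _ = distance_matrix(msa, config, columns=cols)
        for bp in nj_tree(Db, labels).bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = tree.leaf_names()
    for node in tree.root.traverse():
        if node is tree.root or node.is_leaf:
            continue
        side = node.leaf_names()
        bp = frozenset({side, all_leaves - side})
        node.support = 100.0 * counts.get(bp, 0) / config.bootstrap_reps
    return tree


# ---------------------------------------------------------------------------
# Clan assignment
# ---------------------------------------------------------------------------

def assign_clans(tree: PhyloTree, reference_clans: dict[str, str],
                 config: PhyloConfig | None = None,
                 ) -> list[ClanAssignment]:
    """Assign each query leaf to a clan by the smallest supported clade that
    contains references of exactly one clan.

    From each query leaf the walk ascends; at the first ancestor containing
    references, a single shared clan with support >= threshold assigns the
    query (unsupported clades are skipped, not treated as evidence); if the
    references in the current clade span multiple clans before a qualifying
    clade was found, the query is unplaced.
    """
    if config is None:
        config = PhyloConfig()
    leaves = tree.leaves()
    ref_leaves = {l.name for l in leaves} & set(reference_clans)
    if not ref_leaves:
        raise ValueError("tree contains no reference leaves")
    no_support = all(n.support is None for n in tree.root.traverse()
                     if not n.is_leaf and n is not tree.root)
    if no_support:
        warnings.warn("tree has no support annotations; treating all clades "
                      "as fully supported")

    # precompute leaf sets bottom-up
    clade_refs: dict[int, set[str]] = {}
    clade_size: dict[int, int] = {}

    def collect(node: TreeNode) -> tuple[set[str], int]:
        if node.is_leaf:
            clans = ({reference_clans[node.name]}
                     if node.name in reference_clans else set())
            clade_refs[id(node)] = clans
            clade_size[id(node)] = 1
            return clans, 1
        clans: set[str] = set()
        size = 0
        for c in node.children:
            cc, cs = collect(c)
            clans |= cc
            size += cs
        clade_refs[id(node)] = clans
        clade_size[id(node)] = size
        return clans, size

    collect(tree.root)

    out: list[ClanAssignment] = []
    for leaf in leaves:
        if leaf.name in reference_clans:
            continue
        node = leaf.parent
        assignment = ClanAssignment(id=leaf.name, clan="unplaced")
        while node is not None:
            clans = clade_refs[id(node)]
            if clans:
                if len(clans) > 1:
                    break  # mixed references before any qualifying clade
                support = (100.0 if node.support is None or node is tree.root
                           else node.support)
                if support >= config.support_threshold:
                    assignment = ClanAssignment(
                        id=leaf.name, clan=next(iter(clans)), support=support,
                        defining_clade_size=clade_size[id(node)])
                    break
            node = node.parent
        out.append(assignment)
    return out
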