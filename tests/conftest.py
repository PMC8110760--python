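"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cypome.formats import TreeNode, PhyloTree
from cypome.motif_engine import MOTIF_ORDER, MotifConfig, scan


@pytest.fixture
def motif_config() -> MotifConfig:
    return MotifConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def brute_force_chain(seq: str, config: MotifConfig):
    """Exhaustive enumeration over all ordered combinations of reportable
    windows — the independent oracle for chain_motifs.

    Returns (total score, {motif: start or None}).
    """
    candidates = {}
    for name in MOTIF_ORDER:
        pat = config.patterns[name]
        hits = scan(seq, pat,
                    allow_single_indel=config.allow_single_indel
                    and name == "heme",
                    min_score=config.min_anchor_score[name])
        candidates[name] = [None] + hits

    def pair_bounds(a: str, b: str) -> tuple[int, int]:
        ia, ib = MOTIF_ORDER.index(a), MOTIF_ORDER.index(b)
        lo = sum(config.spacing_bounds[(MOTIF_ORDER[k], MOTIF_ORDER[k + 1])][0]
                 for k in range(ia, ib))
        hi = sum(config.spacing_bounds[(MOTIF_ORDER[k], MOTIF_ORDER[k + 1])][1]
                 for k in range(ia, ib))
        return lo, hi

    best = None
    for combo in itertools.product(*(candidates[n] for n in MOTIF_ORDER)):
        present = [(n, m) for n, m in zip(MOTIF_ORDER, combo) if m is not None]
        feasible = True
        for (na, ma), (nb, mb) in zip(present, present[1:]):
            lo, hi = pair_bounds(na, nb)
            if not lo <= mb.start - ma.start <= hi:
                feasible = False
                break
        if not feasible:
            continue
        score = sum(m.anchor_score for _, m in present)
        key = tuple(-(m.start if m is not None else math.inf) for m in combo)
        if best is None or (score, key) > (best[0], best[1]):
            best = (score, key, combo)
    score, _, combo = best
    return score, {n: (m.start if m else None)
                   for n, m in zip(MOTIF_ORDER, combo)}


def random_binary_tree(labels: list[str], rng: np.random.Generator,
                       ) -> PhyloTree:
    """Random unrooted binary tree with positive branch lengths (for
    additive-matrix recovery tests)."""
    nodes = [TreeNode(name=l, length=float(rng.uniform(0.05, 1.0)))
             for l in labels]
    work = list(nodes)
    while len(work) > 3:
        i, j = sorted(rng.choice(len(work), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.add(work[i])
        parent.add(work[j])
        work = [w for k, w in enumerate(work) if k not in (i, j)] + [parent]
    root = TreeNode()
    for w in work:
        root.add(w)
    return PhyloTree(root, rooted=False)


def tree_distances(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix via pairwise LCA walks."""
    leaves = tree.leaves()
    labels = [l.name for l in leaves]

    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    n = len(leaves)
    D = np.zeros((n, n))
    paths = [path_to_root(l) for l in leaves]
    for i in range(n):
        for j in range(i + 1, n):
            ancestors = set(id(x) for x in paths[j])
            d = 0.0
            node = leaves[i]
            while id(node) not in ancestors:
                d += node.length or 0.0
                node = node.parent
            lca = node
            node = leaves[j]
            while node is not lca:
                d += node.length or 0.0
                node = node.parent
            D[i, j] = D[j, i] = d
    return D, labels
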