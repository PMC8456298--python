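"""Distance-based plastome phylogenetics and cytonuclear conflict metrics.

Simulated plastomes are substitution-only, so positional homology holds and the
sequences are already aligned; p-distances or JC69 distances feed a
neighbor-joining tree, with nonparametric bootstrap over alignment columns.
Robinson-Foulds distances and monophyly tests quantify the conflict between the
plastid tree and the nuclear (repeat-dendrogram) signal.
"""

from __future__ import annotations

import numpy as np
import dendropy
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


def _aln_to_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = sorted(alignment)
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("plastome sequences must have equal lengths (aligned)")
    rows = []
    for n in names:
        s = alignment[n]
        rows.append(np.frombuffer(s.encode(), np.uint8) if isinstance(s, str)
                    else np.asarray(s, dtype=np.uint8))
    return names, np.vstack(rows)


def plastome_distances(alignment: dict[str, str], model: str = "jc69") -> DistanceMatrix:
    """Pairwise distances: p = mismatches/length, or the JC69 correction
    d = -(3/4) ln(1 - 4p/3) (undefined at p >= 0.75)."""
    names, m = _aln_to_matrix(alignment)
    n, L = m.shape
    p = np.zeros((n, n))
    for i in range(n):
        diff = (m[i] != m[i + 1:]).sum(axis=1) / L
        p[i, i + 1:] = diff
        p[i + 1:, i] = diff
    if model == "p-distance":
        d = p
    elif model == "jc69":
        off = ~np.eye(n, dtype=bool)
        if (p[off] >= 0.75).any():
            raise ValueError("saturated divergence (p >= 0.75) under JC69")
        d = np.zeros_like(p)
        d[off] = -0.75 * np.log(1.0 - 4.0 * p[off] / 3.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return DistanceMatrix(d, names)


def jc69_distance(p: float) -> float:
    """Closed-form JC69 distance for an observed mismatch fraction p."""
    if p >= 0.75:
        raise ValueError("saturated divergence (p >= 0.75)")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ (Saitou-Nei agglomeration; negative branch lengths clamped
    to zero); returns an unrooted tree."""
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    sk_tree = _skbio_nj(dist, neg_as_zero=True)
    newick = str(sk_tree).strip()
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _common_namespace(*trees: dendropy.Tree) -> list[dendropy.Tree]:
    tns = dendropy.TaxonNamespace()
    out = []
    for t in trees:
        nw = t.as_string(schema="newick", suppress_rooting=True)
        nt = dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=tns)
        nt.is_rooted = False
        nt.encode_bipartitions()
        out.append(nt)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Count of non-trivial splits present in exactly one of the two trees."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("leaf sets differ")
    a, b = _common_namespace(t1, t2)
    return int(treecompare.symmetric_difference(a, b))


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side,
    ties broken lexicographically) — the unrooted split set."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    (t,) = _common_namespace(tree)
    out: set[frozenset] = set()
    labels = sorted(leaves)
    for edge in t.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = edge.bipartition.leafset_bitmask
        side = frozenset(lab for i, lab in enumerate(
            x.label for x in t.taxon_namespace) if mask >> i & 1)
        comp = leaves - side
        if len(side) < 2 or len(comp) < 2:
            continue
        canon = min(side, comp, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def is_monophyletic(tree: dendropy.Tree, taxa, outgroup: str | None = None) -> bool:
    """True iff some split separates exactly ``taxa`` (unrooted sense); with an
    ``outgroup`` label the tree is first rooted on it and the rooted sense
    (an ancestor whose descendants are exactly the subset) is used."""
    taxa = frozenset(taxa)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not taxa:
        raise ValueError("empty taxon subset")
    unknown = taxa - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if outgroup is not None:
        if outgroup not in leaves:
            raise ValueError(f"unknown outgroup {outgroup!r}")
        rest = leaves - {outgroup}
        if taxa == rest or len(taxa) == 1:
            return True
        return taxa in _rooted_clades(tree, outgroup)
    if taxa == leaves or len(taxa) == 1 or len(leaves - taxa) == 1:
        return True
    return min(taxa, leaves - taxa,
               key=lambda s: (len(s), sorted(s))) in tree_splits(tree)


def _rooted_clades(tree: dendropy.Tree, outgroup: str) -> set[frozenset]:
    nw = tree.as_string(schema="newick", suppress_rooting=True)
    t = dendropy.Tree.get(data=nw, schema="newick")
    og = t.find_node_with_taxon_label(outgroup)
    t.to_outgroup_position(og, update_bipartitions=False, suppress_unifurcations=True)
    clades: set[frozenset] = set()
    for node in t.preorder_node_iter():
        labs = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if outgroup not in labs:
            clades.add(labs)
    return clades


def bootstrap_support(alignment: dict[str, str], B: int = 100, seed: int = 0,
                      model: str = "jc69") -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement B times; the support of each
    internal split is the fraction of replicate trees containing it, written as
    the internal node label.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    names, m = _aln_to_matrix(alignment)
    main = neighbor_joining(plastome_distances(alignment, model=model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    L = m.shape[1]
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep_aln = {n: m[i, cols] for i, n in enumerate(names)}
        try:
            rep = neighbor_joining(plastome_distances(rep_aln, model=model))
        except ValueError:  # saturated replicate
            continue
        for split in tree_splits(rep):
            counts[split] = counts.get(split, 0) + 1
    leaves = frozenset(names)
    for node in main.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        labs = frozenset(lf.taxon.label for lf in node.leaf_iter())
        comp = leaves - labs
        if len(labs) < 2 or len(comp) < 2:
            continue
        canon = min(labs, comp, key=lambda s: (len(s), sorted(s)))
        node.label = f"{counts.get(canon, 0) / B:.2f}"
    return main


def clade_collapsed_tree(tree: dendropy.Tree, clade_map: dict[str, str],
                         clades) -> dendropy.Tree | None:
    """Collapse each (monophyletic) clade to a single leaf named after it.

    Returns None when some clade is not monophyletic (unrooted sense), in which
    case a collapsed topology is not defined.  Leaves outside ``clades``
    (e.g. an outgroup) are pruned.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    members = {c: [sp for sp in leaves if clade_map.get(sp) == c] for c in clades}
    for c, sps in members.items():
        if not sps:
            raise ValueError(f"no leaves for clade {c}")
        if not is_monophyletic(tree, sps):
            return None
    nw = tree.as_string(schema="newick", suppress_rooting=True)
    t = dendropy.Tree.get(data=nw, schema="newick")
    reps = {sorted(sps)[0]: c for c, sps in members.items()}
    keep = set(reps)
    t.retain_taxa_with_labels(sorted(keep))
    for lf in t.leaf_node_iter():
        lf.taxon.label = reps[lf.taxon.label]
    t.is_rooted = False
    return t
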