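"""Species-by-species correlation of repeat-cluster abundances and its dendrogram.

The species' abundance vectors over the top clusters are log-transformed
(log1p of reads-per-million) and correlated (Pearson); agglomerative average
linkage on distance 1 - r yields the species dendrogram whose deep structure
is the nuclear (repeat) phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # symmetric, unit diagonal

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def validate(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def to_long(self) -> pd.DataFrame:
        out = self.values.stack().reset_index()
        out.columns = ["species_i", "species_j", "r"]
        return out


def correlation_matrix(matrix, top: list, transform: str = "log1p_normalized",
                       species: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation between species over top-cluster abundances.

    ``transform``: "log1p_normalized" (default; log(1 + reads per million)),
    "log1p_raw", or "raw".  A zero-variance species vector makes its
    correlations undefined and raises, naming the species.
    """
    if transform == "log1p_normalized":
        # depth-normalize to the median species total (not per-million): keeps
        # counts on their natural scale so log1p of a stray singleton stays
        # near zero instead of rivalling a genuinely abundant cluster
        totals = matrix.counts.sum(axis=0)
        med = float(np.median(totals[species] if species is not None else totals))
        data = np.log1p(matrix.counts.loc[top] / totals.replace(0, 1) * med)
    elif transform == "log1p_raw":
        data = np.log1p(matrix.counts.loc[top])
    elif transform == "raw":
        data = matrix.counts.loc[top].astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if species is not None:
        data = data[species]
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 species and 2 clusters")
    flat = [sp for sp in data.columns if float(data[sp].std()) == 0.0]
    if flat:
        raise ValueError(f"zero-variance abundance vector for species: {', '.join(flat)}")
    corr = data.corr(method="pearson")
    return CorrelationMatrix(corr)


@dataclass
class Dendrogram:
    """Rooted binary merge tree from average-linkage clustering on 1 - r."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def root(self):
        return to_tree(self.linkage_matrix)

    def leaf_sets(self) -> dict[int, frozenset]:
        """Node id -> set of leaf labels under that node."""
        out: dict[int, frozenset] = {}

        def rec(node):
            if node.is_leaf():
                s = frozenset([self.labels[node.id]])
            else:
                s = rec(node.left) | rec(node.right)
            out[node.id] = s
            return s

        rec(self.root())
        return out


def hierarchical_cluster(corr: CorrelationMatrix, method: str = "average") -> Dendrogram:
    """Agglomerate species on distance d = 1 - r; labels are pre-sorted so that
    ties break deterministically by label order."""
    corr.validate()
    labels = sorted(corr.species)
    d = 1.0 - corr.values.loc[labels, labels].to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    z = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(z, labels)


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    """Newick with branch lengths equal to half the height difference between a
    node and its parent (ultrametric representation: leaves sit at depth h/2)."""

    def rec(node, parent_height: float) -> str:
        bl = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{dendro.labels[node.id]}:{bl:.10g}"
        inner = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
        return f"{inner}:{bl:.10g}"

    root = dendro.root()
    if root.is_leaf():
        return f"{dendro.labels[root.id]}:0;"
    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def grouping_check(dendro: Dendrogram, clade_map: dict[str, str]) -> dict:
    """Report per-clade coherence and which clades share the two deepest branches.

    A clade is coherent when its species form a contiguous subtree (some node's
    leaf set equals the clade's species set).  ``deep_split_pairs`` lists, for
    each of the root's two children, the clades wholly contained in it.
    """
    leaves = set(dendro.labels)
    for sp in leaves:
        if sp not in clade_map:
            raise ValueError(f"species {sp} missing from clade map")
    clades: dict[str, set] = {}
    for sp in dendro.labels:
        clades.setdefault(clade_map[sp], set()).add(sp)
    node_sets = set(dendro.leaf_sets().values())
    coherence = {c: (len(s) == 1 or frozenset(s) in node_sets) for c, s in clades.items()}
    root = dendro.root()
    sides = []
    if not root.is_leaf():
        ls = dendro.leaf_sets()
        for child in (root.left, root.right):
            child_leaves = ls[child.id]
            sides.append(sorted(c for c, s in clades.items() if s <= child_leaves))
    return {
        "clade_coherence": coherence,
        "deep_split_pairs": sides,
        "all_coherent": all(coherence.values()),
    }
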