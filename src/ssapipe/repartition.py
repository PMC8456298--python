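"""Cluster x species abundance accounting and the 4-clade shared/exclusive partition.

Given a read-cluster table, this module tabulates the cluster-by-species read
count matrix, selects the most abundant clusters up to a cumulative fraction of
all clustered reads (the "top clusters making up 50% of clustered reads" rule),
derives a cluster-by-clade presence matrix, and counts clusters per exact
clade-subset (the 15 regions of a 4-set Venn diagram).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

CLADES = ("Olyreae", "Arundinarieae", "NWB", "PWB")


@dataclass
class AbundanceMatrix:
    """Raw cluster x species read counts plus per-species normalized abundances."""

    counts: pd.DataFrame      # index cluster_id, columns species
    normalized: pd.DataFrame  # reads per million clustered reads of each species

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cluster_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def species_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def abundance_matrix(cluster_table) -> AbundanceMatrix:
    """Tabulate exact counts; normalization is reads-per-million clustered reads
    of the species (recorded alongside, the raw counts stay authoritative)."""
    df = cluster_table.assignments if hasattr(cluster_table, "assignments") else cluster_table
    if not len(df):
        empty = pd.DataFrame()
        return AbundanceMatrix(empty, empty)
    counts = (df.groupby(["cluster_id", "species"]).size()
              .unstack(fill_value=0).sort_index())
    totals = counts.sum(axis=0)
    normalized = counts / totals.replace(0, 1) * 1e6
    return AbundanceMatrix(counts, normalized)


def select_top_clusters(matrix: AbundanceMatrix, fraction: float = 0.5) -> list:
    """Shortest prefix of clusters (by total reads, descending; ties by id
    ascending) whose cumulative read count reaches ``fraction`` of all
    clustered reads."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if matrix.counts.empty:
        raise ValueError("empty abundance matrix")
    totals = matrix.cluster_totals()
    order = sorted(totals.index, key=lambda c: (-totals[c], c))
    target = fraction * matrix.grand_total
    out, cum = [], 0
    for cid in order:
        out.append(cid)
        cum += int(totals[cid])
        if cum >= target:
            break
    return out


def clade_presence(matrix: AbundanceMatrix, clade_map: dict[str, str],
                   top: list, min_reads: int = 1, min_species: int = 1,
                   clades: tuple = CLADES) -> pd.DataFrame:
    """Presence matrix (cluster x clade, 0/1): a cluster is present in a clade
    iff at least ``min_species`` species of the clade each contribute at least
    ``min_reads`` reads."""
    for sp in matrix.counts.columns:
        if sp not in clade_map:
            raise ValueError(f"species {sp} missing from clade map")
    sub = matrix.counts.loc[top]
    out = {}
    for clade in clades:
        sps = [s for s in sub.columns if clade_map[s] == clade]
        if sps:
            out[clade] = ((sub[sps] >= min_reads).sum(axis=1) >= min_species).astype(int)
        else:
            out[clade] = pd.Series(0, index=sub.index)
    return pd.DataFrame(out)


@dataclass
class CladePartition:
    """Counts of top clusters per exact clade-presence pattern (15 Venn regions)."""

    clades: tuple
    region_counts: dict[frozenset, int]
    absent: int  # all-zero presence rows, reported separately

    def region(self, *clades: str) -> int:
        return self.region_counts.get(frozenset(clades), 0)

    def per_clade_total(self, clade: str) -> int:
        return sum(n for region, n in self.region_counts.items() if clade in region)

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())

    def exclusive_pair(self, a: str, b: str) -> int:
        """Clusters shared by exactly clades {a, b} and no other."""
        return self.region(a, b)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.region_counts, key=lambda s: (len(s), sorted(s))):
            rows.append(("+".join(sorted(r, key=self.clades.index)),
                         len(r), self.region_counts[r]))
        return pd.DataFrame(rows, columns=["region", "n_clades", "count"])

    def to_dict(self) -> dict:
        return {
            "regions": {"+".join(sorted(r, key=self.clades.index)): n
                        for r, n in sorted(self.region_counts.items(),
                                           key=lambda kv: (len(kv[0]), sorted(kv[0])))},
            "per_clade_totals": {c: self.per_clade_total(c) for c in self.clades},
            "woody_triple": self.region("Arundinarieae", "NWB", "PWB")
            if set(("Arundinarieae", "NWB", "PWB")) <= set(self.clades) else None,
            "absent": self.absent,
        }

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def venn_partition(presence: pd.DataFrame) -> CladePartition:
    """Count clusters per exact presence pattern over exactly four clades."""
    clades = tuple(presence.columns)
    if len(clades) != 4:
        raise ValueError("presence matrix must cover exactly 4 clades")
    counts: dict[frozenset, int] = {}
    for r in range(1, 5):
        for combo in combinations(clades, r):
            counts[frozenset(combo)] = 0
    absent = 0
    for _, row in presence.iterrows():
        present = frozenset(c for c in clades if row[c])
        if not present:
            absent += 1
        else:
            counts[present] += 1
    return CladePartition(clades, counts, absent)
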