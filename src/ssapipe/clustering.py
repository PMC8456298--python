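"""Graph-based clustering of pooled multi-species reads into repeat families.

A cluster is the read-graph analogue of a repeat family: reads are linked
whenever a local alignment on either strand shows more than 80% identity over
a sufficient overlap, and families are the connected components of that graph.
Species are carried along from the read-id prefix (everything before the first
underscore), which is the contract the downstream repartition stage consumes.

Candidate pairs are proposed by a shared-k-mer prefilter and every candidate
is verified by alignment, so no edge can violate the identity or overlap
thresholds; a brute-force all-vs-all mode bypasses the prefilter for oracle
checks on small inputs.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import Align, SeqIO

# defaults mirror the >80%-identity family definition with an mgblast-like
# minimum overlap of 55% of the shorter read
IDENTITY_THRESHOLD = 0.80
MIN_OVERLAP_FRAC = 0.55
KMER_SIZE = 15
MIN_SHARED_KMERS = 1
MIN_CLUSTER_SIZE = 5

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(s: str) -> str:
    return s.translate(_RC)[::-1]


def species_of(read_id: str) -> str:
    return read_id.split("_", 1)[0]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def read_sequences(path) -> list[tuple[str, str]]:
    """Load (read_id, sequence) pairs from FASTA/FASTQ, optionally gzipped."""
    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith(("fastq", "fq")) else "fasta"
    with opener(p, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def filter_reads(reads: list[tuple[str, str]], min_len: int) -> list[tuple[str, str]]:
    """Drop reads shorter than ``min_len`` (boundary inclusive); order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [(rid, seq) for rid, seq in reads if len(seq) >= min_len]


def pairwise_identity(r1: str, r2: str, min_overlap_frac: float = MIN_OVERLAP_FRAC,
                      aligner: Align.PairwiseAligner | None = None):
    """Best-strand local alignment identity between two reads.

    Returns (identity, overlap_columns) where identity = matches / alignment
    columns, or None if the alignment span is shorter than
    ``min_overlap_frac`` times the shorter read.
    """
    if not r1 or not r2:
        raise ValueError("empty read")
    al = aligner or _aligner()
    fwd = al.score(r1, r2)
    r2rc = reverse_complement(r2)
    rev = al.score(r1, r2rc)
    aln = al.align(r1, r2 if fwd >= rev else r2rc)[0]
    counts = aln.counts()
    cols = aln.length
    if cols < min_overlap_frac * min(len(r1), len(r2)):
        return None
    return counts.identities / cols, cols


@dataclass
class SimilarityGraph:
    """Undirected read-similarity graph; edges carry identity and overlap length."""

    graph: nx.Graph
    identity_threshold: float = IDENTITY_THRESHOLD
    min_overlap_frac: float = MIN_OVERLAP_FRAC

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d["identity"] <= self.identity_threshold:
                raise ValueError(f"edge ({u},{v}) below identity threshold")


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    return {min(seq[i:i + k], rc[n - k - i:n - i]) for i in range(n - k + 1)}


def build_similarity_graph(reads: list[tuple[str, str]],
                           identity_threshold: float = IDENTITY_THRESHOLD,
                           min_overlap_frac: float = MIN_OVERLAP_FRAC,
                           k: int = KMER_SIZE,
                           min_shared_kmers: int = MIN_SHARED_KMERS,
                           brute_force: bool = False) -> SimilarityGraph:
    """Build the read-similarity graph.

    Shared-canonical-k-mer counting proposes candidate pairs (at least
    ``min_shared_kmers`` k-mers in common; random k-mer collisions between
    unrelated reads are vanishingly rare at k=15, so a single shared k-mer is
    sound evidence); every candidate is then verified
    with :func:`pairwise_identity`, and an edge is added only when identity
    strictly exceeds the threshold and the overlap is sufficient.  With
    ``brute_force=True`` all pairs are verified (the oracle mode).
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    ids = [rid for rid, _ in reads]
    seqs = [seq for _, seq in reads]
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(reads)
    if n > 1 and any(len(s) < k for s in seqs) and not brute_force:
        raise ValueError(f"k={k} exceeds a read length; filter reads first")

    if brute_force:
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        buckets: dict[str, list[int]] = defaultdict(list)
        for i, s in enumerate(seqs):
            for km in _canonical_kmers(s, k):
                buckets[km].append(i)
        pair_counts: Counter = Counter()
        for members in buckets.values():
            if len(members) < 2:
                continue
            for a in range(len(members)):
                ma = members[a]
                for b in range(a + 1, len(members)):
                    pair_counts[(ma, members[b])] += 1
        candidates = [p for p, c in pair_counts.items() if c >= min_shared_kmers]

    al = _aligner()
    # score-only prescreen: an edge needs matches > t*cols and cols >= min
    # overlap, so its best local score is at least (2t-1)*min_overlap columns
    min_cols_abs = {}
    for i, j in candidates:
        s1, s2 = seqs[i], seqs[j]
        key = min(len(s1), len(s2))
        floor = min_cols_abs.get(key)
        if floor is None:
            floor = min_cols_abs[key] = (2 * identity_threshold - 1) * min_overlap_frac * key
        s2rc = reverse_complement(s2)
        sc_f = al.score(s1, s2)
        sc_r = al.score(s1, s2rc)
        if max(sc_f, sc_r) < floor:
            continue
        aln = al.align(s1, s2 if sc_f >= sc_r else s2rc)[0]
        cols = aln.length
        if cols < min_overlap_frac * key:
            continue
        ident = aln.counts().identities / cols
        if ident > identity_threshold:
            g.add_edge(ids[i], ids[j], identity=ident, overlap=cols)
    return SimilarityGraph(g, identity_threshold, min_overlap_frac)


@dataclass
class ClusterTable:
    """Partition of clustered reads into repeat clusters, with per-species counts."""

    assignments: pd.DataFrame        # read_id, species, cluster_id
    unclustered: list[str]
    min_cluster_size: int
    superfamilies: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.assignments["cluster_id"].nunique() if len(self.assignments) else 0

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.groupby("cluster_id").size().sort_index()

    def members(self, cluster_id: int) -> list[str]:
        return self.assignments.loc[self.assignments.cluster_id == cluster_id,
                                    "read_id"].tolist()

    def summary(self) -> pd.DataFrame:
        if not len(self.assignments):
            return pd.DataFrame(columns=["cluster_id", "size", "superfamily"])
        per_species = (self.assignments.groupby(["cluster_id", "species"]).size()
                       .unstack(fill_value=0))
        out = pd.DataFrame({
            "cluster_id": per_species.index,
            "size": per_species.sum(axis=1).values,
            "superfamily": [self.superfamilies.get(c, "") for c in per_species.index],
        }).set_index("cluster_id")
        return out.join(per_species).reset_index()

    def write_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def cluster_reads(sim_graph: SimilarityGraph,
                  min_cluster_size: int = MIN_CLUSTER_SIZE) -> ClusterTable:
    """Extract clusters as connected components of size >= ``min_cluster_size``.

    Cluster ids are assigned in decreasing component size; ties broken by the
    smallest member read_id.  Reads in smaller components are reported as
    unclustered.
    """
    comps = [sorted(c) for c in nx.connected_components(sim_graph.graph)]
    kept = [c for c in comps if len(c) >= max(1, min_cluster_size)]
    kept.sort(key=lambda c: (-len(c), c[0]))
    rows = []
    for cid, comp in enumerate(kept, start=1):
        for rid in comp:
            rows.append((rid, species_of(rid), cid))
    unclustered = sorted(rid for c in comps if len(c) < max(1, min_cluster_size)
                         for rid in c)
    df = pd.DataFrame(rows, columns=["read_id", "species", "cluster_id"])
    return ClusterTable(df, unclustered, min_cluster_size)


# ---------------------------------------------------------------------------
# superfamily classification against a repeat library
# ---------------------------------------------------------------------------

class LibraryIndex:
    """Canonical k-mer inverted index over library consensus sequences."""

    def __init__(self, library, k: int = 11):
        self.k = k
        self.superfamily: dict[str, str] = {}
        self.kmer_to_family: dict[str, set[str]] = defaultdict(set)
        for fam in library:
            from .simulate import seq_to_str  # library consensi are uint8 arrays
            seq = fam.consensus if isinstance(fam.consensus, str) else seq_to_str(fam.consensus)
            self.superfamily[fam.family_id] = fam.superfamily
            for km in _canonical_kmers(seq, k):
                self.kmer_to_family[km].add(fam.family_id)

    def best_hit(self, seq: str) -> tuple[str | None, float]:
        kms = _canonical_kmers(seq, self.k)
        if not kms:
            return None, 0.0
        counts: Counter = Counter()
        for km in kms:
            for fid in self.kmer_to_family.get(km, ()):
                counts[fid] += 1
        if not counts:
            return None, 0.0
        fid, c = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        return fid, c / len(kms)


def classify_cluster(read_seqs: list[str], index: LibraryIndex,
                     containment_floor: float = 0.15,
                     min_hit_frac: float = 0.5,
                     max_reads: int = 60) -> str:
    """Majority best-hit vote of cluster reads against the library.

    Each read is assigned to the consensus with maximal shared-k-mer
    containment above ``containment_floor``; the cluster label is the plurality
    superfamily, or "unknown" when fewer than ``min_hit_frac`` of reads hit.
    """
    if not index.superfamily:
        raise ValueError("empty library")
    sample = read_seqs[:max_reads]
    votes: Counter = Counter()
    hits = 0
    for seq in sample:
        fid, containment = index.best_hit(seq)
        if fid is not None and containment >= containment_floor:
            hits += 1
            votes[index.superfamily[fid]] += 1
    if not sample or hits / len(sample) < min_hit_frac:
        return "unknown"
    return max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]


def classify_clusters(table: ClusterTable, seqs_by_id: dict[str, str],
                      index: LibraryIndex, **kw) -> ClusterTable:
    """Label every cluster in a table; returns the same table with labels filled."""
    for cid in sorted(table.assignments["cluster_id"].unique()):
        members = table.members(cid)
        table.superfamilies[int(cid)] = classify_cluster(
            [seqs_by_id[r] for r in members], index, **kw)
    return table
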