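"""Synthetic low-depth sequencing data for a hybridization / biased-fractionation scenario.

This module simulates the nuclear and plastid genomes of a set of related
lineages evolving under a model of ancient hybridization, transient
allopolyploidy, subgenome-biased fractionation (genome dominance) and
diploidization, together with their mobilomes (transposable-element family
complements).  It then samples low-coverage paired reads at a requested
coverage C = L*N/G per species, with a full per-read truth table
(read -> repeat family or background).

The default scenario encodes a bamboo-like four-clade history: a herbaceous
ancestral genome (H, leading to the Olyreae), and two woody ancestral genomes
(C and D).  A maternal-H x paternal-C hybridization with near-complete loss of
the H subgenome founds the tropical woody lineage (NWB + PWB), so that those
clades carry an H-derived, maternally inherited plastome while their nuclear
background is C-derived; TE families active in the herbaceous lineage
transpose into the retained C blocks around the hybridization events and
survive fractionation.  The temperate clade (Arundinarieae) arises from a
C x D hybridization and keeps a non-H plastome.  This architecture produces
a cytonuclear conflict: repeat-abundance similarity pairs Olyreae with NWB and
Arundinarieae with PWB, while the plastome tree groups Olyreae with both
Bambuseae clades to the exclusion of Arundinarieae.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# sequence primitives (A,C,G,T <-> uint8 0..3)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[ord(chr(_b).lower())] = _i
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def seq_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr.copy()


def random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rng_for(master_seed: int, *parts: str) -> np.random.Generator:
    """Derive an independent, stable random stream from a master seed and string keys."""
    keys = [int(master_seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(p.encode()) & 0x7FFFFFFF for p in parts]
    return np.random.default_rng(keys)


def mutate_sequence(seq, d: float, seed) -> np.ndarray | str:
    """Substitute each site independently with probability ``d`` (capped at 0.75).

    ``d`` is the expected observed per-site divergence from the input; a
    substituted site receives one of the three other bases uniformly.  Accepts
    and returns either a string or a uint8 array; deterministic given ``seed``
    (an int or a numpy Generator).
    """
    if d < 0:
        raise ValueError("substitution rate d must be >= 0")
    as_str = isinstance(seq, str)
    arr = str_to_seq(seq) if as_str else np.asarray(seq, dtype=np.uint8)
    d_eff = min(float(d), 0.75)
    rng = _as_rng(seed)
    out = arr.copy()
    if d_eff > 0 and len(out):
        hit = np.flatnonzero(rng.random(len(out)) < d_eff)
        if len(hit):
            out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit), dtype=np.uint8)) % 4
    return seq_to_str(out) if as_str else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

SUPERFAMILIES = ("Gypsy", "Copia", "DNA", "simple", "other")


@dataclass(frozen=True)
class TEFamily:
    """A repeat family: a named consensus with a superfamily class and origin genome."""

    family_id: str
    superfamily: str
    consensus: np.ndarray  # uint8
    origin_genome: str

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if len(self.consensus) == 0:
            raise ValueError("empty consensus")


class RepeatLibrary:
    """Named TE family consensus sequences; the simulation's ground truth."""

    def __init__(self, families: list[TEFamily]):
        self.families = list(families)
        self._by_id = {f.family_id: f for f in families}
        if len(self._by_id) != len(families):
            raise ValueError("duplicate family_id in library")

    def __len__(self):
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def __getitem__(self, family_id: str) -> TEFamily:
        return self._by_id[family_id]

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._by_id

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.families:
                fh.write(f">{f.family_id} superfamily={f.superfamily} origin={f.origin_genome}\n")
                fh.write(seq_to_str(f.consensus) + "\n")


@dataclass
class SubgenomeBlock:
    """A contiguous nuclear segment tagged with its parental (ancestral-genome) origin.

    ``copies`` holds (family_id, start, end, inserted_after_hybridization),
    0-based half-open, sorted and non-overlapping.
    """

    parent_label: str
    seq: np.ndarray
    copies: list[tuple[str, int, int, bool]] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = 0
        for fid, s, e, _ in self.copies:
            if not (0 <= s < e <= len(self.seq)):
                raise ValueError(f"copy {fid} interval [{s},{e}) outside block")
            if s < prev_end:
                raise ValueError(f"copy {fid} overlaps previous copy")
            prev_end = e

    def clone(self) -> "SubgenomeBlock":
        return SubgenomeBlock(self.parent_label, self.seq.copy(), list(self.copies))


@dataclass
class GenomeState:
    """A lineage's nuclear genome (subgenome blocks with TE provenance) plus plastome."""

    label: str
    blocks: list[SubgenomeBlock]
    plastome: np.ndarray
    plastome_lineage: str
    ploidy_contrib: dict[str, int]  # ancestral label -> ploidy contributed

    @property
    def ploidy(self) -> int:
        return sum(self.ploidy_contrib.values())

    @property
    def total_length(self) -> int:
        return sum(len(b.seq) for b in self.blocks)

    def family_copy_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.blocks:
            for fid, _, _, _ in b.copies:
                out[fid] = out.get(fid, 0) + 1
        return out

    def clone(self) -> "GenomeState":
        return GenomeState(
            self.label,
            [b.clone() for b in self.blocks],
            self.plastome.copy(),
            self.plastome_lineage,
            dict(self.ploidy_contrib),
        )

    def validate(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        for b in self.blocks:
            b.validate()


@dataclass(frozen=True)
class ReadSamplingSpec:
    """Sampling plan honouring C = L*N/G exactly (N rounded up, C recomputed)."""

    L: int
    N: int
    G: int
    C: float
    paired: bool = True
    insert: int = 300
    seed: int = 0

    @classmethod
    def from_coverage(cls, L: int, C: float, G: int, paired: bool = True,
                      insert: int = 300, seed: int = 0) -> "ReadSamplingSpec":
        if L <= 0 or G <= 0 or C < 0:
            raise ValueError("need L > 0, G > 0, C >= 0")
        n = math.ceil(C * G / L)
        if paired and n % 2:
            n += 1
        return cls(L=L, N=n, G=G, C=L * n / G, paired=paired, insert=insert, seed=seed)

    def __post_init__(self):
        if self.L <= 0 or self.G <= 0:
            raise ValueError("need L > 0 and G > 0")
        if abs(self.C - self.L * self.N / self.G) > 1e-9:
            raise ValueError("C = L*N/G must hold exactly")


@dataclass
class ReadSet:
    """Species-prefixed reads plus the truth mapping read -> family/background."""

    species: str
    clade: str
    spec: ReadSamplingSpec
    read_ids: list[str]
    sequences: list[str]
    mates: np.ndarray          # 1 or 2 per read
    family_ids: list[str]      # "background" for non-repeat reads
    origins: list[str]         # ancestral-genome label of the source block/family

    def __len__(self):
        return len(self.read_ids)

    def truth(self) -> dict[str, tuple[str, str]]:
        return {r: (f, o) for r, f, o in zip(self.read_ids, self.family_ids, self.origins)}

    def write_fastq(self, fh) -> None:
        L_qual = {}
        for rid, seq in zip(self.read_ids, self.sequences):
            q = L_qual.get(len(seq))
            if q is None:
                q = L_qual[len(seq)] = "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{q}\n")

    def write_truth(self, fh, header: bool = True) -> None:
        if header:
            fh.write("read_id\tspecies\tclade\tfamily_id\torigin_genome\n")
        for rid, fid, org in zip(self.read_ids, self.family_ids, self.origins):
            fh.write(f"{rid}\t{self.species}\t{self.clade}\t{fid}\t{org}\n")


# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------

EVENT_KINDS = ("divergence", "hybridization", "fractionation", "te_burst", "establish")


@dataclass
class Event:
    """A lineage-history event bound to a scenario node.

    kinds and params:
      establish     {label, ancestral_copies: {family_id: n}}  (founds an ancestral genome)
      hybridization {partner: node name, maternal: node name}
      fractionation {removed_parent: label, f: probability}
      te_burst      {family_id, n_copies, post_hybrid: bool}
      divergence    {}  (no-op marker; splits are implicit in the tree)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "fractionation":
            f = self.params["f"]
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractionation probability f must be in [0,1]")
        if self.kind == "te_burst" and self.params["n_copies"] < 0:
            raise ValueError("te_burst copy count must be >= 0")


@dataclass
class LineageNode:
    name: str
    parent: str | None
    branch_length: float
    events: list[Event] = field(default_factory=list)
    tip: bool = False

    def __post_init__(self):
        if self.branch_length < 0:
            raise ValueError("branch lengths must be >= 0")


@dataclass
class Scenario:
    """A lineage tree with events, a TE family library and per-species sampling params."""

    nodes: list[LineageNode]                 # parent always defined before child
    library: RepeatLibrary
    clade_map: dict[str, str]                # tip species -> clade
    species_params: dict[str, dict]          # species -> {coverage, read_length}
    block_size: int = 50_000
    insert_size: int = 300
    plastome_length: int = 20_000
    background_length: int = 2_000_000
    intra_family_divergence: float = 0.05
    clades: tuple[str, ...] = ("Olyreae", "Arundinarieae", "NWB", "PWB")

    def node(self, name: str) -> LineageNode:
        return self._index()[name]

    def _index(self) -> dict[str, LineageNode]:
        return {n.name: n for n in self.nodes}

    def tips(self) -> list[LineageNode]:
        return [n for n in self.nodes if n.tip]

    def validate(self) -> None:
        seen: set[str] = set()
        idx = self._index()
        if len(idx) != len(self.nodes):
            raise ValueError("duplicate node names")
        for n in self.nodes:
            if n.parent is not None and n.parent not in seen:
                raise ValueError(f"node {n.name}: parent {n.parent} not defined before use")
            for ev in n.events:
                if ev.kind == "hybridization":
                    partner = ev.params["partner"]
                    if partner not in seen:
                        raise ValueError(
                            f"hybridization at {n.name} references unknown/extinct lineage {partner}")
                    maternal = ev.params["maternal"]
                    if maternal not in (partner, n.name):
                        raise ValueError("maternal must name one of the two merging lineages")
                if ev.kind == "te_burst" and ev.params["family_id"] not in self.library:
                    raise ValueError(f"unknown family {ev.params['family_id']}")
            seen.add(n.name)
        tips = {n.name for n in self.tips()}
        if set(self.clade_map) != tips:
            raise ValueError("clade_map must cover exactly the tip species")
        for sp in tips:
            if sp not in self.species_params:
                raise ValueError(f"missing species_params for {sp}")

    # -- maternal bookkeeping oracle used by property tests ------------------
    def expected_plastome_lineage(self, tip_name: str) -> str:
        """Follow maternal parents up the event list, independently of simulation."""
        idx = self._index()
        name = tip_name
        while True:
            node = idx[name]
            lineage = None
            for ev in reversed(node.events):
                if ev.kind == "establish":
                    lineage = ev.params["label"]
                    break
                if ev.kind == "hybridization":
                    maternal = ev.params["maternal"]
                    if maternal != node.name:
                        lineage = self.expected_plastome_lineage(maternal)
                        break
                    # maternal is this lineage: keep walking above this event
            if lineage is not None:
                return lineage
            if node.parent is None:
                return node.name
            name = node.parent

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "block_size": self.block_size,
            "insert_size": self.insert_size,
            "plastome_length": self.plastome_length,
            "background_length": self.background_length,
            "intra_family_divergence": self.intra_family_divergence,
            "clades": list(self.clades),
            "clade_map": dict(self.clade_map),
            "species_params": {k: dict(v) for k, v in self.species_params.items()},
            "library": [
                {
                    "family_id": f.family_id,
                    "superfamily": f.superfamily,
                    "origin_genome": f.origin_genome,
                    "consensus": seq_to_str(f.consensus),
                }
                for f in self.library
            ],
            "nodes": [
                {
                    "name": n.name,
                    "parent": n.parent,
                    "branch_length": n.branch_length,
                    "tip": n.tip,
                    "events": [{"kind": e.kind, "params": dict(e.params)} for e in n.events],
                }
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        lib = RepeatLibrary([
            TEFamily(f["family_id"], f["superfamily"], str_to_seq(f["consensus"]),
                     f["origin_genome"])
            for f in d["library"]
        ])
        nodes = [
            LineageNode(n["name"], n["parent"], n["branch_length"],
                        [Event(e["kind"], dict(e["params"])) for e in n.get("events", [])],
                        tip=n.get("tip", False))
            for n in d["nodes"]
        ]
        sc = cls(
            nodes=nodes,
            library=lib,
            clade_map=dict(d["clade_map"]),
            species_params={k: dict(v) for k, v in d["species_params"].items()},
            block_size=d.get("block_size", 50_000),
            insert_size=d.get("insert_size", 300),
            plastome_length=d.get("plastome_length", 20_000),
            background_length=d.get("background_length", 2_000_000),
            intra_family_divergence=d.get("intra_family_divergence", 0.05),
            clades=tuple(d.get("clades", ("Olyreae", "Arundinarieae", "NWB", "PWB"))),
        )
        sc.validate()
        return sc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# genome operations
# ---------------------------------------------------------------------------

def hybridize(parent_a: GenomeState, parent_b: GenomeState, maternal: str) -> GenomeState:
    """Merge two genomes (allopolyploidy): blocks concatenate, ploidies add,
    plastome follows the maternal parent."""
    if maternal == parent_a.label:
        mat, pat = parent_a, parent_b
    elif maternal == parent_b.label:
        mat, pat = parent_b, parent_a
    else:
        raise ValueError(f"maternal label {maternal!r} matches neither parent")
    contrib = dict(mat.ploidy_contrib)
    for k, v in pat.ploidy_contrib.items():
        contrib[k] = contrib.get(k, 0) + v
    return GenomeState(
        label=mat.label + pat.label,
        blocks=[b.clone() for b in mat.blocks] + [b.clone() for b in pat.blocks],
        plastome=mat.plastome.copy(),
        plastome_lineage=mat.plastome_lineage,
        ploidy_contrib=contrib,
    )


def fractionate(g: GenomeState, removed_parent: str, f: float, seed) -> GenomeState:
    """Biased fractionation: delete each block of ``removed_parent`` origin
    independently with probability ``f``.  TE copies residing in retained
    blocks are untouched (the survival mechanism for post-hybridization
    insertions); if every removed-parent block is lost, the ploidy that parent
    contributed is subtracted (diploidization)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must be in [0,1]")
    labels = {b.parent_label for b in g.blocks}
    if removed_parent not in labels:
        raise ValueError(f"no blocks with parent label {removed_parent!r}")
    rng = _as_rng(seed)
    out_blocks = []
    for b in g.blocks:
        if b.parent_label == removed_parent and rng.random() < f:
            continue
        out_blocks.append(b.clone())
    contrib = dict(g.ploidy_contrib)
    if all(b.parent_label != removed_parent for b in out_blocks):
        contrib.pop(removed_parent, None)
    return GenomeState(g.label, out_blocks, g.plastome.copy(), g.plastome_lineage, contrib)


def _insert_into_block(block: SubgenomeBlock,
                       items: list[tuple[int, str, np.ndarray, bool]]) -> None:
    """Insert TE copies into one block.  Positions falling inside an existing
    copy are snapped to that copy's end so copy intervals never overlap."""
    snapped = []
    for pos, fid, seq, flag in items:
        for _, s, e, _ in block.copies:
            if s < pos < e:
                pos = e
                break
        snapped.append((pos, fid, seq, flag))
    snapped.sort(key=lambda t: t[0])
    positions = [t[0] for t in snapped]
    segs = np.split(block.seq, positions)
    parts = [segs[0]]
    new_copies = []
    shift = 0
    for (pos, fid, seq, flag), nxt in zip(snapped, segs[1:]):
        new_copies.append((fid, pos + shift, pos + shift + len(seq), flag))
        parts.append(seq)
        parts.append(nxt)
        shift += len(seq)
    block.seq = np.concatenate(parts) if len(parts) > 1 else parts[0]
    adjusted = []
    for fid, s, e, flag in block.copies:
        sh = sum(len(t[2]) for t in snapped if t[0] <= s)
        adjusted.append((fid, s + sh, e + sh, flag))
    block.copies = sorted(adjusted + new_copies, key=lambda c: c[1])


def te_burst(g: GenomeState, library: RepeatLibrary, family_id: str, n_copies: int,
             post_hybrid: bool, seed, intra_divergence: float = 0.05,
             min_spacing: int = 120) -> GenomeState:
    """Insert ``n_copies`` mutated copies of a family consensus at uniform-random
    genomic positions (any subgenome), flagged with ``post_hybrid``.

    Insertion sites keep at least ``min_spacing`` bp away from existing copies
    of other bursts: nested and tandem TE structures are out of the simulator's
    scope, and read-length spacers prevent junction-spanning reads from
    chaining unrelated families into one cluster.
    """
    if family_id not in library:
        raise ValueError(f"unknown family {family_id!r}")
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    out = g.clone()
    if n_copies == 0:
        return out
    rng = _as_rng(seed)
    consensus = library[family_id].consensus
    lengths = np.array([len(b.seq) for b in out.blocks], dtype=float)
    p = lengths / lengths.sum()
    blocked: dict[int, list[tuple[int, int]]] = {}
    per_block: dict[int, list] = {}
    for _ in range(n_copies):
        placed = False
        for _try in range(30):
            bi = int(rng.choice(len(out.blocks), p=p))
            pos = int(rng.integers(0, len(out.blocks[bi].seq) + 1))
            if bi not in blocked:
                blocked[bi] = [(max(0, s - min_spacing), e + min_spacing)
                               for _, s, e, _ in out.blocks[bi].copies]
            if any(lo <= pos <= hi for lo, hi in blocked[bi]):
                continue
            placed = True
            break
        if not placed:  # genome too dense near existing copies; drop this copy
            continue
        copy_seq = mutate_sequence(consensus, intra_divergence, rng)
        per_block.setdefault(bi, []).append((pos, family_id, copy_seq, post_hybrid))
    for bi, items in per_block.items():
        _insert_into_block(out.blocks[bi], items)
    return out


def _establish(g: GenomeState, library: RepeatLibrary, label: str,
               ancestral_copies: dict[str, int], rng, intra_div: float) -> GenomeState:
    """Found an ancestral diploid genome: relabel all blocks, reset ploidy to 2X,
    set the plastome lineage, and seed the mobilome with ancestral TE copies."""
    out = g.clone()
    out.label = label
    out.plastome_lineage = label
    out.ploidy_contrib = {label: 2}
    for b in out.blocks:
        b.parent_label = label
    for fid, n in ancestral_copies.items():
        out = te_burst(out, library, fid, n, post_hybrid=False, seed=rng,
                       intra_divergence=intra_div)
    return out


def _inherit(parent: GenomeState, d: float, rng) -> GenomeState:
    """Evolve a genome along a branch: substitutions only (positional homology
    of plastomes is preserved so simulated plastomes stay aligned)."""
    child = parent.clone()
    if d > 0:
        for b in child.blocks:
            b.seq = mutate_sequence(b.seq, d, rng)
        child.plastome = mutate_sequence(child.plastome, d, rng)
    return child


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def sample_reads(g: GenomeState, spec: ReadSamplingSpec, species_id: str,
                 clade: str = "") -> ReadSet:
    """Sample N uniform reads of length L (paired: mates from opposite strands of
    an insert); label each read by majority-overlap TE copy or "background"."""
    L = spec.L
    seq_parts, cstarts, cends, cfams, blabels, bbounds = [], [], [], [], [], [0]
    offset = 0
    for b in g.blocks:
        seq_parts.append(b.seq)
        for fid, s, e, _ in b.copies:
            cstarts.append(s + offset)
            cends.append(e + offset)
            cfams.append(fid)
        offset += len(b.seq)
        blabels.append(b.parent_label)
        bbounds.append(offset)
    genome = np.concatenate(seq_parts) if seq_parts else np.empty(0, np.uint8)
    G = len(genome)
    if L > G:
        raise ValueError("read length exceeds genome length")
    cstarts = np.asarray(cstarts, dtype=np.int64)
    cends = np.asarray(cends, dtype=np.int64)
    bbounds = np.asarray(bbounds, dtype=np.int64)
    rng = _as_rng(spec.seed)

    def label_positions(starts: np.ndarray) -> tuple[list[str], list[str]]:
        fams: list[str] = []
        origins: list[str] = []
        if len(cstarts):
            hi = np.searchsorted(cstarts, starts + L)  # first copy starting at/after read end
        else:
            hi = np.zeros(len(starts), dtype=np.int64)
        block_idx = np.clip(np.searchsorted(bbounds, starts, side="right") - 1,
                            0, len(blabels) - 1)
        for s, h, bi in zip(starts, hi, block_idx):
            best_fid, best_ov = None, 0
            for j in (h - 1, h - 2):  # copies are >= 2x read length apart at most twice
                if 0 <= j < len(cstarts):
                    ov = min(cends[j], s + L) - max(cstarts[j], s)
                    if ov > best_ov:
                        best_ov, best_fid = ov, cfams[j]
            if best_fid is not None and best_ov > L / 2:
                fams.append(best_fid)
                origins.append(best_fid.split("_", 1)[0])
            else:
                fams.append("background")
                origins.append(blabels[bi])
        return fams, origins

    read_ids: list[str] = []
    seqs: list[str] = []
    mates_l: list[int] = []
    fams_l: list[str] = []
    orgs_l: list[str] = []
    if spec.paired:
        insert = min(spec.insert, G)
        n_pairs = spec.N // 2
        starts = rng.integers(0, G - insert + 1, size=n_pairs)
        flips = rng.random(n_pairs) < 0.5
        s2 = starts + insert - L
        f1, o1 = label_positions(starts)
        f2, o2 = label_positions(s2)
        for i in range(n_pairs):
            a = genome[starts[i]:starts[i] + L]
            b = revcomp(genome[s2[i]:s2[i] + L])
            if flips[i]:
                a, b = b, a
                fa, fb, oa, ob = f2[i], f1[i], o2[i], o1[i]
            else:
                fa, fb, oa, ob = f1[i], f2[i], o1[i], o2[i]
            base = f"{species_id}_{i:07d}"
            read_ids.append(base + "/1")
            seqs.append(seq_to_str(a))
            mates_l.append(1)
            fams_l.append(fa)
            orgs_l.append(oa)
            read_ids.append(base + "/2")
            seqs.append(seq_to_str(b))
            mates_l.append(2)
            fams_l.append(fb)
            orgs_l.append(ob)
    else:
        starts = rng.integers(0, G - L + 1, size=spec.N)
        strands = rng.random(spec.N) < 0.5
        f1, o1 = label_positions(starts)
        for i in range(spec.N):
            a = genome[starts[i]:starts[i] + L]
            if strands[i]:
                a = revcomp(a)
            read_ids.append(f"{species_id}_{i:07d}")
            seqs.append(seq_to_str(a))
            mates_l.append(1)
            fams_l.append(f1[i])
            orgs_l.append(o1[i])
    return ReadSet(species_id, clade, spec, read_ids, seqs,
                   np.asarray(mates_l, dtype=np.int8), fams_l, orgs_l)


# ---------------------------------------------------------------------------
# the tree walk
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    scenario: Scenario
    genomes: dict[str, GenomeState]        # tip species -> genome
    reads: dict[str, ReadSet]              # tip species -> reads
    plastomes: dict[str, np.ndarray]       # tip species -> plastome (aligned)
    library: RepeatLibrary

    def truth_table(self):
        import pandas as pd

        frames = []
        for sp, rs in self.reads.items():
            frames.append(pd.DataFrame({
                "read_id": rs.read_ids,
                "species": sp,
                "clade": rs.clade,
                "family_id": rs.family_ids,
                "origin_genome": rs.origins,
            }))
        return pd.concat(frames, ignore_index=True)

    def write_outputs(self, outdir, write_reads: bool = True) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "plastomes.fasta"), "w") as fh:
            for sp in sorted(self.plastomes):
                fh.write(f">{sp}\n{seq_to_str(self.plastomes[sp])}\n")
        self.library.write_fasta(os.path.join(outdir, "repeat_library.fasta"))
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            first = True
            for sp in sorted(self.reads):
                self.reads[sp].write_truth(fh, header=first)
                first = False
        if write_reads:
            with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
                for sp in sorted(self.reads):
                    self.reads[sp].write_fastq(fh)
            with open(os.path.join(outdir, "genomes.fasta"), "w") as fh:
                for sp in sorted(self.genomes):
                    g = self.genomes[sp]
                    for i, b in enumerate(g.blocks):
                        fh.write(f">{sp}_block{i:04d} parent={b.parent_label}\n")
                        fh.write(seq_to_str(b.seq) + "\n")


def _apply_events(g: GenomeState, node: LineageNode, genomes: dict[str, GenomeState],
                  scenario: Scenario, master_seed: int) -> GenomeState:
    for i, ev in enumerate(node.events):
        rng = rng_for(master_seed, node.name, f"ev{i}")
        if ev.kind == "divergence":
            continue
        if ev.kind == "establish":
            g = _establish(g, scenario.library, ev.params["label"],
                           ev.params.get("ancestral_copies", {}), rng,
                           scenario.intra_family_divergence)
        elif ev.kind == "hybridization":
            partner = genomes[ev.params["partner"]]
            maternal = ev.params["maternal"]
            mat_label = partner.label if maternal == ev.params["partner"] else g.label
            g = hybridize(g, partner, mat_label)
        elif ev.kind == "fractionation":
            g = fractionate(g, ev.params["removed_parent"], ev.params["f"], rng)
        elif ev.kind == "te_burst":
            g = te_burst(g, scenario.library, ev.params["family_id"],
                         ev.params["n_copies"], ev.params.get("post_hybrid", False),
                         rng, scenario.intra_family_divergence)
    return g


def simulate(scenario: Scenario, master_seed: int) -> SimulationResult:
    """Walk the lineage tree root-to-tips applying events, then sample reads per tip.

    Fully reproducible from ``master_seed``: every mutation, insertion and
    sampling stream is derived from (master_seed, node/species name, step).
    """
    scenario.validate()
    genomes: dict[str, GenomeState] = {}
    for node in scenario.nodes:
        if node.parent is None:
            rng = rng_for(master_seed, node.name, "found")
            g = GenomeState(
                label=node.name,
                blocks=[
                    SubgenomeBlock(node.name,
                                   random_seq(scenario.block_size, rng))
                    for _ in range(max(1, scenario.background_length // scenario.block_size))
                ],
                plastome=random_seq(scenario.plastome_length, rng),
                plastome_lineage=node.name,
                ploidy_contrib={node.name: 2},
            )
        else:
            rng = rng_for(master_seed, node.name, "branch")
            g = _inherit(genomes[node.parent], node.branch_length, rng)
        g = _apply_events(g, node, genomes, scenario, master_seed)
        genomes[node.name] = g

    tip_genomes: dict[str, GenomeState] = {}
    reads: dict[str, ReadSet] = {}
    plastomes: dict[str, np.ndarray] = {}
    for node in scenario.tips():
        sp = node.name
        g = genomes[sp]
        tip_genomes[sp] = g
        plastomes[sp] = g.plastome
        params = scenario.species_params[sp]
        seed = int(rng_for(master_seed, sp, "reads").integers(0, 2**31 - 1))
        spec = ReadSamplingSpec.from_coverage(
            L=int(params.get("read_length", 100)),
            C=float(params["coverage"]),
            G=g.total_length,
            paired=bool(params.get("paired", True)),
            insert=scenario.insert_size,
            seed=seed,
        )
        reads[sp] = sample_reads(g, spec, sp, clade=scenario.clade_map[sp])
    return SimulationResult(scenario, tip_genomes, reads, plastomes, scenario.library)


# ---------------------------------------------------------------------------
# the default (bamboo-like) scenario and controls
# ---------------------------------------------------------------------------

_SF_PLAN = [("Gypsy", 12, (400, 800)), ("Copia", 8, (350, 700)),
            ("DNA", 6, (300, 600)), ("simple", 3, (200, 300)),
            ("other", 1, (300, 500))]

# slots of the 30-family mobilome that belong to the slow-evolving set shared
# across ancestral genomes (3 Gypsy, 2 Copia, 2 DNA, 1 simple)
_SHARED_SLOTS = (0, 1, 2, 12, 13, 20, 21, 26)


def _solve_branch_div(pairwise: float) -> float:
    # two versions mutated independently by d from a common base differ with
    # probability 1 - [(1-d)^2 + d^2/3]; invert for d
    a, b, c = 4.0 / 3.0, -2.0, pairwise
    return (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)


def _make_library(rng: np.random.Generator, genome_labels: list[str],
                  n_per_genome: int = 30, inter_divergence: float = 0.45):
    """Per-ancestral-genome mobilomes of ``n_per_genome`` families each.

    A small conserved subset ("B" families, slow-evolving, retained from the
    common ancestor) is shared identically by all ancestral genomes; the rest
    are genome-specific versions diverged by ~``inter_divergence`` pairwise, so
    homologous families from different ancestors never link at the 80% read
    identity threshold even through locally conserved alignment windows.

    Returns (library, shared_ids, specific_ids: label -> ids).
    """
    plan: list[tuple[str, int]] = []
    for sf, n, lr in _SF_PLAN:
        plan += [(sf, int(rng.integers(lr[0], lr[1] + 1))) for _ in range(n)]
    plan = plan[:n_per_genome]
    shared_slots = set(_SHARED_SLOTS) if len(genome_labels) > 1 else set()
    d_branch = _solve_branch_div(inter_divergence)
    fams: list[TEFamily] = []
    shared_ids: list[str] = []
    specific: dict[str, list[str]] = {lab: [] for lab in genome_labels}
    for i, (sf, ln) in enumerate(plan):
        base = random_seq(ln, rng)
        if i in shared_slots:
            fid = f"B_{i:02d}"
            fams.append(TEFamily(fid, sf, base, "B"))
            shared_ids.append(fid)
        else:
            for label in genome_labels:
                fid = f"{label}_{i:02d}"
                fams.append(TEFamily(fid, sf, mutate_sequence(base, d_branch, rng), label))
                specific[label].append(fid)
    return RepeatLibrary(fams), shared_ids, specific


def _copies(rng, fids, lo, hi):
    return {fid: int(rng.integers(lo, hi + 1)) for fid in fids}


def _bursts(rng, fids, lo, hi, post_hybrid):
    return [Event("te_burst", {"family_id": fid, "n_copies": int(rng.integers(lo, hi + 1)),
                               "post_hybrid": post_hybrid}) for fid in fids]


def default_scenario(species_per_clade: int = 4, size_scale: float = 1.0) -> Scenario:
    """The encoded four-clade hybridization/fractionation model.

    Diploid ancestors: H (herbaceous), C and D (woody).  A maternal-H x
    paternal-C hybridization with complete loss of H blocks founds the tropical
    woody lineage, which splits into NWB and PWB; the NWB branch receives three
    further rounds of herbaceous hybridization (with post-hybridization H-family
    transposition into retained C blocks); the PWB branch undergoes a second
    polyploidization with D and partial fractionation against D; Arundinarieae
    arises from a C x D hybridization with a D (non-H) plastome.  Deterministic:
    all free parameters are drawn from a fixed internal stream.
    """
    rng = np.random.default_rng(709)
    lib, shared, specific = _make_library(rng, ["H", "C", "D"])
    hf, cf, df = specific["H"], specific["C"], specific["D"]
    # "active" family subsets (recently amplifying families)
    HA = [str(x) for x in rng.permutation(hf)[:15]]   # active H families
    S1 = HA[:10]                            # re-enter NWB at hybridizations 1-3
    S0 = S1[:4]                             # faint survivors of the founding H x C cross
    OX = HA[10:15]                          # H actives that never re-entered the woody clades
    cperm = [str(x) for x in rng.permutation(cf)]
    CA_T = cperm[:3]                        # mildly amplified in the tropical woody ancestor
    CA_N, CA_P, CA_A = cperm[3:8], cperm[8:13], cperm[13:18]  # lineage-specific
    DA = [str(x) for x in rng.permutation(df)[:8]]    # active D families
    BA = shared[:4]                         # conserved families, recently active everywhere

    anc = lambda fids: {**_copies(rng, fids, 4, 10), **_copies(rng, shared, 8, 14)}

    nodes: list[LineageNode] = [
        LineageNode("ROOT", None, 0.0),
        LineageNode("Out1", "ROOT", 0.10,
                    [Event("establish", {"label": "O", "ancestral_copies": {}})], tip=True),
        LineageNode("BAMB", "ROOT", 0.03, [Event("divergence")]),
        LineageNode("H_ANC", "BAMB", 0.05,
                    [Event("establish", {"label": "H", "ancestral_copies": anc(hf)})]),
        LineageNode("OLY_ANC", "H_ANC", 0.012,
                    _bursts(rng, S1, 30, 48, False) + _bursts(rng, OX, 110, 160, False)
                    + _bursts(rng, BA, 15, 28, False)),
        LineageNode("H_HYB", "H_ANC", 0.008),
        LineageNode("H_NEO1", "OLY_ANC", 0.004),
        LineageNode("H_NEO2", "OLY_ANC", 0.006),
        LineageNode("OLYRIN", "OLY_ANC", 0.008),
        LineageNode("WANC", "BAMB", 0.02, [Event("divergence")]),
        LineageNode("C_ANC", "WANC", 0.03,
                    [Event("establish", {"label": "C", "ancestral_copies": anc(cf)})]),
        LineageNode("D_ANC", "WANC", 0.03,
                    [Event("establish", {"label": "D", "ancestral_copies": anc(df)})]),
        LineageNode("D_PWB", "D_ANC", 0.008),
        LineageNode("D_ARU", "D_ANC", 0.006),
        # founding hybridization: maternal herbaceous x paternal woody,
        # then complete biased fractionation against H (genome dominance of C)
        LineageNode("TROP", "C_ANC", 0.008,
                    [Event("hybridization", {"partner": "H_HYB", "maternal": "H_HYB"}),
                     Event("fractionation", {"removed_parent": "H", "f": 1.0})]
                    + _bursts(rng, S0, 12, 20, True)
                    + _bursts(rng, CA_T, 12, 20, False)),
        # NWB: hybridization 1 (tropical woody x Neotropical herbaceous)
        LineageNode("NWB_ANC", "TROP", 0.010,
                    [Event("hybridization", {"partner": "H_NEO1", "maternal": "NWB_ANC"}),
                     Event("fractionation", {"removed_parent": "H", "f": 1.0})]
                    + _bursts(rng, S1, 34, 54, True)
                    + _bursts(rng, CA_N, 100, 150, False)
                    + _bursts(rng, BA, 15, 28, False)),
        LineageNode("CHU_ANC", "NWB_ANC", 0.010),
        # Arthrostylidiinae+Guaduinae: hybridizations 2 and 3 with the herbaceous lineage
        LineageNode("AG_ANC", "NWB_ANC", 0.006,
                    [Event("hybridization", {"partner": "H_NEO2", "maternal": "AG_ANC"}),
                     Event("fractionation", {"removed_parent": "H", "f": 1.0})]
                    + _bursts(rng, S1, 18, 32, True)
                    + [Event("hybridization", {"partner": "OLYRIN", "maternal": "AG_ANC"}),
                       Event("fractionation", {"removed_parent": "H", "f": 0.85})]
                    + _bursts(rng, S1, 15, 26, True)),
        # PWB: second polyploidization (with D), fractionation favouring C
        LineageNode("PWB_ANC", "TROP", 0.012,
                    [Event("hybridization", {"partner": "D_PWB", "maternal": "PWB_ANC"}),
                     Event("fractionation", {"removed_parent": "D", "f": 0.5})]
                    + _bursts(rng, DA, 60, 90, True)
                    + _bursts(rng, CA_P, 130, 190, False)
                    + _bursts(rng, BA, 15, 28, False)),
        # Arundinarieae: C x D allotetraploid, maternal D (non-H plastome)
        LineageNode("ARU_ANC", "C_ANC", 0.014,
                    [Event("hybridization", {"partner": "D_ARU", "maternal": "D_ARU"})]
                    + _bursts(rng, DA, 110, 160, True)
                    + _bursts(rng, CA_A, 170, 250, False)
                    + _bursts(rng, BA, 15, 28, False)),
    ]

    coverages = {
        "Olyreae": [1.1, 1.3, 2.0, 5.1, 1.0, 1.4],
        "NWB": [1.0, 1.3, 1.6, 2.2, 1.1, 1.2],
        "PWB": [0.8, 1.1, 1.3, 1.7, 1.0, 1.2],
        "Arundinarieae": [0.5, 0.9, 1.2, 1.5, 1.0, 1.1],
    }
    clade_map: dict[str, str] = {"Out1": "Outgroup"}
    species_params: dict[str, dict] = {"Out1": {"coverage": 1.0, "read_length": 100}}
    n = max(2, min(6, species_per_clade))
    half = n // 2

    def add_tips(prefix, clade, parents, pool):
        for i in range(n):
            sp = f"{prefix}{i + 1}"
            parent = parents[0] if i < half else parents[-1]
            tip_f = [str(x) for x in rng.permutation(pool)[:2]]
            nodes.append(LineageNode(sp, parent, float(rng.uniform(0.008, 0.012)),
                                     _bursts(rng, tip_f, 10, 20, False), tip=True))
            clade_map[sp] = clade
            species_params[sp] = {"coverage": coverages[clade][i], "read_length": 100}

    add_tips("Oly", "Olyreae", ["OLY_ANC"], HA)
    add_tips("Nwb", "NWB", ["CHU_ANC", "AG_ANC"], S1 + CA_N)
    add_tips("Pwb", "PWB", ["PWB_ANC"], DA + CA_P)
    add_tips("Aru", "Arundinarieae", ["ARU_ANC"], DA + CA_A)

    sc = Scenario(
        nodes=nodes,
        library=lib,
        clade_map=clade_map,
        species_params=species_params,
        background_length=int(2_400_000 * size_scale),
        block_size=max(10_000, int(50_000 * size_scale)),
    )
    sc.validate()
    return sc


def null_scenario(species_per_clade: int = 3, size_scale: float = 1.0) -> Scenario:
    """Control without hybridization: four clades diverge vertically, plastomes
    track the same tree as the nuclear genomes, so the plastid and repeat signals
    are concordant."""
    rng = np.random.default_rng(1311)
    lib, _, specific = _make_library(rng, ["A"])
    af = specific["A"]
    perm = [str(x) for x in rng.permutation(af)]
    F1, F2 = perm[:7], perm[7:14]            # shared by (Oly,NWB) / (Aru,PWB)
    CS = {cl: perm[14 + 4 * i:18 + 4 * i] for i, cl in
          enumerate(["Olyreae", "NWB", "Arundinarieae", "PWB"])}
    nodes = [
        LineageNode("ROOT", None, 0.0,
                    [Event("establish", {"label": "A",
                                         "ancestral_copies": _copies(rng, af, 4, 10)})]),
        LineageNode("Out1", "ROOT", 0.10, tip=True),
        LineageNode("CORE", "ROOT", 0.02),
        LineageNode("N1", "CORE", 0.02, _bursts(rng, F1, 50, 80, False)),
        LineageNode("N2", "CORE", 0.02, _bursts(rng, F2, 50, 80, False)),
    ]
    clade_map = {"Out1": "Outgroup"}
    species_params: dict[str, dict] = {"Out1": {"coverage": 1.0, "read_length": 100}}
    n = max(2, min(6, species_per_clade))
    for clade, parent, prefix in [("Olyreae", "N1", "Oly"), ("NWB", "N1", "Nwb"),
                                  ("Arundinarieae", "N2", "Aru"), ("PWB", "N2", "Pwb")]:
        anc_name = f"{prefix.upper()}_ANC"
        nodes.append(LineageNode(anc_name, parent, 0.015,
                                 _bursts(rng, CS[clade], 80, 120, False)))
        for i in range(n):
            sp = f"{prefix}{i + 1}"
            nodes.append(LineageNode(sp, anc_name, float(rng.uniform(0.008, 0.012)),
                                     tip=True))
            clade_map[sp] = clade
            species_params[sp] = {"coverage": 1.0, "read_length": 100}
    sc = Scenario(nodes=nodes, library=lib, clade_map=clade_map,
                  species_params=species_params,
                  background_length=int(2_400_000 * size_scale),
                  block_size=max(10_000, int(50_000 * size_scale)))
    sc.validate()
    return sc


def without_fractionation(scenario: Scenario) -> Scenario:
    """Copy of a scenario with every fractionation probability set to 0."""
    nodes = []
    for n in scenario.nodes:
        evs = [Event(e.kind, {**e.params, "f": 0.0}) if e.kind == "fractionation"
               else Event(e.kind, dict(e.params)) for e in n.events]
        nodes.append(LineageNode(n.name, n.parent, n.branch_length, evs, tip=n.tip))
    return replace(scenario, nodes=nodes)
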