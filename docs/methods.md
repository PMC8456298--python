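# Methods

## Model overview

`ssapipe` treats a genome as an ordered list of *subgenome blocks*, each tagged
with the ancestral diploid genome it descends from, carrying non-overlapping TE
copy annotations `(family, start, end, inserted_after_hybridization)`, plus a
plastome sequence and a maternal-lineage label. Evolution is driven by four
event types applied along a rooted lineage tree:

- **divergence** — every branch of length *d* (expected substitutions per
  site) mutates nuclear blocks and plastome i.i.d.: each site is substituted
  with probability *d* (capped at 0.75) to one of the three other bases.
  There are no indels, so plastomes of all tips remain positionally aligned
  and nuclear homology is exact; distance methods can be applied without a
  multiple-alignment step.
- **hybridization** — blocks of the two parents concatenate, per-ancestor
  ploidy contributions add, and the plastome (sequence and lineage label) is
  copied from the maternal parent. This is the allopolyploidy step.
- **fractionation** — each block of the targeted parental genome is deleted
  independently with probability *f* ∈ [0, 1] (biased fractionation / genome
  dominance). TE copies inside retained blocks are untouched — this is the
  mechanism by which donor-genome TEs survive the loss of the donor's own
  chromosome segments. If the last block of a parent disappears, the ploidy
  it contributed is subtracted (diploidization).
- **te_burst** — *n* copies of a family consensus, each independently mutated
  at the intra-family divergence (default 0.05), insert at uniform-random
  genomic positions across all subgenomes, flagged with whether they
  post-date a hybridization. Insertion sites keep ≥ 120 bp (about one read
  length) away from existing copies: nested and tandem TE structures are out
  of scope, and read-length spacers prevent junction-spanning reads from
  spuriously chaining unrelated families during clustering.

Read sampling follows C = L·N/G: N = ⌈C·G/L⌉ reads (rounded up to full pairs),
drawn uniformly with random strand; paired mode emits mates from opposite
strands of a 300 bp insert. Each read's truth label is the TE copy covering
the majority (> L/2) of the read, else `background` with the block's ancestral
origin. All randomness derives from a single master seed via stable
(CRC32-keyed) per-node, per-event and per-species streams, so simulations are
bit-reproducible.

## The default scenario

Three ancestral diploid genomes — herbaceous **H** and woody **C** and **D** —
diverge from a common background (2.4 Mb per haploid complement, 50 kb blocks,
20 kb plastome). Each carries a mobilome of 30 families (superfamily mix
12 Gypsy / 8 Copia / 6 DNA / 3 simple / 1 other, consensus lengths 200–800 bp);
8 of the 30 are a slow-evolving set shared identically across the three
genomes ("retained from the common ancestor"), the other 22 are genome-specific
versions diverged ~0.45 pairwise so that homologous families from different
ancestors can never link at the 80% read-identity threshold. Genome sizes are
scaled down ~10³ from real bamboo (tips span 2.9–6 Mb standing in for ~3–6 Gb)
so the whole study runs on a desk; element lengths and copy numbers are scaled
with them.

The encoded history:

- **Tropical woody origin** — maternal H × paternal C, complete fractionation
  of the H blocks (f = 1, diploidization back to 2X), with a small
  post-hybridization burst of four active H families into the retained C
  blocks (the survival trace that later appears as clusters shared by
  Olyreae, NWB *and* PWB).
- **NWB** — three further hybridization episodes with the herbaceous lineage
  (the third only on the Arthrostylidiinae+Guaduinae branch, whose last
  fractionation is partial, f = 0.85, leaving a residual H subgenome and 4X
  tips), each re-injecting the ten "active" H families into the retained
  blocks. Chusqueinae-like tips stay 2X.
- **PWB** — a second polyploidization with D under C dominance
  (f = 0.5 against D, tips 4X), plus bursts of the active D families.
- **Arundinarieae** — C × D allotetraploid with maternal D, hence the only
  clade whose plastome does not descend from H.
- Every clade ancestor additionally amplifies its own subset of C families
  and the four "recently active" shared families; tips get two small private
  bursts each. Lineage-specific amplification deliberately dominates the deep
  shared C content — the repeat similarity signal is carried by recently
  amplified families, mirroring the observation that the most abundant
  clusters are the most recently active ones.

Per-species coverages span 0.5–5.1X (median ≈ 1.2) with 100 bp paired reads —
the regime of a single low-depth sequencing lane. The tree has 4 species per
clade plus one outgroup tip used only to root the plastome tree.

Copy numbers per burst were chosen once, at design time, with two aims: every
"signature" family group (shared H actives, Olyreae-exclusive H actives,
per-clade C amplifications, D actives, conserved-set actives) pools 40–100
reads at the default clustering depth so that the heavy-tail selection rule
(top clusters covering 50% of clustered reads) samples all of them; and the
background (single-copy) fraction stays below the read density at which
homologous loci would chain into spurious clusters (see below).

Two control scenarios ship with the package: `null` (four clades diverge
vertically with no hybridization — plastid and repeat signals must agree) and
`no_fractionation` (the default history with every *f* forced to 0 — the
herbaceous subgenome is then retained by both Bambuseae lineages and the
shared-cluster asymmetry collapses).

## Clustering

Identity between two reads is defined by the best local alignment
(match +1, mismatch −1, gap −2) over both strands: identity = matches /
alignment columns, with a minimum span of 55% of the shorter read. An edge
requires identity strictly above 0.80; clusters are connected components with
≥ 5 reads; cluster ids are assigned by decreasing size with ties broken by the
smallest member read id. Candidate pairs come from a shared canonical-k-mer
index (k = 15, ≥ 1 shared k-mer — at k = 15 a random collision between
unrelated 100 bp reads has probability ~7·10⁻⁶, so a single shared k-mer is
already strong evidence); every candidate is verified by alignment, so no edge
can violate the thresholds. The prefilter can only *miss* edges: pairs that
overlap near the 55% minimum at ~10% divergence sometimes share no intact
15-mer. A `brute_force` mode verifies all pairs and is used by the oracle
tests; in the pipeline's operating regime (well-covered families at ≤ 5% copy
divergence) the accelerated and exhaustive partitions coincide.

Superfamily classification assigns each read to the library consensus with the
highest shared-k-mer containment (k = 11, floor 0.15) and labels the cluster by
plurality vote, or `unknown` when fewer than half the reads hit anything.

The pipeline pools the first 1 000 reads of each species for clustering. This
cap plays the role of the fixed-size subsampling used by read-clustering
pipelines on real data, and it matters quantitatively at desk scale: genome
downscaling inflates per-locus coverage ~10³-fold relative to real low-depth
data, so without the cap, homologous *single-copy* loci across related species
reach the read density needed to form clusters of ≥ 5 reads, something that
essentially never happens at real scale. At the default cap the pooled
background start density (≈ 0.3X per homologous locus) keeps such clusters
rare, while repeat families (tens to hundreds of pooled copies) stay densely
connected.

## Repartition, correlation, trees

The abundance matrix holds raw counts (reads-per-million per species recorded
alongside). Top clusters are the shortest abundance-sorted prefix reaching the
requested fraction (default 0.5) of all clustered reads; ties break by cluster
id. A cluster is "present" in a clade if ≥ 1 species of the clade has ≥ 1 read
(both thresholds configurable); the Venn partition counts clusters per exact
presence pattern over the four clades.

Species correlation uses Pearson's r over log1p-transformed abundances of the
top clusters, with counts depth-normalized to the *median species total*
rather than per-million: Pearson is invariant to the per-species log-offset
for nonzero counts either way, but with clustered-read totals of order 10²,
per-million scaling lets a stray singleton read (log ≈ 9) rival a genuinely
abundant cluster (log ≈ 11) and drowns the clade structure in presence
flicker; on the natural count scale a singleton stays near zero. The
dendrogram is average-linkage agglomeration on d = 1 − r with species
pre-sorted by name for deterministic tie-breaking; Newick export places leaves
at half the merge height (ultrametric form). The grouping report flags, per
clade, whether its species form a contiguous subtree, and lists the clades
wholly contained in each of the root's two children.

Plastome trees: p-distance or JC69 (d = −(3/4)·ln(1 − 4p/3), rejected at
p ≥ 0.75) feeds standard neighbor joining (negative branch lengths clamped to
zero). Distance-based inference is sufficient here because the simulator
guarantees alignment-free positional homology; the package's claim is about
topological conflict, not substitution-model estimation. Nonparametric
bootstrap resamples alignment columns and reports per-split frequencies.
Monophyly is tested in the unrooted sense (a split separating exactly the
subset) or rooted on a named outgroup. The conflict metric collapses each
clade (if monophyletic in both trees) to a single leaf and reports the
Robinson–Foulds distance between the collapsed plastid tree and repeat
dendrogram; on four clade-leaves this is 0 (concordant) or 2 (conflicting).

## Verification scorecard

Simulated runs score themselves against the truth tables: the adjusted Rand
index between recovered clusters and truth families is computed over clustered
reads whose truth *is* a family; clustered background reads — homologous
single-copy loci correctly linked by the > 80% rule, a desk-scale coverage
effect — belong to no family and are counted separately
(`ari_including_background`, `background_reads_clustered` are also reported).
The scorecard further flags the grouping pattern ({Olyreae,NWB} and
{Arundinarieae,PWB} with four coherent blocks), plastid paraphyly of the woody
clades (Bambuseae sister to Olyreae with Arundinarieae outside), conservation
of Venn per-clade totals, and the asymmetry ordering of exclusive pairwise
shared-cluster counts.

## Problem sizes and determinism

Default study: 17 species, 2.9–6 Mb genomes, ~1 M simulated reads, 17 000
pooled for clustering; one full run takes ~20 s on one CPU. The test suite
executes the full pipeline for five master seeds plus the null control; the
acceptance script repeats that and adds 50 brute-force oracle read sets
(≤ 100 reads) and 100 random additive matrices (≤ 12 taxa) for
neighbor-joining recovery. Identical (configuration, seed) pairs produce
byte-identical reports and FASTQ.

## What the simulation does and does not show

The generator emulates: distinctive per-ancestor mobilomes with a conserved
shared core, maternal plastome inheritance through hybridization, survival of
donor-genome TEs via post-hybridization transposition into retained blocks,
subgenome-biased block loss with diploidization, species-level divergence, and
uniform low-coverage paired sampling. It does not emulate: indels or
rearrangements, TE structural features (LTRs, target-site duplications),
nested/tandem insertions, satellite arrays, selection, recombination,
horizontal transfer, sequencing error or quality variation, or chromosome-level
karyotypes. Passing tests therefore show that the analysis chain recovers the
designed repeat-sharing and cytonuclear signals under clean substitution-only
evolution at reduced scale — not that it is robust to assembly-free artifacts
of real sequencing data (chimeric reads, contamination, organellar carry-over),
which must be handled upstream.

## Known limitations

- Connected-component clustering is single-linkage: one spurious edge merges
  two families. The simulator's family divergences are chosen so this does
  not happen; real data would benefit from the (off-by-default) modularity
  splitting of chimeric clusters, which is not implemented here.
- The Venn presence rule (≥ 1 read in ≥ 1 species) is noise-sensitive at
  very low depth; the sensitivity thresholds are exposed but the defaults are
  deliberately the permissive ones.
- Bootstrap supports on the plastome tree are computed but not used by any
  decision rule; topology tests are deterministic given the seed.
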