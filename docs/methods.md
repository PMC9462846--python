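# Methods

This note documents the models, algorithms and numerical choices behind
`synpan`, and what the simulated-data validation does and does not show.

## Inputs and coordinate conventions

Gene models are reduced to intervals: internal bp coordinates are 0-based
half-open (GFF3 I/O converts from/to 1-based closed). All synteny
inference happens in **gene rank space**: `ord` is the 1-based rank of a
gene along its chromosome by start position (ties broken by end, then gene
id, so loading is deterministic). Chromosomes with fewer than `blk_size`
genes are removed before inference; a genome losing all chromosomes is a
fatal input error. For each genome pair the genome with more gene models
is treated as the query; reciprocal hit files are merged and duplicated
(query, target) rows keep the highest bitscore (strongest evidence), then
highest percent identity.

## Tandem arrays

Candidate arrays are orthogroups with more than one gene on a single
(genome, chromosome). Members are split wherever the rank gap between
adjacent genes exceeds `syn_buff`; this gap-splitting is exactly 1-D
density clustering (DBSCAN with eps = `syn_buff`, minPts = 1) and is
checked against an exhaustive-scan oracle in the tests. Clusters of ≥ 2
genes become arrays. The representative is the member closest to the
median rank; ties go to the longest peptide (when a peptide FASTA is
supplied) and then to the lexicographically smallest gene id. `arrayOrd`
re-ranks representatives per chromosome; non-representative members borrow
their representative's rank for all distance computations, so arrays act
as single loci downstream.

## Anchor candidacy and collinear chaining

Hits are annotated with rank positions, array representativeness,
orthogroup agreement (`isOg`) and score ranks: `scrRank` is the dense rank
of bitscore among hits sharing a gene (rank 1 = that gene's best hit;
equal bitscores share a rank). **Potential anchors** require both genes to
be representatives, `scrRank` within the per-gene hit caps (which default
to the opposite genome's ploidy), and — unless `only_og_anchors` is off —
a shared orthogroup.

Rank order is then condensed over the pair's full potential-anchor table
(dense rank of (chromosome, arrayOrd) per genome side). Condensing masks
PAV: an orthogroup missing in one genome leaves no gap. Condensing over
the whole table rather than per chromosome pair is deliberate: a sparse
set of incidental hits between two chromosomes must stay sparse, otherwise
it collapses onto a small dense grid and chains spuriously (measured as a
~4% anchor rate on shuffled-order data versus 0% with table-wide
condensing).

A **collinear chain** is a sequence of hits strictly increasing in x with
y strictly monotone (increasing = "+", decreasing = "−"), where
consecutive hits satisfy (Δx − 1) ≤ `n_gaps` and (|Δy| − 1) ≤ `n_gaps`.
Chain score is the hit count; the best chain is found by an O(n²) dynamic
program and chains are extracted greedily by descending score (ties: the
chain with smaller minimum x, then y, then "+" orientation; within the DP,
first-in-sort-order endpoints and predecessors make reconstruction
deterministic). Chains shorter than `blk_size` are discarded. On ≤ 12-hit
instances the DP's top score equals exhaustive search over all valid
chains (tested on hundreds of random instances).

## Blocks and regions

Per chromosome pair: (1) potential anchors within Chebyshev distance
`syn_buff` (in arrayOrd space) of any initial anchor are re-chained into
cleaned anchors; (2) cleaned anchors are clustered by DBSCAN (Euclidean,
eps = `syn_buff`, minPts = `blk_size`), dropping undersized clusters; (3)
chaining reruns inside each cluster, giving the final anchors; (4)
**regions** are a coarse DBSCAN pass (eps = `syn_buff`, minPts = 1, i.e.
connected components at that radius) and **blocks** split each chain at
re-ranked gaps > `blk_size` (fragments below `blk_size` merge into their
neighbor so blocks keep ≥ `blk_size` anchors); (5) where two blocks of one
region overlap on the query axis, overlap anchors are reassigned to the
block holding the longest consecutive run there, and a loser split into
disjoint remainders becomes separate blocks. DBSCAN inputs are pre-sorted
by (x, y) and labels renumbered by first occurrence, so clustering is
order-independent and deterministic.

Every hit within Chebyshev `syn_buff` of an anchor is flagged `inBuffer`
and inherits the nearest anchor's region id (ties to the lower region id).
Block and region bp coordinates are the bounding-anchor extrema. Blocks
are fine-grained fully collinear runs; regions average across minor
inversions — a micro-inversion yields one region containing blocks of
both orientations.

Distance metrics: Chebyshev for all "radius" tests in rank space (a square
buffer on both axes), Euclidean inside DBSCAN (the conventional metric).

## Self-synteny and the secondary (paralog) scan

A haploid genome's self-synteny is the identity map: one block per
chromosome, ids = chromosome ids. For ploidy p > 1, hits within
`self_mask_radius` (default 500 genes) of the identity diagonal are masked
— excluding large tandem neighborhoods — and the standard scan reruns
with p − 1 hits per gene to recover homeologous blocks.

With `n_secondary_hits` > 0, everything inside the primary syntenic buffer
is masked, score ranks are recomputed on the remaining hits, and the scan
reruns with the secondary parameter set (`blk_size_second`,
`n_gaps_second`, `syn_buff_second`) and **without** the orthogroup
requirement. This recovers WGD-derived paralogous regions when no
pre-duplication outgroup is available: paralog hits score lower than
ortholog hits, so the primary scan locks onto orthologs and the secondary
scan inherits the homeologs.

## Syntenic orthogroups

Syntenic orthogroups are connected components of the graph whose edges are
in-buffer, orthogroup-consistent hits pooled over all genome pairs;
non-representative tandem members are bookkept as array members of their
representative. For polyploids (`orthofinder_in_blk`, on by default iff
any ploidy > 1), orthogroups are first re-estimated inside each syntenic
region as connected components of the region-restricted reciprocal-best-
hit graph, and the synteny scan reruns once on the combined (global,
in-block) labels. This is a behavioral substitute for re-clustering
sequences within blocks: inside a region homologs are single copy, so RBH
resolves the homeolog columns that global orthogroups lump together. When
no orthogroup input is given at all, global orthogroups fall back to
RBH-graph components.

## Pan-genome annotation

The reference genome's array representatives form the positional backbone
(`arrayOrd` is the coordinate). For every other genome, anchors against
the reference are reduced to a 1:1 set (anchors sharing a rank on either
axis are dropped), split into clusters at rank jumps > 1, and used to
interpolate a reference rank for every representative: a gene at rank t
between flanking anchors (t₁→r₁, t₂→r₂) receives
r₁ + (t−t₁)(r₂−r₁)/(t₂−t₁) whenever the flanking gap is spannable
(≤ `syn_buff` on both axes); beyond terminal anchors the nearest anchor
extrapolates at unit slope in its cluster's orientation, up to `syn_buff`
away. Interpolating across small gaps (rather than extrapolating) is
essential: those gaps are exactly the PAV the pan-genome must mask, and
unit-slope extrapolation drifts whenever both genomes carry losses. A gene
keeps only its minimum-anchor-distance placements — a direct anchor beats
any interpolated position (a translocated gene follows its own block, not
the gap it left), while equally supported placements on homeologous
reference chromosomes are all retained.

Each syntenic orthogroup's member positions are split by reference
chromosome and at rank gaps > `syn_buff`; multi-cluster groups keep
clusters holding ≥ `prop_assign_thresh` (default 0.5) of positioned
members (largest cluster as fallback when none qualifies) and at most
`max_placements_per_ref_chr` (default 2) per chromosome, ranked by member
proportion, then size, then lower rank. An entry is placed at the median
member rank; its bp position is the nearest backbone gene's start.
Finalization appends: orthogroup members without a placed position
(`indirectSyn`), orthogroups with no position at all (null coordinates),
non-representative tandem members next to their representative
(`arrayMember`), optional non-syntenic orthologs from a user-supplied
ortholog list (`NSOrtho`; the pipeline itself performs no gene-tree
ortholog inference), and a backbone entry for every reference
representative not covered by any orthogroup — the reference defines the
coordinate system, and "absent everywhere else" is itself a PAV
observation. Genes with no syntenic evidence in any pair are reported as
unplaced rather than guessed. PAV/CNV matrices are entry × genome presence
and member counts.

## Simulator

`synpan.simulate` evolves a uniform ancestral gene order (`n_chrom` ×
`genes_per_chrom`; 3 kb genes with 2 kb spacing — only rank order matters
downstream) along a user-defined tree. Branch events: segment inversions
and translocations, per-gene tandem duplication (children inserted
adjacently, sharing the parent's ancestral id), per-gene loss, and WGD
(every chromosome duplicated with a `w` suffix; copy labels track the
duplication so ortholog vs homeolog relations are exact). Events apply
sequentially in a seeded random order and are logged with concrete
coordinates, so a log replays to the identical genome. Hit tables emit
bitscore ~ Normal(500, 50) for pairs sharing an ancestral gene, scaled by
`paralog_decay` (default 0.7) for cross-WGD pairs, plus ~5% spurious
random pairs with low scores (30–60); percent identity is a monotone
function of bitscore. One RNG stream per scenario makes every artifact
byte-reproducible.

What the simulator does **not** emulate: sequence evolution (bitscores are
drawn, not computed from alignments), rate variation along chromosomes,
segmental duplications other than WGD and tandem copies, assembly errors,
and annotation noise (missing or fused gene models). Passing validation
therefore demonstrates the pipeline's logic — collapsing, chaining,
clustering, interpolation, placement — under realistic rearrangement and
copy-number processes, not robustness to annotation quality.

## Validation experiments and measurement choices

`synpan.benchmarks` (driven by `scripts/acceptance.py` and the acceptance
tests) measures, at the default parameters and 2 × 500-gene genomes:

- **single-copy placement**: among genes with ≥ 1 orthogroup-consistent
  hit in a pair, the fraction whose in-buffer hits map to exactly one
  syntenic *region*. Region granularity is the operational form of the
  single-copy assumption (regions exist precisely to average across minor
  inversions); genes lost in the partner genome have nothing to be placed
  against and are excluded from the denominator.
- **anchor recall**: truth ortholog pairs are evaluated between tandem-
  array representatives, because collapsing is part of the method —
  non-representative members can never be anchors by construction. The
  ~1–2% shortfall is concentrated at rearrangement breakpoints, where
  residual collinear fragments shorter than `blk_size` are (by design) not
  called syntenic.
- **WGD**: primary-scan anchors are scored against truth ortholog vs
  homeolog labels; secondary-scan coverage is the fraction of truth
  homeolog representative pairs inside the secondary buffer.
- **interpolation**: 10% of reference genes are withheld and re-derived
  through the other genome; accuracy (± 1 rank) is assessed in
  rearrangement-free segments, identified from the simulator's event log
  with a two-gene flank margin.
- **PAV**: absent pan-genome cells against truth presence per ancestral
  gene; plus conservation checks (no gene in two entries; unplaced genes
  have no surviving partner anywhere).
- **nulls and oracles**: shuffled gene order must yield essentially zero
  anchors; the chaining DP must match exhaustive search; tandem-array
  recovery must be exact on tandem-only scenarios; two end-to-end runs
  must be byte-identical.

Problem sizes (three genomes of ~1000 genes; 100 tandem scenarios of 60
genes; 200 chaining instances of ≤ 12 hits) were chosen so the whole
validation completes in well under a minute per experiment while every
rate is estimated from at least ~100 events.

## Known limitations

- Collinearity is scored by hit count only; bitscore-weighted chaining (as
  in MCScanX's scoring) is not implemented.
- The overlap-resolution step ("majority-run" reassignment) is one reading
  of run-length decoding of overlapping blocks; alternatives exist.
- bp-space synteny is out of scope: all inference is in gene-rank space,
  so gene-desert structure is invisible.
- The in-block orthogroup refinement is an RBH substitute for full
  sequence re-clustering within regions; it resolves homeolog columns but
  will not split arrays whose members are reciprocal best hits of the same
  partner.
- Peptide sequences are used only as an optional tie-break for array
  representatives; no alignment statistics are computed.
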