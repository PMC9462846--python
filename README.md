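# synpan

Synteny-constrained orthology and pan-genome annotation across multiple
genomes.

## The problem

Comparing gene content across several genomes requires telling orthologs
(descended through speciation) apart from paralogs (descended through
duplication). Sequence similarity alone struggles whenever genomes carry
whole-genome duplications (WGDs), tandem arrays, or presence–absence
variation (PAV): a priori knowledge of copy number is needed to infer
orthology, yet orthology is needed to infer copy number. Conserved gene
order breaks the circle — `synpan` operates on the assumption that
**homologs are exactly single copy within any syntenic region between two
genomes**, and handles the two systematic violations directly:

- **tandem arrays** are collapsed to a single representative gene and rank
  order is recomputed over representatives (`arrayOrd`), masking local
  copy-number noise;
- **PAV** is masked by condensing gene rank order over the orthogroup-
  constrained candidate hits before collinearity is scored.

The pipeline takes per-genome gene annotations (GFF3/BED), pairwise
protein-similarity hits (BLAST/DIAMOND `outfmt 6`), orthogroup membership
(`Orthogroups.tsv` dialect, or an internal reciprocal-best-hit fallback)
and per-genome ploidies, and produces:

1. **syntenic anchors, blocks and regions** per genome pair — collinear
   chains (score = hit count, per-axis gap cap `nGaps`, minimum length
   `blkSize`) cleaned and clustered by density (DBSCAN, radius `synBuff`);
2. optional **secondary (paralog) synteny**: after masking primary regions,
   a rerun recovers WGD-derived homeologous regions;
3. **syntenic orthogroups**: connected components of orthogroup-consistent
   in-buffer hits across all pairs, optionally re-estimated within blocks
   for polyploids;
4. a **reference-anchored pan-genome annotation**: every orthogroup placed
   at its (interpolated) position on a chosen reference genome, exposing
   gene PAV and copy-number variation as entry × genome matrices.

A genome-evolution simulator (`synpan.simulate`) generates multi-genome
datasets with known ancestral gene order, inversions, translocations,
tandem duplications, losses and WGDs, plus bitscore-realistic hit tables —
so every stage is testable against ground truth without external data.

## Worked example

```python
from synpan import SyntenyParams, run_pipeline, simulate as sim

scenario = sim.default_scenario(seed=1)          # 3 genomes, 2 chr x 500 genes
result = sim.simulate_scenario(scenario)
run = run_pipeline(result.genomes, result.hits, result.og_map, SyntenyParams())

blocks = run.blocks
print(f"{len(blocks)} syntenic blocks in {blocks['reg_id'].nunique()} regions")
print(blocks[["blk_id", "orientation", "n_anchors"]].head(4).to_string(index=False))

pangenome = run.pangenome("genA")
pav, cnv = pangenome.pav_cnv()
print(f"{len(pav)} pan-genome entries; absent cells per genome:")
print((~pav).sum().to_string())
```

prints

```
36 syntenic blocks in 12 regions
                  blk_id orientation  n_anchors
genA|genB|chr1|chr1|r0b0           +        204
genA|genB|chr1|chr1|r0b1           -         37
genA|genB|chr1|chr1|r0b2           +        125
genA|genB|chr1|chr1|r0b3           -         36
1001 pan-genome entries; absent cells per genome:
genome
genA    17
genB    22
genC    22
```

Each simulated branch carried two inversions, a translocation, 1% tandem
duplication and 2% gene loss. The `-` blocks are the recovered inversions
(orientation is the sign of the collinear chain). The 1000 ancestral genes
resolve into 1001 pan-genome entries, and the absent cells per genome match
the simulated losses (16/21/21 ancestral genes lost on the three branches;
one orthogroup is split in two).

The same run from a shell:

```bash
synpan simulate --seed 1 --out fixtures/demo
synpan synteny  --dir fixtures/demo --out results/demo
synpan pangenome --dir fixtures/demo --out results/demo --ref genA
synpan riparian --dir fixtures/demo --out results/demo --ref genA --highlight genA=chr1
```

Key parameters (see `SyntenyParams`): `blk_size=5` (minimum collinear hits
per block), `n_gaps=5` (maximum rank gap inside a chain), `syn_buff=100`
(gene-rank radius of the syntenic buffer), per-genome `ploidy`,
`n_secondary_hits` (enable the paralog scan), `only_og_anchors`,
`prop_assign_thresh=0.5` and `max_placements_per_ref_chr=2` for pan-genome
placement.

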