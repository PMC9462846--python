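"""Tunable parameters for synteny and pan-genome construction.

All distance-like parameters are in gene-rank units (positions along a
chromosome counted in genes, not base pairs): the pipeline infers synteny
in rank space, where gene density differences between genomes cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping


@dataclass
class SyntenyParams:
    """Parameter set controlling every stage of the pipeline.

    Parameters
    ----------
    blk_size
        Minimum number of collinear anchor hits for a run to qualify as a
        syntenic block. Chromosomes with fewer than ``blk_size`` genes are
        dropped during QC.
    n_gaps
        Maximum number of skipped rank positions allowed between two
        consecutive hits of a collinear chain, applied independently on
        each axis.
    syn_buff
        Radius (gene-rank units) around syntenic anchors: hits within this
        radius are "in buffer"; it is also the density-clustering radius
        used when grouping anchors into blocks and regions, and the gap
        size that splits tandem arrays.
    n_hits1, n_hits2
        Number of top-scoring hits per query (resp. target) gene eligible
        as anchors. ``"auto"`` resolves to the ploidy of the opposite
        genome, so a haploid-vs-tetraploid comparison keeps two hits per
        haploid gene.
    only_og_anchors
        Require anchor hits to join genes of the same orthogroup.
    n_secondary_hits
        If > 0, rerun synteny after masking primary regions to recover
        paralogous (e.g. WGD-derived) regions, keeping this many hits per
        gene and not requiring shared orthogroups.
    blk_size_second, n_gaps_second, syn_buff_second
        Parameter set used for the secondary (paralog) scan.
    prop_assign_thresh
        Minimum proportion of a syntenic orthogroup's positioned members a
        placement cluster must hold to be retained in the pan-genome.
    max_placements_per_ref_chr
        Maximum pan-genome placements of one orthogroup on a single
        reference chromosome.
    ploidy
        Mapping genome name -> ploidy (>= 1). Missing genomes default to 1.
    outgroups
        Genomes used only for orthogroup input and excluded from synteny
        and pan-genome stages.
    orthofinder_in_blk
        Re-estimate orthogroups within syntenic regions and rerun synteny
        once. ``None`` (default) enables this iff any genome has ploidy > 1.
    self_mask_radius
        Gene-rank radius around the self-hit identity diagonal masked
        before scanning a polyploid genome against itself.
    """

    blk_size: int = 5
    n_gaps: int = 5
    syn_buff: int = 100
    n_hits1: int | str = "auto"
    n_hits2: int | str = "auto"
    only_og_anchors: bool = True
    n_secondary_hits: int = 0
    blk_size_second: int = 5
    n_gaps_second: int = 5
    syn_buff_second: int = 100
    prop_assign_thresh: float = 0.5
    max_placements_per_ref_chr: int = 2
    ploidy: Mapping[str, int] = field(default_factory=dict)
    outgroups: frozenset[str] = field(default_factory=frozenset)
    orthofinder_in_blk: bool | None = None
    self_mask_radius: int = 500

    def __post_init__(self) -> None:
        for name in ("blk_size", "n_gaps", "syn_buff", "blk_size_second",
                     "n_gaps_second", "syn_buff_second",
                     "max_placements_per_ref_chr", "self_mask_radius"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.n_secondary_hits, int) or self.n_secondary_hits < 0:
            raise ValueError("n_secondary_hits must be an integer >= 0")
        if not (0 < self.prop_assign_thresh <= 1):
            raise ValueError("prop_assign_thresh must be in (0, 1]")
        for nh in (self.n_hits1, self.n_hits2):
            if nh != "auto" and (not isinstance(nh, int) or nh < 1):
                raise ValueError("n_hits1/n_hits2 must be 'auto' or int >= 1")
        for g, p in dict(self.ploidy).items():
            if not isinstance(p, int) or p < 1:
                raise ValueError(f"ploidy of {g} must be an integer >= 1")
        self.outgroups = frozenset(self.outgroups)

    def ploidy_of(self, genome: str) -> int:
        return dict(self.ploidy).get(genome, 1)

    def resolve_n_hits(self, genome_q: str, genome_t: str) -> tuple[int, int]:
        """Resolve 'auto' hit counts: top-n per query gene defaults to the
        target genome's ploidy and vice versa."""
        n1 = self.ploidy_of(genome_t) if self.n_hits1 == "auto" else self.n_hits1
        n2 = self.ploidy_of(genome_q) if self.n_hits2 == "auto" else self.n_hits2
        return int(n1), int(n2)

    def in_blk_enabled(self, genomes) -> bool:
        if self.orthofinder_in_blk is not None:
            return bool(self.orthofinder_in_blk)
        return any(self.ploidy_of(g) > 1 for g in genomes)

    def secondary(self) -> "SyntenyParams":
        """Parameter set for the secondary (paralog) scan."""
        return replace(
            self,
            blk_size=self.blk_size_second,
            n_gaps=self.n_gaps_second,
            syn_buff=self.syn_buff_second,
            n_hits1=self.n_secondary_hits,
            n_hits2=self.n_secondary_hits,
            only_og_anchors=False,
            n_secondary_hits=0,
        )
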