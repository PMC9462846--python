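"""Summary statistics over synteny runs.

The headline diagnostic mirrors how synteny pipelines are benchmarked: the
percentage of genes placed in exactly one syntenic location per genome
pair. Placement is counted through a gene's orthogroup-consistent
in-buffer hits at region granularity (regions average across minor
inversions, so a micro-inversion does not split a placement), which is the
operational form of the single-copy assumption: homologs should be exactly
single copy within any syntenic region.
"""

from __future__ import annotations

import pandas as pd


def gene_placement_counts(hits: pd.DataFrame) -> pd.Series:
    """Distinct syntenic-region placements per gene of one genome pair.

    Every gene appearing in an orthogroup-consistent (``is_og``) hit is
    counted; its placements are the distinct region ids of its is_og
    in-buffer hits (genes whose hits all fall outside every syntenic
    buffer get 0).
    """
    og = hits.loc[hits["is_og"]]
    buf = og.loc[og["in_buffer"] & og["reg_id"].notna()]
    out = {}
    for col in ("query", "target"):
        regs = buf.groupby(col)["reg_id"].nunique()
        base = pd.Series(0, index=pd.unique(og[col]))
        out[col] = base.add(regs, fill_value=0).astype(int)
    return pd.concat([out["query"], out["target"]])


def single_copy_rate(hits: pd.DataFrame) -> float:
    """Fraction of genes (both genomes pooled) with exactly one syntenic
    placement in this pair."""
    counts = gene_placement_counts(hits)
    if len(counts) == 0:
        return 0.0
    return float((counts == 1).mean())


def block_coverage(genes: pd.DataFrame, blocks: pd.DataFrame,
                   genome: str) -> pd.Series:
    """Positional diagnostic: for each gene of ``genome``, the number of
    (primary, non-self) block rank spans containing it on this genome's
    axis."""
    b = blocks.loc[~blocks["is_secondary"] & ~blocks["is_self"]]
    g = genes.loc[genes["genome"] == genome]
    counts = pd.Series(0, index=g["gene_id"].to_numpy())
    for side in ("q", "t"):
        sub = b.loc[b[f"genome_{side}"] == genome]
        for chrom, bl in sub.groupby(f"chrom_{side}"):
            gg = g.loc[g["chrom"] == chrom]
            pos = gg["array_ord_eff"].to_numpy(float)
            lo = bl[f"min_ord_{side}"].to_numpy(float)
            hi = bl[f"max_ord_{side}"].to_numpy(float)
            inside = (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
            counts.loc[gg["gene_id"].to_numpy()] += inside.sum(axis=1)
    return counts


def anchor_rate(hits: pd.DataFrame) -> float:
    """Fraction of all hits flagged as syntenic anchors."""
    if len(hits) == 0:
        return 0.0
    return float(hits["is_anchor"].mean())
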