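"""Dotplot and riparian-plot coordinate computation.

The layouts are the tested artifact; rendering is a thin matplotlib
convenience on top. Riparian ("braided ribbon") plots stack genomes as
horizontal rows of chromosome segments scaled by gene counts, with braids
connecting syntenic regions between vertically adjacent genomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synteny import region_table


def _natural_key(chrom: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", str(chrom))]


def dotplot_table(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per in-buffer hit with condensed rank coordinates and a
    deterministic per-block color key (order of block appearance)."""
    sub = hits.loc[hits["in_buffer"]].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=["query", "target", "chrom_q", "chrom_t",
                                     "x", "y", "blk_id", "color_key"])
    sub = sub.sort_values(["chrom_q", "ord_q", "chrom_t", "ord_t"],
                          kind="mergesort")
    key_q = pd.MultiIndex.from_arrays([sub["chrom_q"], sub["ord_q"]])
    key_t = pd.MultiIndex.from_arrays([sub["chrom_t"], sub["ord_t"]])
    sub["x"] = pd.factorize(key_q, sort=True)[0] + 1
    sub["y"] = pd.factorize(key_t, sort=True)[0] + 1
    seen: dict = {}
    keys = []
    for b in sub["blk_id"]:
        if b not in seen:
            seen[b] = len(seen)
        keys.append(seen[b])
    sub["color_key"] = keys
    return sub[["query", "target", "chrom_q", "chrom_t", "x", "y",
                "blk_id", "color_key"]].reset_index(drop=True)


def _block_sides(blocks: pd.DataFrame, genome: str) -> pd.DataFrame:
    """Blocks touching ``genome`` reoriented as (chrom, lo, hi, other
    genome/chrom/lo/hi, n_anchors, reg_id)."""
    rows = []
    for side, other in (("q", "t"), ("t", "q")):
        sub = blocks.loc[(blocks[f"genome_{side}"] == genome)
                         & (blocks["genome_q"] != blocks["genome_t"])]
        for r in sub.itertuples(index=False):
            rows.append({
                "chrom": getattr(r, f"chrom_{side}"),
                "lo": getattr(r, f"min_ord_{side}"),
                "hi": getattr(r, f"max_ord_{side}"),
                "other_genome": getattr(r, f"genome_{other}"),
                "other_chrom": getattr(r, f"chrom_{other}"),
                "other_lo": getattr(r, f"min_ord_{other}"),
                "other_hi": getattr(r, f"max_ord_{other}"),
                "n_anchors": r.n_anchors, "reg_id": r.reg_id})
    return pd.DataFrame(rows)


def order_chromosomes(blocks: pd.DataFrame, genomes: dict[str, pd.DataFrame],
                      ref: str) -> dict[str, list[str]]:
    """Per-genome chromosome order for plotting.

    Reference chromosomes keep natural order; every other genome's
    chromosomes are sorted by the anchor-count-weighted mean reference
    position of their blocks against the reference (chromosomes without
    blocks sort last, by name).
    """
    ref_chroms = sorted(genomes[ref]["chrom"].unique(), key=_natural_key)
    ref_sizes = genomes[ref].groupby("chrom")["gene_id"].size()
    offset = {}
    cum = 0.0
    for c in ref_chroms:
        offset[c] = cum
        cum += float(ref_sizes.get(c, 0))
    orders = {ref: ref_chroms}
    for genome in sorted(genomes):
        if genome == ref:
            continue
        sides = _block_sides(blocks, genome)
        means: dict[str, float] = {}
        if len(sides):
            vs_ref = sides.loc[sides["other_genome"] == ref]
            for chrom, sub in vs_ref.groupby("chrom"):
                w = sub["n_anchors"].to_numpy(float)
                mid = ((sub["other_lo"] + sub["other_hi"]) / 2).to_numpy(float)
                gpos = np.array([offset.get(c, cum) for c in sub["other_chrom"]])
                means[chrom] = float(np.average(gpos + mid, weights=w))
        chroms = sorted(genomes[genome]["chrom"].unique(), key=_natural_key)
        withb = sorted([c for c in chroms if c in means],
                       key=lambda c: (means[c], _natural_key(c)))
        without = [c for c in chroms if c not in means]
        orders[genome] = withb + without
    return orders


@dataclass
class RiparianLayout:
    genome_order: list[str]
    segments: pd.DataFrame   # genome, chrom, x0, x1, n_genes
    braids: pd.DataFrame     # top/bottom genome+chrom+span, reg_id, highlighted
    highlighted: set = field(default_factory=set)


def riparian_layout(blocks: pd.DataFrame, genomes: dict[str, pd.DataFrame],
                    genome_order: list[str], ref: str | None = None,
                    highlights: set[tuple[str, str]] | None = None,
                    gap: float = 20.0) -> RiparianLayout:
    """Compute segment offsets and braid polygons between adjacent rows.

    Chromosome segment widths are proportional to gene counts; braids are
    one per syntenic region between vertically adjacent genomes.
    ``highlights`` seeds a set of (genome, chrom) tuples that propagate
    transitively through syntenic regions across rows.
    """
    ref = ref or genome_order[0]
    orders = order_chromosomes(blocks, genomes, ref)
    seg_rows = []
    offsets: dict[tuple[str, str], float] = {}
    for genome in genome_order:
        x = 0.0
        sizes = genomes[genome].groupby("chrom")["gene_id"].size()
        for chrom in orders[genome]:
            n = float(sizes.get(chrom, 0))
            offsets[(genome, chrom)] = x
            seg_rows.append({"genome": genome, "chrom": chrom,
                             "x0": x, "x1": x + n, "n_genes": n})
            x += n + gap
    segments = pd.DataFrame(seg_rows)

    braid_rows = []
    for gi in range(len(genome_order) - 1):
        top, bottom = genome_order[gi], genome_order[gi + 1]
        sub = blocks.loc[
            ((blocks["genome_q"] == top) & (blocks["genome_t"] == bottom))
            | ((blocks["genome_q"] == bottom) & (blocks["genome_t"] == top))]
        regs = region_table(sub)
        if len(regs) == 0:
            continue
        for r in regs.itertuples(index=False):
            if r.genome_q == top:
                tc, t0, t1 = r.chrom_q, r.min_ord_q, r.max_ord_q
                bc, b0, b1 = r.chrom_t, r.min_ord_t, r.max_ord_t
            else:
                tc, t0, t1 = r.chrom_t, r.min_ord_t, r.max_ord_t
                bc, b0, b1 = r.chrom_q, r.min_ord_q, r.max_ord_q
            braid_rows.append({
                "reg_id": r.reg_id,
                "top_genome": top, "top_chrom": tc,
                "top_x0": offsets.get((top, tc), 0.0) + t0,
                "top_x1": offsets.get((top, tc), 0.0) + t1,
                "bottom_genome": bottom, "bottom_chrom": bc,
                "bottom_x0": offsets.get((bottom, bc), 0.0) + b0,
                "bottom_x1": offsets.get((bottom, bc), 0.0) + b1})
    braids = pd.DataFrame(braid_rows)

    highlighted: set[tuple[str, str]] = set(highlights or ())
    if len(braids) and highlighted:
        changed = True
        while changed:
            changed = False
            for r in braids.itertuples(index=False):
                a = (r.top_genome, r.top_chrom)
                b = (r.bottom_genome, r.bottom_chrom)
                if (a in highlighted) != (b in highlighted):
                    highlighted |= {a, b}
                    changed = True
    if len(braids):
        braids["highlighted"] = [
            (r.top_genome, r.top_chrom) in highlighted
            and (r.bottom_genome, r.bottom_chrom) in highlighted
            if highlighted else False
            for r in braids.itertuples(index=False)]
    return RiparianLayout(genome_order=list(genome_order), segments=segments,
                          braids=braids, highlighted=highlighted)


# ---------------------------------------------------------------- plotting

def plot_dotplot(dots: pd.DataFrame, path: str) -> None:
    """Render a dotplot table to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(dots):
        ax.scatter(dots["x"], dots["y"], c=dots["color_key"] % 8, cmap="Set2",
                   s=4, linewidths=0)
    ax.set_xlabel("query gene rank")
    ax.set_ylabel("target gene rank")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_riparian(layout: RiparianLayout, path: str) -> None:
    """Render a riparian layout to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon
    fig, ax = plt.subplots(figsize=(8, 1.2 * len(layout.genome_order) + 1))
    ypos = {g: -i for i, g in enumerate(layout.genome_order)}
    for r in layout.segments.itertuples(index=False):
        y = ypos[r.genome]
        ax.plot([r.x0, r.x1], [y, y], lw=6, solid_capstyle="butt",
                color="#cccccc")
    for r in (layout.braids.itertuples(index=False)
              if len(layout.braids) else ()):
        yt, yb = ypos[r.top_genome] - 0.05, ypos[r.bottom_genome] + 0.05
        color = "#d4a017" if getattr(r, "highlighted", False) else "#7f9fc4"
        poly = Polygon([(r.top_x0, yt), (r.top_x1, yt),
                        (r.bottom_x1, yb), (r.bottom_x0, yb)],
                       closed=True, alpha=0.5, color=color, lw=0)
        ax.add_patch(poly)
    for g, y in ypos.items():
        ax.text(-5, y, g, ha="right", va="center", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
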