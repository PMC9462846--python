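"""End-to-end orchestration: annotations + hits + orthogroups -> tandem
arrays -> pairwise syntenic blocks -> syntenic orthogroups -> pan-genome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import genome_io, og_refine, pangenome as pg, synteny, tandem
from .params import SyntenyParams

log = logging.getLogger(__name__)


@dataclass
class SyntenyRun:
    """Everything the pairwise synteny stage produced."""
    genomes: dict[str, pd.DataFrame]
    hits: dict[tuple[str, str], pd.DataFrame]
    blocks: pd.DataFrame
    sogs: pd.DataFrame
    og_map: dict[str, str]
    params: SyntenyParams
    arrays: pd.DataFrame
    secondary_hits: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    self_blocks: pd.DataFrame | None = None

    def pangenome(self, ref: str, orthologs=None) -> pg.PanGenome:
        return pg.build_pangenome(self.genomes, self.hits, self.sogs,
                                  self.params, ref, orthologs=orthologs)


def normalize_raw_hits(raw: pd.DataFrame, genome_a: str, genome_b: str,
                       genes_a: pd.DataFrame, genes_b: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, str, str]:
    """In-memory equivalent of :func:`genome_io.load_hits`: orient the pair
    so the genome with more gene models is the query, dedup (query, target)
    by max bitscore and drop intragenomic self rows."""
    hits = raw.copy()
    if genome_a == genome_b:
        genome_q = genome_t = genome_a
    else:
        if (len(genes_a), genome_b) > (len(genes_b), genome_a):
            genome_q, genome_t = genome_a, genome_b
        else:
            genome_q, genome_t = genome_b, genome_a
        if genome_q != genome_a:
            hits = hits.rename(columns={
                "query": "target", "target": "query",
                "q_start": "t_start", "q_end": "t_end",
                "t_start": "q_start", "t_end": "q_end"})
            hits = hits[genome_io.OUTFMT6_COLUMNS]
    if genome_q == genome_t:
        hits = hits.loc[hits["query"] != hits["target"]]
    hits = (hits.sort_values(["query", "target", "bitscore", "pident"],
                             ascending=[True, True, False, False],
                             kind="mergesort")
                .drop_duplicates(["query", "target"])
                .reset_index(drop=True))
    return hits, genome_q, genome_t


def prepare_genomes(annotations: dict[str, pd.DataFrame],
                    og_map: dict[str, str], params: SyntenyParams,
                    peptide_lengths=None,
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """QC chromosomes, attach orthogroups, call tandem arrays and compute
    collapsed rank order for every genome."""
    out = {}
    all_arrays = []
    for name in sorted(annotations):
        g = genome_io.qc_chromosomes(annotations[name], params)
        g = genome_io.apply_orthogroups(g, og_map)
        arrays, g = tandem.find_tandem_arrays(g, params, peptide_lengths)
        g = tandem.assign_array_ord(g)
        out[name] = g
        all_arrays.append(tandem.arrays_table(arrays))
    arrays_df = (pd.concat(all_arrays, ignore_index=True)
                 if all_arrays else tandem.arrays_table([]))
    return out, arrays_df


def _scan_all_pairs(genomes, raw_hits, annotations, og_map, params):
    hits_out, blocks_out = {}, []
    for a, b in sorted(raw_hits):
        if a in params.outgroups or b in params.outgroups:
            continue
        hits, gq, gt = normalize_raw_hits(
            raw_hits[(a, b)], a, b, annotations[a], annotations[b])
        h = synteny.annotate_hits(hits, genomes[gq], genomes[gt], og_map)
        h, blocks = synteny.run_pair_scan(h, params)
        hits_out[(gq, gt)] = h
        blocks_out.append(blocks)
    blocks_df = (pd.concat(blocks_out, ignore_index=True)
                 if blocks_out else synteny._empty_blocks())
    return hits_out, blocks_df


def run_pipeline(annotations: dict[str, pd.DataFrame],
                 raw_hits: dict[tuple[str, str], pd.DataFrame],
                 og_map: dict[str, str] | None = None,
                 params: SyntenyParams | None = None,
                 peptide_lengths=None,
                 self_hits: dict[str, pd.DataFrame] | None = None,
                 ) -> SyntenyRun:
    """Run the full synteny stage over all genome pairs.

    ``annotations`` are normalized gene tables (one per genome);
    ``raw_hits`` holds one outfmt-6-shaped table per unordered genome pair
    keyed ``(a, b)``. If ``og_map`` is None, global orthogroups are
    estimated from reciprocal best hits. Genomes named in
    ``params.outgroups`` contribute to orthogroup input only.
    """
    params = params or SyntenyParams()
    if og_map is None:
        og_map = og_refine.global_rbh_orthogroups(raw_hits)
        log.info("estimated %d RBH orthogroups", len(set(og_map.values())))
    core = {n: a for n, a in annotations.items() if n not in params.outgroups}
    genomes, arrays_df = prepare_genomes(core, og_map, params, peptide_lengths)
    hits_out, blocks_df = _scan_all_pairs(genomes, raw_hits, core, og_map, params)

    if params.in_blk_enabled(genomes) and hits_out:
        in_blk = og_refine.in_block_orthogroups(hits_out)
        combined = og_refine.combine_og_labels(og_map, in_blk)
        log.info("in-block orthogroups: %d labels; rerunning synteny",
                 len(set(in_blk.values())))
        genomes, arrays_df = prepare_genomes(core, combined, params,
                                             peptide_lengths)
        hits_out, blocks_df = _scan_all_pairs(genomes, raw_hits, core,
                                              combined, params)
        og_map = combined

    self_blocks = []
    for name in sorted(genomes):
        sh = (self_hits or {}).get(name)
        _h, sb = synteny.self_synteny(genomes[name], sh, params, name)
        self_blocks.append(sb)
    self_blocks_df = (pd.concat(self_blocks, ignore_index=True)
                      if self_blocks else None)

    secondary = {}
    if params.n_secondary_hits > 0:
        sec_blocks = []
        for pair, h in sorted(hits_out.items()):
            h2, b2 = synteny.secondary_hits_scan(h, params)
            secondary[pair] = h2
            sec_blocks.append(b2)
        nonempty = [b for b in sec_blocks if len(b)]
        if nonempty:
            blocks_df = pd.concat([blocks_df, *nonempty], ignore_index=True)

    sogs = og_refine.aggregate_syntenic_orthogroups(hits_out, genomes)
    return SyntenyRun(genomes=genomes, hits=hits_out, blocks=blocks_df,
                      sogs=sogs, og_map=og_map, params=params,
                      arrays=arrays_df, secondary_hits=secondary,
                      self_blocks=self_blocks_df)


# ------------------------------------------------------------------ I/O

HIT_TSV_COLUMNS = genome_io.OUTFMT6_COLUMNS + [
    "genome_q", "genome_t", "chrom_q", "chrom_t", "ord_q", "ord_t",
    "array_ord_q", "array_ord_t", "is_og", "scr_rank_q", "scr_rank_t",
    "is_potential", "is_anchor", "in_buffer", "blk_id", "reg_id",
    "orientation"]


def write_run(run: SyntenyRun, outdir: str | Path) -> None:
    """Write blocks, annotated hits, syntenic orthogroups, tandem arrays
    and per-genome block BEDs with deterministic ordering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks = run.blocks.sort_values("blk_id", kind="mergesort")
    blocks.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
    for (gq, gt), h in sorted(run.hits.items()):
        h2 = h[HIT_TSV_COLUMNS].sort_values(["query", "target"],
                                            kind="mergesort")
        h2.to_csv(outdir / f"hits.{gq}__vs__{gt}.tsv", sep="\t", index=False)
    run.sogs.to_csv(outdir / "syntenic_orthogroups.tsv", sep="\t", index=False)
    run.arrays.to_csv(outdir / "tandem_arrays.tsv", sep="\t", index=False)
    for genome in sorted(run.genomes):
        rows = []
        for side in ("q", "t"):
            sub = blocks.loc[blocks[f"genome_{side}"] == genome]
            for r in sub.itertuples(index=False):
                rows.append((getattr(r, f"chrom_{side}"),
                             getattr(r, f"start_bp_{side}"),
                             getattr(r, f"end_bp_{side}"), r.blk_id))
        bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        bed = bed.sort_values(["chrom", "start", "name"], kind="mergesort")
        bed.to_csv(outdir / f"blocks.{genome}.bed", sep="\t", index=False,
                   header=False)


def write_pangenome(result: pg.PanGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.entries_long.to_csv(outdir / f"pangenome.{result.ref}.long.tsv",
                               sep="\t", index=False)
    result.entries_wide.to_csv(outdir / f"pangenome.{result.ref}.wide.tsv",
                               sep="\t", index=False)
    pav, cnv = result.pav_cnv()
    pav.astype(int).to_csv(outdir / f"pav.{result.ref}.tsv", sep="\t")
    cnv.to_csv(outdir / f"cnv.{result.ref}.tsv", sep="\t")
    with open(outdir / f"unplaced.{result.ref}.txt", "w") as fh:
        fh.write("\n".join(result.unplaced) + ("\n" if result.unplaced else ""))


def load_fixture(fixture_dir: str | Path):
    """Load a simulator-written fixture directory (manifest.json layout)
    into pipeline inputs: (annotations, raw_hits, og_map, ploidy)."""
    fixture_dir = Path(fixture_dir)
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    annotations = {
        name: genome_io.load_annotation(fixture_dir / rel, name)
        for name, rel in manifest["annotations"].items()}
    og_map = genome_io.load_orthogroups(fixture_dir / manifest["orthogroups"])
    raw_hits = {}
    for key, rel in manifest["hits"].items():
        a, b = key.split("__")
        hits, gq, gt = genome_io.load_hits(
            fixture_dir / rel, a, b, annotations[a], annotations[b])
        # keep the caller-facing key orientation (a, b); normalize later
        raw_hits[(a, b)] = hits if gq == a else hits.rename(columns={
            "query": "target", "target": "query",
            "q_start": "t_start", "q_end": "t_end",
            "t_start": "q_start", "t_end": "q_end"})[genome_io.OUTFMT6_COLUMNS]
    return annotations, raw_hits, og_map, manifest.get("ploidy", {})
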