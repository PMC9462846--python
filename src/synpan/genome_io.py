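"""Readers and writers for gene annotations, similarity hits and orthogroups.

Internal conventions: bp intervals are 0-based half-open (GFF3 I/O converts
from/to 1-based closed); gene rank order (``ord``) is 1-based per
(genome, chromosome); all writers emit deterministic column order and row
sort so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

#: columns of a normalized gene table
GENE_COLUMNS = [
    "gene_id", "genome", "chrom", "start", "end", "strand",
    "ord", "og", "is_array_rep", "array_id", "array_ord",
]

#: BLAST/DIAMOND tabular output, outfmt 6
OUTFMT6_COLUMNS = [
    "query", "target", "pident", "length", "mismatch", "gap_open",
    "q_start", "q_end", "t_start", "t_end", "evalue", "bitscore",
]

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


class AnnotationError(ValueError):
    """Fatal problem in an annotation, hits or orthogroups input."""


def _finish_gene_table(df: pd.DataFrame, genome: str) -> pd.DataFrame:
    if len(df) == 0:
        raise AnnotationError(f"{genome}: annotation contains zero genes")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise AnnotationError(
            f"{genome}: duplicate gene ids, e.g. {df.loc[dup, 'gene_id'].iloc[0]!r}")
    if (df["start"] >= df["end"]).any():
        raise AnnotationError(f"{genome}: gene with start >= end")
    # rank order per chromosome; ties on start broken by end then gene_id
    df = df.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
    df["ord"] = df.groupby("chrom", sort=False).cumcount() + 1
    df["genome"] = genome
    df["og"] = None
    df["is_array_rep"] = True
    df["array_id"] = None
    df["array_ord"] = float("nan")
    return df[GENE_COLUMNS].reset_index(drop=True)


def load_annotation(path: str | Path, genome: str, *,
                    feature: str = "gene", id_attr: str = "ID") -> pd.DataFrame:
    """Load one genome's gene models from GFF3 or BED into a gene table.

    Format is chosen from the file suffix (``.bed`` -> BED4+; anything else
    is parsed as GFF3, keeping rows whose feature type equals ``feature``).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _load_bed(path, genome)
    return _load_gff3(path, genome, feature=feature, id_attr=id_attr)


def _load_gff3(path: Path, genome: str, *, feature: str, id_attr: str) -> pd.DataFrame:
    rows = []
    attr_re = (_GFF_ID_RE if id_attr == "ID"
               else re.compile(r"(?:^|;)\s*%s=([^;]+)" % re.escape(id_attr)))
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            m = attr_re.search(parts[8])
            if m is None:
                raise AnnotationError(
                    f"{genome}: {feature} record without {id_attr} attribute: {line[:80]}")
            rows.append((m.group(1), parts[0], int(parts[3]) - 1, int(parts[4]),
                         parts[6] if parts[6] in "+-" else "."))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return _finish_gene_table(df, genome)


def _load_bed(path: Path, genome: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise AnnotationError(f"{genome}: BED file needs >= 4 columns")
    out = pd.DataFrame({
        "gene_id": df.iloc[:, 3].astype(str),
        "chrom": df.iloc[:, 0].astype(str),
        "start": df.iloc[:, 1].astype(int),
        "end": df.iloc[:, 2].astype(int),
        "strand": (df.iloc[:, 5].astype(str)
                   if df.shape[1] > 5 else pd.Series(["."] * len(df))),
    })
    out.loc[~out["strand"].isin(["+", "-"]), "strand"] = "."
    return _finish_gene_table(out, genome)


def write_annotation(genes: pd.DataFrame, path: str | Path, *, fmt: str = "gff3") -> None:
    """Write a gene table back to GFF3 (1-based closed) or BED (0-based)."""
    path = Path(path)
    g = genes.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for r in g.itertuples(index=False):
                fh.write(f"{r.chrom}\tsynpan\tgene\t{r.start + 1}\t{r.end}\t."
                         f"\t{r.strand}\t.\tID={r.gene_id}\n")
        elif fmt == "bed":
            for r in g.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


def qc_chromosomes(genes: pd.DataFrame, params) -> pd.DataFrame:
    """Drop chromosomes with fewer than ``blk_size`` genes.

    Per-chromosome ranks are left untouched (they are already local to each
    chromosome). Fatal if a genome loses all of its chromosomes.
    """
    sizes = genes.groupby(["genome", "chrom"])["gene_id"].transform("size")
    keep = sizes >= params.blk_size
    dropped = genes.loc[~keep]
    if len(dropped):
        log.info("qc_chromosomes: dropped %d genes on %d small chromosomes",
                 len(dropped), dropped.groupby(["genome", "chrom"]).ngroups)
    out = genes.loc[keep].reset_index(drop=True)
    for genome in genes["genome"].unique():
        if (out["genome"] == genome).sum() == 0:
            raise AnnotationError(
                f"{genome}: all chromosomes dropped by QC (blk_size={params.blk_size})")
    return out


def _read_outfmt6(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=OUTFMT6_COLUMNS, dtype={0: str, 1: str})
    return df


def load_hits(path_ab: str | Path, genome_a: str, genome_b: str,
              genes_a: pd.DataFrame, genes_b: pd.DataFrame,
              path_ba: str | Path | None = None,
              ) -> tuple[pd.DataFrame, str, str]:
    """Load (and merge reciprocal) outfmt-6 hit files for one genome pair.

    ``path_ab`` is oriented A query -> B target, ``path_ba`` the reciprocal.
    For intergenomic pairs the genome with more gene models becomes the
    query (ties broken by genome name); duplicated (query, target) rows keep
    the max bitscore, then max pident, then first occurrence. Intragenomic
    self rows (query == target) are removed.

    Returns ``(hits, genome_q, genome_t)``.
    """
    frames = [_read_outfmt6(Path(path_ab))]
    if path_ba is not None:
        rec = _read_outfmt6(Path(path_ba))
        rec = rec.rename(columns={
            "query": "target", "target": "query",
            "q_start": "t_start", "q_end": "t_end",
            "t_start": "q_start", "t_end": "q_end"})
        frames.append(rec[OUTFMT6_COLUMNS])
    hits = pd.concat(frames, ignore_index=True)
    if len(hits) == 0:
        raise AnnotationError(f"{genome_a} vs {genome_b}: empty hit file")

    if genome_a == genome_b:
        genome_q = genome_t = genome_a
    else:
        na, nb = len(genes_a), len(genes_b)
        if (na, genome_b) > (nb, genome_a):  # more genes wins; name tiebreak
            genome_q, genome_t = genome_a, genome_b
        else:
            genome_q, genome_t = genome_b, genome_a
        if genome_q != genome_a:
            hits = hits.rename(columns={
                "query": "target", "target": "query",
                "q_start": "t_start", "q_end": "t_end",
                "t_start": "q_start", "t_end": "q_end"})[OUTFMT6_COLUMNS]

    genes_q = genes_a if genome_q == genome_a else genes_b
    genes_t = genes_b if genome_q == genome_a else genes_a
    ok = (hits["query"].isin(set(genes_q["gene_id"]))
          & hits["target"].isin(set(genes_t["gene_id"])))
    n_bad = int((~ok).sum())
    if n_bad:
        if n_bad > 0.1 * len(hits):
            raise AnnotationError(
                f"{genome_q} vs {genome_t}: {n_bad}/{len(hits)} hit rows "
                "reference unknown genes")
        log.warning("load_hits %s vs %s: dropped %d unresolvable rows",
                    genome_q, genome_t, n_bad)
        hits = hits.loc[ok]

    if genome_q == genome_t:
        hits = hits.loc[hits["query"] != hits["target"]]

    hits = (hits.sort_values(["query", "target", "bitscore", "pident"],
                             ascending=[True, True, False, False], kind="mergesort")
                .drop_duplicates(["query", "target"], keep="first")
                .reset_index(drop=True))
    if len(hits) == 0:
        raise AnnotationError(f"{genome_q} vs {genome_t}: no usable hits")
    return hits, genome_q, genome_t


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[OUTFMT6_COLUMNS].sort_values(["query", "target"], kind="mergesort").to_csv(
        path, sep="\t", header=False, index=False)


def load_orthogroups(path: str | Path) -> dict[str, str]:
    """Read an Orthogroups.tsv-dialect file into a gene -> orthogroup map.

    First column is the orthogroup id; remaining columns hold
    comma-separated member lists (one column per genome). A gene listed in
    two orthogroups is fatal.
    """
    og_map: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise AnnotationError("empty orthogroups file")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            og = parts[0]
            for cell in parts[1:]:
                for gene in cell.split(","):
                    gene = gene.strip()
                    if not gene:
                        continue
                    if gene in og_map and og_map[gene] != og:
                        raise AnnotationError(
                            f"gene {gene!r} listed in orthogroups "
                            f"{og_map[gene]!r} and {og!r}")
                    og_map[gene] = og
    return og_map


def write_orthogroups(og_map: Mapping[str, str], genomes: Mapping[str, Iterable[str]],
                      path: str | Path) -> None:
    """Write a gene -> og map as Orthogroups.tsv (one column per genome)."""
    genome_names = sorted(genomes)
    by_og: dict[str, dict[str, list[str]]] = {}
    gene_genome = {g: name for name, ids in genomes.items() for g in ids}
    for gene, og in og_map.items():
        gm = gene_genome.get(gene)
        if gm is None:
            continue
        by_og.setdefault(og, {}).setdefault(gm, []).append(gene)
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genome_names) + "\n")
        for og in sorted(by_og):
            cells = [", ".join(sorted(by_og[og].get(g, []))) for g in genome_names]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def apply_orthogroups(genes: pd.DataFrame, og_map: Mapping[str, str]) -> pd.DataFrame:
    """Fill the ``og`` column from a gene -> orthogroup map (missing -> None)."""
    genes = genes.copy()
    genes["og"] = genes["gene_id"].map(lambda g: og_map.get(g))
    return genes


def load_peptide_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from a peptide FASTA (used only as array-representative
    tie-break)."""
    from Bio import SeqIO
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
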