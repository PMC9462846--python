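"""Orthogroup refinement inside syntenic regions and aggregation of
pairwise syntenic hits into multi-genome syntenic orthogroups.

Global orthogroups can lump WGD-derived paralog columns together; within a
syntenic region the correct pairing is recoverable, because homologs are
single copy there. Genes are therefore re-clustered per region as the
connected components of the reciprocal-best-hit (RBH) graph restricted to
in-buffer hits, and the synteny scan is rerun once on the combined
(global og, in-block og) labels.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def rbh_pairs(hits: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal best hits of one (query, target, bitscore) table: rows
    where the target is the query's top-scoring hit and vice versa. Ties on
    bitscore are broken by partner gene id for determinism."""
    h = hits.sort_values(["bitscore", "target"], ascending=[False, True],
                         kind="mergesort")
    best_t = h.drop_duplicates("query").set_index("query")["target"]
    h2 = hits.sort_values(["bitscore", "query"], ascending=[False, True],
                          kind="mergesort")
    best_q = h2.drop_duplicates("target").set_index("target")["query"]
    keep = (hits["target"] == hits["query"].map(best_t)) \
        & (hits["query"] == hits["target"].map(best_q))
    return hits.loc[keep, ["query", "target"]]


def global_rbh_orthogroups(hit_tables: Mapping[tuple, pd.DataFrame]) -> dict[str, str]:
    """Fallback global orthogroups when no orthogroup file is supplied:
    connected components of the union of pairwise RBH graphs."""
    graph = nx.Graph()
    for pair in sorted(hit_tables):
        for q, t in rbh_pairs(hit_tables[pair]).itertuples(index=False):
            graph.add_edge(q, t)
    og_map: dict[str, str] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for i, comp in enumerate(comps):
        og = f"rbhOG{i:06d}"
        for g in comp:
            og_map[g] = og
    return og_map


def in_block_orthogroups(hit_tables: Mapping[tuple, pd.DataFrame],
                         ) -> dict[str, str]:
    """Re-cluster genes within each syntenic region.

    For every region of every genome pair, the RBH graph over in-buffer
    hits is built and its connected components become in-block orthogroup
    labels. Labels from all pairs/regions are aggregated into one graph so
    a gene shared by two regions joins its components.
    """
    graph = nx.Graph()
    for pair in sorted(hit_tables):
        h = hit_tables[pair]
        buf = h.loc[h["in_buffer"] & h["reg_id"].notna()]
        for _reg, sub in buf.groupby("reg_id", sort=True):
            for q, t in rbh_pairs(sub).itertuples(index=False):
                graph.add_edge(q, t)
    og_map: dict[str, str] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for i, comp in enumerate(comps):
        og = f"blkOG{i:06d}"
        for g in comp:
            og_map[g] = og
    return og_map


def combine_og_labels(global_og: Mapping[str, str] | None,
                      in_blk_og: Mapping[str, str]) -> dict[str, str]:
    """Combined label: genes with an in-block orthogroup are split by it
    within their global orthogroup; genes without keep the global label."""
    out: dict[str, str] = {}
    genes = set(in_blk_og)
    if global_og:
        genes |= set(global_og)
    for g in genes:
        glob = global_og.get(g) if global_og else None
        blk = in_blk_og.get(g)
        if blk is None:
            out[g] = glob
        elif glob is None:
            out[g] = blk
        else:
            out[g] = f"{glob}|{blk}"
    return {g: v for g, v in out.items() if v is not None}


def aggregate_syntenic_orthogroups(hit_tables: Mapping[tuple, pd.DataFrame],
                                   genomes: Mapping[str, pd.DataFrame],
                                   ) -> pd.DataFrame:
    """Connected components of syntenic orthogroup-consistent hits.

    Edges are hits that are both in-buffer and orthogroup matches, pooled
    over all genome pairs; tandem-array members inherit their
    representative's component. Returns a long table
    (sog_id, genome, gene_id, provenance).
    """
    graph = nx.Graph()
    for pair in sorted(hit_tables):
        h = hit_tables[pair]
        syn = h.loc[h["in_buffer"] & h["is_og"]]
        for q, t in syn[["query", "target"]].itertuples(index=False):
            graph.add_edge(q, t)
    gene_genome: dict[str, str] = {}
    rep_members: dict[str, list[str]] = {}
    nonrep: set[str] = set()
    for name, df in genomes.items():
        for gid in df["gene_id"]:
            gene_genome[gid] = name
        arr = df.loc[df["array_id"].notna()]
        nonrep |= set(arr.loc[~arr["is_array_rep"], "gene_id"])
        for _aid, sub in arr.groupby("array_id"):
            reps = sub.loc[sub["is_array_rep"], "gene_id"]
            if len(reps) == 0:
                continue
            rep = reps.iloc[0]
            rep_members[rep] = [g for g in sub["gene_id"] if g != rep]
    rows = []
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for i, comp in enumerate(comps):
        sog = f"sog{i:06d}"
        for g in sorted(comp):
            # non-representative array members are bookkept as array
            # members of their representative even when they carry their
            # own syntenic edges
            prov = "array" if g in nonrep else "direct"
            rows.append((sog, gene_genome.get(g), g, prov))
            for member in rep_members.get(g, []):
                rows.append((sog, gene_genome.get(member), member, "array"))
    out = pd.DataFrame(rows, columns=["sog_id", "genome", "gene_id", "provenance"])
    # a gene can only belong to one component; array members follow one rep
    out = out.drop_duplicates("gene_id")
    return out.reset_index(drop=True)


def sog_wide_table(sogs: pd.DataFrame, genome_names: Iterable[str]) -> pd.DataFrame:
    """Syntenic orthogroups, one row per group with comma-joined member
    lists per genome."""
    names = sorted(genome_names)
    rows = []
    for sog, sub in sogs.groupby("sog_id", sort=True):
        row = {"sog_id": sog}
        for g in names:
            row[g] = ",".join(sorted(sub.loc[sub["genome"] == g, "gene_id"]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sog_id", *names])
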