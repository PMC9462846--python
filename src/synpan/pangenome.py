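"""Reference-anchored pan-genome annotation.

Pairwise syntenic orthology is decoded onto the coordinate system of one
reference genome: reference tandem-array representatives form a positional
backbone; every other genome's representatives receive an interpolated
reference rank from ungapped 1:1 anchor runs; syntenic orthogroups are then
placed (possibly more than once, e.g. on homeologous chromosomes of a
polyploid reference) and all remaining gene classes are appended with
explanatory flags. The result exposes gene presence-absence (PAV) and copy
number (CNV) across genomes.

Member flags: ``synOg`` direct syntenic member of the placed cluster;
``indirectSyn`` syntenic orthogroup member without a direct placed
position; ``arrayMember`` non-representative tandem-array member;
``NSOrtho`` non-syntenic ortholog added from an optional ortholog list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LONG_COLUMNS = ["pg_id", "ref_chrom", "ref_ord", "ref_bp", "sog_id",
                "genome", "gene_id", "flag"]


@dataclass
class PanGenome:
    ref: str
    entries_long: pd.DataFrame
    entries_wide: pd.DataFrame
    unplaced: list[str]

    def pav_cnv(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return pav_cnv_matrix(self.entries_long)


def build_reference_backbone(ref_genes: pd.DataFrame) -> pd.DataFrame:
    """Reference tandem-array representatives with (chrom, ord, array_ord,
    bp): the coordinate system everything else is placed on."""
    reps = ref_genes.loc[ref_genes["is_array_rep"]].copy()
    if len(reps) == 0:
        raise ValueError("reference genome has no representative genes")
    reps = reps.sort_values(["chrom", "ord"], kind="mergesort")
    return reps[["gene_id", "chrom", "ord", "array_ord", "start", "end"]] \
        .reset_index(drop=True)


def ref_anchor_pairs(hits: pd.DataFrame, ref: str) -> pd.DataFrame:
    """Final syntenic anchors of one (ref, other) pair oriented as
    (nonref gene/chrom/rank, ref chrom/rank, block orientation)."""
    a = hits.loc[hits["is_anchor"]]
    if len(a) == 0:
        return pd.DataFrame(columns=["gene", "chrom", "t_ord", "ref_chrom",
                                     "r_ord", "blk_id", "orientation"])
    if a["genome_q"].iat[0] == ref:
        out = pd.DataFrame({
            "gene": a["target"], "chrom": a["chrom_t"], "t_ord": a["array_ord_t"],
            "ref_chrom": a["chrom_q"], "r_ord": a["array_ord_q"],
            "blk_id": a["blk_id"], "orientation": a["orientation"]})
    else:
        out = pd.DataFrame({
            "gene": a["query"], "chrom": a["chrom_q"], "t_ord": a["array_ord_q"],
            "ref_chrom": a["chrom_t"], "r_ord": a["array_ord_t"],
            "blk_id": a["blk_id"], "orientation": a["orientation"]})
    return out.reset_index(drop=True)


def _one_to_one_anchors(anchors: pd.DataFrame) -> pd.DataFrame:
    """Subset anchors to a 1:1 mapping: anchors sharing a nonref or
    reference rank with another anchor (non-1:1 mapping ratio) are dropped,
    keeping the first by (block, rank) order. Sorted by nonref rank."""
    sub = anchors.sort_values(["blk_id", "t_ord"], kind="mergesort")
    sub = sub.drop_duplicates("t_ord").drop_duplicates("r_ord")
    return sub.sort_values(["t_ord", "r_ord"], kind="mergesort")


def _one_to_one_clusters(anchors: pd.DataFrame) -> list[pd.DataFrame]:
    """1:1 anchors split into collinear clusters wherever either axis
    jumps by more than one rank between adjacent anchors."""
    kept = _one_to_one_anchors(anchors)
    if len(kept) == 0:
        return []
    dt = kept["t_ord"].diff().to_numpy()
    dr = kept["r_ord"].diff().to_numpy()
    new_cluster = np.ones(len(kept), dtype=bool)
    new_cluster[1:] = (np.abs(dt[1:]) > 1) | (np.abs(dr[1:]) > 1)
    ids = np.cumsum(new_cluster)
    return [kept.loc[ids == k] for k in np.unique(ids)]


def _cluster_orientation(cl: pd.DataFrame) -> int:
    if len(cl) >= 2:
        return 1 if cl["r_ord"].iloc[-1] >= cl["r_ord"].iloc[0] else -1
    return 1 if cl["orientation"].iloc[0] == "+" else -1


def interpolate_positions(anchors: pd.DataFrame, nonref_genes: pd.DataFrame,
                          params) -> pd.DataFrame:
    """Interpolated reference rank for every nonref array representative.

    A gene at rank t between flanking 1:1 anchors (t1 -> r1, t2 -> r2)
    receives r1 + (t - t1) * (r2 - r1) / (t2 - t1), provided both flanking
    gaps are spannable (within ``syn_buff`` on both axes) — this bridges
    the small rank gaps that gene loss leaves on either genome, which is
    precisely the presence-absence variation the pan-genome has to mask.
    Beyond terminal anchors (or across unspannable gaps) the nearest
    anchor extrapolates at unit slope in its cluster's orientation, up to
    ``syn_buff`` away. Genes out of reach of every anchor get no position.
    One position is produced per reachable reference chromosome.
    """
    reps = nonref_genes.loc[nonref_genes["is_array_rep"]]
    out_rows = []
    for (chrom, ref_chrom), sub in anchors.groupby(["chrom", "ref_chrom"],
                                                   sort=True):
        clusters = _one_to_one_clusters(sub)
        if not clusters:
            continue
        ts = np.concatenate([cl["t_ord"].to_numpy(float) for cl in clusters])
        rs = np.concatenate([cl["r_ord"].to_numpy(float) for cl in clusters])
        signs = np.concatenate([
            np.full(len(cl), _cluster_orientation(cl)) for cl in clusters])
        order = np.argsort(ts, kind="mergesort")
        ts, rs, signs = ts[order], rs[order], signs[order]
        genes = reps.loc[reps["chrom"] == chrom]
        anchor_genes = set(sub["gene"])
        for gid, t in zip(genes["gene_id"].to_numpy(),
                          genes["array_ord"].to_numpy(float)):
            j = np.searchsorted(ts, t)
            if j < len(ts) and ts[j] == t:
                pos, dist = rs[j], 0.0
            else:
                left = j - 1 if j > 0 else None
                right = j if j < len(ts) else None
                dl = t - ts[left] if left is not None else np.inf
                dr_ = ts[right] - t if right is not None else np.inf
                span_ok = (left is not None and right is not None
                           and ts[right] - ts[left] <= params.syn_buff
                           and abs(rs[right] - rs[left]) <= params.syn_buff)
                if span_ok:
                    t1, t2 = ts[left], ts[right]
                    r1, r2 = rs[left], rs[right]
                    pos = r1 + (t - t1) * (r2 - r1) / (t2 - t1)
                    dist = min(dl, dr_)
                elif min(dl, dr_) <= params.syn_buff:
                    # unit-slope extrapolation from the nearest anchor
                    # (equidistant ties go to the lower-rank anchor)
                    k = left if dl <= dr_ else right
                    pos = rs[k] + signs[k] * (t - ts[k])
                    dist = min(dl, dr_)
                else:
                    continue
            out_rows.append((gid, genes["genome"].iat[0], chrom, ref_chrom,
                             float(pos), float(dist),
                             "anchor" if dist == 0 else "interpolated"))
    out = pd.DataFrame(out_rows, columns=[
        "gene_id", "genome", "chrom", "ref_chrom", "ref_ord", "dist", "source"])
    # one candidate per (gene, ref_chrom), then keep only the gene's
    # best-supported placements: a direct anchor (distance 0) beats any
    # interpolated position — e.g. a translocated gene must follow its own
    # syntenic block, not the gap it left behind — while equally supported
    # placements (a gene anchored on two homeologous reference
    # chromosomes) are all retained
    out = (out.sort_values(["gene_id", "ref_chrom", "dist", "ref_ord"],
                           kind="mergesort")
              .drop_duplicates(["gene_id", "ref_chrom"]))
    best = out.groupby("gene_id")["dist"].transform("min")
    out = out.loc[out["dist"] == best].reset_index(drop=True)
    return out[["gene_id", "genome", "chrom", "ref_chrom", "ref_ord", "source"]]


def backbone_positions(backbone: pd.DataFrame, ref: str) -> pd.DataFrame:
    """The reference genome's own representatives as exact positions."""
    return pd.DataFrame({
        "gene_id": backbone["gene_id"], "genome": ref,
        "chrom": backbone["chrom"], "ref_chrom": backbone["chrom"],
        "ref_ord": backbone["array_ord"].astype(float), "source": "backbone"})


def place_orthogroups(sogs: pd.DataFrame, positions: pd.DataFrame,
                      params) -> pd.DataFrame:
    """Cluster each syntenic orthogroup's member positions and choose its
    pan-genome placements.

    Positions are split by reference chromosome, then at rank gaps >
    ``syn_buff``. Multi-cluster groups keep clusters holding at least
    ``prop_assign_thresh`` of positioned members (falling back to the
    largest cluster if none qualifies) and at most
    ``max_placements_per_ref_chr`` per chromosome (ranked by proportion,
    then size, then lower rank). Each kept cluster becomes one entry at the
    median member rank.
    """
    pos = positions.merge(
        sogs.loc[sogs["provenance"] == "direct", ["gene_id", "sog_id"]],
        on="gene_id", how="inner")
    rows = []
    for sog, sub in pos.groupby("sog_id", sort=True):
        n_pos = sub["gene_id"].nunique()
        clusters = []
        for ref_chrom, csub in sub.groupby("ref_chrom", sort=True):
            csub = csub.sort_values(["ref_ord", "gene_id"], kind="mergesort")
            gaps = np.flatnonzero(np.diff(csub["ref_ord"].to_numpy())
                                  > params.syn_buff) + 1
            for part in np.split(np.arange(len(csub)), gaps):
                cl = csub.iloc[part]
                clusters.append((ref_chrom, cl))
        if len(clusters) > 1:
            scored = []
            for ref_chrom, cl in clusters:
                prop = cl["gene_id"].nunique() / n_pos
                scored.append((prop, ref_chrom, cl))
            kept = [(p, rc, cl) for p, rc, cl in scored
                    if p >= params.prop_assign_thresh]
            if not kept:
                kept = [max(scored,
                            key=lambda s: (len(s[2]), -s[2]["ref_ord"].min()))]
            by_chr: dict[str, list] = {}
            for item in kept:
                by_chr.setdefault(item[1], []).append(item)
            clusters = []
            for rc in sorted(by_chr):
                ranked = sorted(
                    by_chr[rc],
                    key=lambda s: (-s[0], -len(s[2]), s[2]["ref_ord"].min()))
                clusters.extend((rc, cl) for _p, rc2, cl in
                                ranked[:params.max_placements_per_ref_chr])
        else:
            clusters = [(rc, cl) for rc, cl in clusters]
        for ref_chrom, cl in clusters:
            members = sorted(cl["gene_id"].unique())
            rows.append({"sog_id": sog, "ref_chrom": ref_chrom,
                         "ref_ord": float(np.median(cl["ref_ord"])),
                         "members": members})
    return pd.DataFrame(rows, columns=["sog_id", "ref_chrom", "ref_ord",
                                       "members"])


def finalize_pangenome(entries: pd.DataFrame, sogs: pd.DataFrame,
                       genomes: dict[str, pd.DataFrame],
                       backbone: pd.DataFrame, ref: str,
                       orthologs: pd.DataFrame | None = None,
                       ) -> PanGenome:
    """Assemble the long/wide pan-genome annotation.

    Adds indirect syntenic members, position-less orthogroups (null
    positions), non-representative tandem-array members, and (optionally)
    non-syntenic orthologs; everything else is reported as unplaced.
    """
    gene_genome = {g: name for name, df in genomes.items()
                   for g in df["gene_id"]}
    placed_members: dict[str, int] = {}
    records: list[dict] = []
    entry_sizes: dict[int, int] = {}

    def add(entry_idx, gene, flag):
        if gene in placed_members:
            return
        placed_members[gene] = entry_idx
        entry_sizes[entry_idx] = entry_sizes.get(entry_idx, 0) + 1
        records.append({"entry": entry_idx, "gene_id": gene, "flag": flag,
                        "genome": gene_genome.get(gene)})

    entry_meta: list[dict] = []
    entry_of_sog: dict[str, list[int]] = {}
    for _, row in entries.sort_values(["sog_id", "ref_chrom", "ref_ord"],
                                      kind="mergesort").iterrows():
        idx = len(entry_meta)
        entry_meta.append({"sog_id": row["sog_id"], "ref_chrom": row["ref_chrom"],
                           "ref_ord": row["ref_ord"]})
        entry_of_sog.setdefault(row["sog_id"], []).append(idx)
        for g in row["members"]:
            add(idx, g, "synOg")

    direct = sogs.loc[sogs["provenance"] == "direct"]
    for sog, sub in direct.groupby("sog_id", sort=True):
        own = entry_of_sog.get(sog)
        if own is None:
            # orthogroup with no interpolated position at all
            idx = len(entry_meta)
            entry_meta.append({"sog_id": sog, "ref_chrom": None,
                               "ref_ord": np.nan})
            entry_of_sog[sog] = [idx]
            for g in sorted(sub["gene_id"]):
                add(idx, g, "synOg")
        else:
            # members that missed every placed cluster -> indirect, attached
            # to the sog's largest entry
            target = max(own, key=lambda i: (entry_sizes.get(i, 0), -i))
            for g in sorted(sub["gene_id"]):
                add(target, g, "indirectSyn")

    arr = sogs.loc[sogs["provenance"] == "array"]
    rep_of: dict[str, str] = {}
    members_of: dict[str, list[str]] = {}
    for name, df in genomes.items():
        sub = df.loc[df["array_id"].notna()]
        reps = sub.loc[sub["is_array_rep"]].set_index("array_id")["gene_id"]
        nonrep = sub.loc[~sub["is_array_rep"]]
        for gid, aid in zip(nonrep["gene_id"], nonrep["array_id"]):
            rep = reps.get(aid)
            rep_of[gid] = rep
            if rep is not None:
                members_of.setdefault(rep, []).append(gid)
    for g in sorted(arr["gene_id"]):
        rep = rep_of.get(g)
        if rep is not None and rep in placed_members:
            add(placed_members[rep], g, "arrayMember")

    # reference representatives without any syntenic orthogroup still get a
    # backbone entry: the reference defines the coordinate system, and
    # "absent in every other genome" is itself a PAV observation
    bb = backbone.set_index("gene_id")
    for g in backbone["gene_id"]:
        if g in placed_members:
            continue
        idx = len(entry_meta)
        entry_meta.append({"sog_id": f"refonly_{g}",
                           "ref_chrom": bb.loc[g, "chrom"],
                           "ref_ord": float(bb.loc[g, "array_ord"])})
        add(idx, g, "synOg")
        for member in sorted(members_of.get(g, [])):
            add(idx, member, "arrayMember")

    if orthologs is not None and len(orthologs):
        for a, b in orthologs[["gene_a", "gene_b"]].itertuples(index=False):
            if a in placed_members and b not in placed_members:
                add(placed_members[a], b, "NSOrtho")
            elif b in placed_members and a not in placed_members:
                add(placed_members[b], a, "NSOrtho")

    # deterministic entry ids ordered along the reference
    meta = pd.DataFrame(entry_meta)
    meta["entry"] = np.arange(len(meta))
    meta["_chrom_key"] = meta["ref_chrom"].fillna("~~unplaced")
    meta = meta.sort_values(["_chrom_key", "ref_ord", "sog_id"],
                            kind="mergesort", na_position="last")
    meta["pg_id"] = [f"pg{i + 1:06d}" for i in range(len(meta))]
    id_of = meta.set_index("entry")["pg_id"]

    bp_lookup = {}
    for chrom, sub in backbone.groupby("chrom"):
        bp_lookup[chrom] = (sub["array_ord"].to_numpy(float),
                            sub["start"].to_numpy())

    def ref_bp(chrom, ref_ord):
        if chrom is None or chrom not in bp_lookup or not np.isfinite(ref_ord):
            return None
        ords, starts = bp_lookup[chrom]
        j = int(np.clip(np.searchsorted(ords, ref_ord), 0, len(ords) - 1))
        if j > 0 and abs(ords[j - 1] - ref_ord) <= abs(ords[j] - ref_ord):
            j -= 1
        return int(starts[j])

    meta["ref_bp"] = [ref_bp(c, o) for c, o in
                      zip(meta["ref_chrom"], meta["ref_ord"])]
    meta_idx = meta.set_index("entry")

    long_rows = []
    for r in records:
        m = meta_idx.loc[r["entry"]]
        long_rows.append((m["pg_id"], m["ref_chrom"], m["ref_ord"], m["ref_bp"],
                          m["sog_id"], r["genome"], r["gene_id"], r["flag"]))
    long_df = pd.DataFrame(long_rows, columns=LONG_COLUMNS)
    long_df = long_df.sort_values(["pg_id", "genome", "gene_id"],
                                  kind="mergesort").reset_index(drop=True)

    genome_names = sorted(genomes)
    wide_rows = []
    for pg, sub in long_df.groupby("pg_id", sort=True):
        row = {"pg_id": pg, "ref_chrom": sub["ref_chrom"].iat[0],
               "ref_ord": sub["ref_ord"].iat[0], "ref_bp": sub["ref_bp"].iat[0],
               "sog_id": sub["sog_id"].iat[0]}
        for g in genome_names:
            row[g] = ",".join(sorted(sub.loc[sub["genome"] == g, "gene_id"]))
        wide_rows.append(row)
    wide_df = pd.DataFrame(wide_rows, columns=[
        "pg_id", "ref_chrom", "ref_ord", "ref_bp", "sog_id", *genome_names])

    all_genes = set(gene_genome)
    unplaced = sorted(all_genes - set(placed_members))
    return PanGenome(ref=ref, entries_long=long_df, entries_wide=wide_df,
                     unplaced=unplaced)


def pav_cnv_matrix(entries_long: pd.DataFrame,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence-absence (bool) and copy-number (member count) matrices,
    entries x genomes. CNV >= 1 iff PAV is true."""
    cnv = (entries_long.groupby(["pg_id", "genome"])["gene_id"].size()
           .unstack(fill_value=0).sort_index())
    pav = cnv > 0
    return pav, cnv


def build_pangenome(genomes: dict[str, pd.DataFrame],
                    hit_tables: dict[tuple, pd.DataFrame],
                    sogs: pd.DataFrame, params, ref: str,
                    orthologs: pd.DataFrame | None = None) -> PanGenome:
    """Full pan-genome construction against one reference genome."""
    if ref not in genomes:
        raise ValueError(f"reference genome {ref!r} is not part of this run")
    backbone = build_reference_backbone(genomes[ref])
    positions = [backbone_positions(backbone, ref)]
    for pair in sorted(hit_tables):
        if ref not in pair or pair[0] == pair[1]:
            continue
        other = pair[0] if pair[1] == ref else pair[1]
        anchors = ref_anchor_pairs(hit_tables[pair], ref)
        positions.append(
            interpolate_positions(anchors, genomes[other], params))
    pos = pd.concat(positions, ignore_index=True)
    entries = place_orthogroups(sogs, pos, params)
    return finalize_pangenome(entries, sogs, genomes, backbone, ref,
                              orthologs=orthologs)
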