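"""Syntenic anchor and block inference.

Hits are decorated with rank positions, orthogroup agreement and score
ranks; "potential anchors" (top-scoring orthogroup-consistent hits between
tandem-array representatives) are chained into collinear runs in condensed
rank space; chains are cleaned, clustered with DBSCAN into blocks and
regions, and every hit near an anchor is flagged as in the syntenic buffer.

Collinearity is scored by hit count under per-axis gap caps: consecutive
chain members must satisfy (dx - 1) <= n_gaps and (|dy| - 1) <= n_gaps with
x strictly increasing and y strictly monotone. Chains are extracted
greedily by descending score.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

log = logging.getLogger(__name__)

BLOCK_COLUMNS = [
    "blk_id", "reg_id", "genome_q", "genome_t", "chrom_q", "chrom_t",
    "orientation", "n_anchors", "min_ord_q", "max_ord_q", "min_ord_t",
    "max_ord_t", "start_bp_q", "end_bp_q", "start_bp_t", "end_bp_t",
    "is_secondary", "is_self",
]

HIT_FLAG_DEFAULTS = {
    "is_potential": False, "is_anchor": False, "in_buffer": False,
    "blk_id": None, "reg_id": None, "orientation": None,
}


def _empty_blocks() -> pd.DataFrame:
    return pd.DataFrame(columns=BLOCK_COLUMNS)


# ------------------------------------------------------------- annotation

def annotate_hits(hits: pd.DataFrame, genes_q: pd.DataFrame,
                  genes_t: pd.DataFrame, og_map=None) -> pd.DataFrame:
    """Decorate raw hits with positions, array representativeness,
    orthogroup agreement and score ranks.

    ``scr_rank`` is the dense rank of bitscore among all hits sharing the
    query (resp. target) gene, descending; equal bitscores share a rank.
    Hits whose genes were QC-dropped are silently excluded (counted in the
    log). Gene tables must already carry ``array_ord_eff``.
    """
    qcols = genes_q.set_index("gene_id")[
        ["genome", "chrom", "ord", "array_ord_eff", "is_array_rep",
         "start", "end", "og"]]
    tcols = genes_t.set_index("gene_id")[
        ["genome", "chrom", "ord", "array_ord_eff", "is_array_rep",
         "start", "end", "og"]]
    h = hits.copy()
    n0 = len(h)
    keep = h["query"].isin(qcols.index) & h["target"].isin(tcols.index)
    h = h.loc[keep].reset_index(drop=True)
    if len(h) < n0:
        log.info("annotate_hits: excluded %d hits on QC-dropped genes", n0 - len(h))
    q = qcols.loc[h["query"]].reset_index(drop=True)
    t = tcols.loc[h["target"]].reset_index(drop=True)
    h["genome_q"], h["genome_t"] = q["genome"].to_numpy(), t["genome"].to_numpy()
    h["chrom_q"], h["chrom_t"] = q["chrom"].to_numpy(), t["chrom"].to_numpy()
    h["ord_q"], h["ord_t"] = q["ord"].to_numpy(), t["ord"].to_numpy()
    h["array_ord_q"] = q["array_ord_eff"].to_numpy()
    h["array_ord_t"] = t["array_ord_eff"].to_numpy()
    h["is_rep_q"] = q["is_array_rep"].to_numpy()
    h["is_rep_t"] = t["is_array_rep"].to_numpy()
    h["start_q"], h["end_q"] = q["start"].to_numpy(), q["end"].to_numpy()
    h["start_t"], h["end_t"] = t["start"].to_numpy(), t["end"].to_numpy()
    if og_map is not None:
        og_q = h["query"].map(lambda g: og_map.get(g))
        og_t = h["target"].map(lambda g: og_map.get(g))
    else:
        og_q, og_t = q["og"].reset_index(drop=True), t["og"].reset_index(drop=True)
    h["og_q"], h["og_t"] = og_q, og_t
    h["is_og"] = og_q.notna() & (og_q == og_t)
    h["scr_rank_q"] = (h.groupby("query")["bitscore"]
                       .rank(method="dense", ascending=False).astype(int))
    h["scr_rank_t"] = (h.groupby("target")["bitscore"]
                       .rank(method="dense", ascending=False).astype(int))
    for col, val in HIT_FLAG_DEFAULTS.items():
        h[col] = val
    return h


def flag_potential_anchors(hits: pd.DataFrame, params,
                           mask: pd.Series | np.ndarray | None = None,
                           ) -> pd.DataFrame:
    """Flag hits eligible as syntenic anchors: both genes are array
    representatives, the hit is not masked, score ranks pass the per-gene
    hit caps, and (optionally) both genes share an orthogroup."""
    h = hits.copy()
    n1, n2 = params.resolve_n_hits(h["genome_q"].iat[0] if len(h) else "",
                                   h["genome_t"].iat[0] if len(h) else "")
    pot = (h["is_rep_q"] & h["is_rep_t"]
           & (h["scr_rank_q"] <= n1) & (h["scr_rank_t"] <= n2))
    if params.only_og_anchors:
        pot &= h["is_og"]
    if mask is not None:
        pot &= ~np.asarray(mask, bool)
    h["is_potential"] = pot.to_numpy()
    return h


# --------------------------------------------------------------- chaining

def _best_chain(x: np.ndarray, y: np.ndarray, n_gaps: int, sign: int):
    """Max-hit-count chain on points sorted by (x, y): x strictly
    increasing, y strictly monotone in ``sign`` direction, per-axis gap
    <= n_gaps. First maximal endpoint/predecessor in sort order, so the
    result is deterministic."""
    n = len(x)
    if n == 0:
        return None
    g = n_gaps + 1
    dp = np.ones(n, dtype=np.int64)
    pred = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        dx = x[i] - x[:i]
        dy = (y[i] - y[:i]) * sign
        ok = (dx >= 1) & (dx <= g) & (dy >= 1) & (dy <= g)
        if ok.any():
            idx = np.flatnonzero(ok)
            j = idx[np.argmax(dp[idx])]
            dp[i] = dp[j] + 1
            pred[i] = j
    end = int(np.argmax(dp))
    chain = []
    while end != -1:
        chain.append(end)
        end = int(pred[end])
    return np.asarray(chain[::-1], dtype=np.int64)


def chain_collinear(x, y, blk_size: int, n_gaps: int,
                    ) -> list[tuple[np.ndarray, str]]:
    """Greedy extraction of maximal-scoring collinear chains.

    Returns ``[(indices_into_input, orientation), ...]`` with chains of
    fewer than ``blk_size`` hits discarded. Ties between the best "+" and
    "-" chain go to the one with smaller (min x, min y), then "+".
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = len(x)
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    avail = np.ones(n, dtype=bool)
    chains: list[tuple[np.ndarray, str]] = []
    while int(avail.sum()) >= blk_size:
        pool = np.flatnonzero(avail)
        xa, ya = xs[pool], ys[pool]
        best = None
        for sign, orient in ((1, "+"), (-1, "-")):
            ch = _best_chain(xa, ya, n_gaps, sign)
            if ch is None:
                continue
            key = (-len(ch), int(xa[ch].min()), int(ya[ch].min()),
                   0 if sign == 1 else 1)
            if best is None or key < best[0]:
                best = (key, ch, orient)
        if best is None or len(best[1]) < blk_size:
            break
        sel = pool[best[1]]
        chains.append((order[sel], best[2]))
        avail[sel] = False
    return chains


def _dense_rank(a: np.ndarray) -> np.ndarray:
    _, inv = np.unique(a, return_inverse=True)
    return inv + 1


def _condensed_coords(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Condensed gene rank order over a whole potential-anchor table:
    dense rank of (chrom, array rank) per genome side. Condensing over the
    full table (rather than per chromosome pair) keeps sparse
    cross-chromosome hit sets sparse — a handful of random hits between
    two chromosomes must not collapse onto a tight grid that chains."""
    cx = pd.factorize(
        pd.MultiIndex.from_arrays([df["chrom_q"], df["array_ord_q"]]),
        sort=True)[0] + 1
    cy = pd.factorize(
        pd.MultiIndex.from_arrays([df["chrom_t"], df["array_ord_t"]]),
        sort=True)[0] + 1
    return cx, cy


def _dedup_xy(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the highest-bitscore hit per (array_ord_q, array_ord_t)."""
    return (df.sort_values(["array_ord_q", "array_ord_t", "bitscore"],
                           ascending=[True, True, False], kind="mergesort")
              .drop_duplicates(["array_ord_q", "array_ord_t"]))


def define_initial_anchors(hits: pd.DataFrame, params) -> pd.DataFrame:
    """Chain potential anchors per chromosome pair in condensed rank space
    and flag members of retained chains as initial anchors."""
    h = hits.copy()
    h["is_anchor"] = False
    pot = h.loc[h["is_potential"]]
    if len(pot) == 0:
        return h
    pot = pot.copy()
    pot["cx"], pot["cy"] = _condensed_coords(pot)
    anchor_idx = []
    for _, grp in pot.groupby(["chrom_q", "chrom_t"], sort=True):
        grp = _dedup_xy(grp)
        for idx, _orient in chain_collinear(grp["cx"].to_numpy(),
                                            grp["cy"].to_numpy(),
                                            params.blk_size, params.n_gaps):
            anchor_idx.append(grp.index.to_numpy()[idx])
    if anchor_idx:
        h.loc[np.concatenate(anchor_idx), "is_anchor"] = True
    return h


# ------------------------------------------------------------ refinement

def _dbscan_labels(coords: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels, deterministic: points are clustered in sorted (x, y)
    order and labels renumbered by first occurrence."""
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    lab_sorted = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords[order])
    labels = np.empty(len(coords), dtype=np.int64)
    labels[order] = lab_sorted
    # renumber by first occurrence in sorted order
    remap, nxt = {-1: -1}, 0
    out = np.empty_like(labels)
    for pos in order:
        l = labels[pos]
        if l not in remap:
            remap[l] = nxt
            nxt += 1
    for i, l in enumerate(labels):
        out[i] = remap[l]
    return out


def _chebyshev_near(points: np.ndarray, anchors: np.ndarray,
                    radius: float) -> np.ndarray:
    """Boolean mask: point within Chebyshev ``radius`` of any anchor."""
    if len(anchors) == 0 or len(points) == 0:
        return np.zeros(len(points), dtype=bool)
    tree = cKDTree(anchors)
    d, _ = tree.query(points, k=1, p=np.inf)
    return d <= radius


def refine_blocks(hits: pd.DataFrame, params) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean initial anchors, cluster them into blocks and regions, and
    assign every final anchor exactly one block id.

    Per chromosome pair: (1) potential anchors within ``syn_buff``
    (Chebyshev, array-rank space) of an initial anchor are re-chained into
    cleaned anchors; (2) cleaned anchors are DBSCAN-clustered
    (eps=syn_buff, minPts=blk_size) and small clusters dropped; (3)
    chaining is rerun within each cluster giving the final anchors; (4)
    regions come from a coarse DBSCAN pass (eps=syn_buff) and chains are
    split into sub-blocks at re-ranked gaps > blk_size; (5) overlapping
    blocks within a region are resolved by majority-run reassignment.
    """
    h = hits.copy()
    h["is_anchor_initial"] = h["is_anchor"]
    h["is_anchor"] = False
    h["blk_id"] = None
    h["reg_id"] = None
    h["orientation"] = None
    gq = h["genome_q"].iat[0] if len(h) else "?"
    gt = h["genome_t"].iat[0] if len(h) else "?"
    block_rows = []
    pot = h.loc[h["is_potential"]]
    for (cq, ct), grp in pot.groupby(["chrom_q", "chrom_t"], sort=True):
        init = grp.loc[grp["is_anchor_initial"]]
        if len(init) == 0:
            continue
        grp = _dedup_xy(grp)
        pts = grp[["array_ord_q", "array_ord_t"]].to_numpy(float)
        apts = init[["array_ord_q", "array_ord_t"]].to_numpy(float)
        near = grp.loc[_chebyshev_near(pts, apts, params.syn_buff)]
        if len(near) == 0:
            continue
        # (1) re-chain the buffered potential anchors -> cleaned anchors
        x = _dense_rank(near["array_ord_q"].to_numpy())
        y = _dense_rank(near["array_ord_t"].to_numpy())
        cleaned_idx = []
        for idx, _ in chain_collinear(x, y, params.blk_size, params.n_gaps):
            cleaned_idx.append(near.index.to_numpy()[idx])
        if not cleaned_idx:
            continue
        cleaned = near.loc[np.concatenate(cleaned_idx)]
        # (2) cluster cleaned anchors into block neighborhoods
        coords = cleaned[["array_ord_q", "array_ord_t"]].to_numpy(float)
        labels = _dbscan_labels(coords, params.syn_buff, params.blk_size)
        # (3) final chaining within each retained cluster
        final_rows, chain_orient = [], {}
        chain_serial = 0
        for lab in sorted(set(labels) - {-1}):
            sub = cleaned.loc[labels == lab]
            xs = _dense_rank(sub["array_ord_q"].to_numpy())
            ys = _dense_rank(sub["array_ord_t"].to_numpy())
            for idx, orient in chain_collinear(xs, ys, params.blk_size,
                                               params.n_gaps):
                rows = sub.index.to_numpy()[idx]
                final_rows.append((rows, chain_serial))
                chain_orient[chain_serial] = orient
                chain_serial += 1
        if not final_rows:
            continue
        fr = np.concatenate([r for r, _ in final_rows])
        fchain = np.concatenate([np.full(len(r), c) for r, c in final_rows])
        fin = h.loc[fr, ["array_ord_q", "array_ord_t"]].copy()
        fin["chain"] = fchain
        # (4) regions: coarse clustering of final anchors
        fcoords = fin[["array_ord_q", "array_ord_t"]].to_numpy(float)
        rlab = _dbscan_labels(fcoords, params.syn_buff, 1)
        reg_order = (fin.assign(r=rlab).groupby("r")
                     .agg(mq=("array_ord_q", "min"), mt=("array_ord_t", "min"))
                     .sort_values(["mq", "mt"]).index.to_numpy())
        for ri, rl in enumerate(reg_order):
            reg_id = f"{gq}|{gt}|{cq}|{ct}|r{ri}"
            rsub = fin.loc[rlab == rl].copy()
            rsub["xr"] = _dense_rank(rsub["array_ord_q"].to_numpy())
            rsub["yr"] = _dense_rank(rsub["array_ord_t"].to_numpy())
            blk_of = _split_chains_into_blocks(rsub, params.blk_size)
            blk_of = _resolve_block_overlaps(rsub, blk_of, params.blk_size)
            # deterministic block ids ordered by min xr
            rsub["blk"] = blk_of
            order = (rsub.groupby("blk")["xr"].min().sort_values(kind="mergesort")
                     .index.to_numpy())
            for bi, bl in enumerate(order):
                rows = rsub.index[rsub["blk"] == bl]
                blk_id = f"{reg_id}b{bi}"
                chain_ids = fin.loc[rows, "chain"]
                ors = chain_ids.map(chain_orient)
                orient = ors.mode().iat[0] if len(ors) else "+"
                h.loc[rows, "is_anchor"] = True
                h.loc[rows, "blk_id"] = blk_id
                h.loc[rows, "reg_id"] = reg_id
                h.loc[rows, "orientation"] = orient
                block_rows.append({"blk_id": blk_id, "reg_id": reg_id,
                                   "chrom_q": cq, "chrom_t": ct,
                                   "orientation": orient})
    h = h.drop(columns=["is_anchor_initial"])
    blocks = _blocks_from_anchors(h, pd.DataFrame(block_rows), gq, gt)
    return h, blocks


def _split_chains_into_blocks(rsub: pd.DataFrame, blk_size: int) -> np.ndarray:
    """Split each chain at re-ranked Chebyshev gaps > blk_size; fragments
    smaller than blk_size are merged back into the preceding fragment."""
    blk = np.empty(len(rsub), dtype=object)
    pos = {ix: i for i, ix in enumerate(rsub.index)}
    for chain, sub in rsub.groupby("chain", sort=True):
        sub = sub.sort_values(["xr", "yr"], kind="mergesort")
        xr = sub["xr"].to_numpy()
        yr = sub["yr"].to_numpy()
        gaps = np.maximum(np.abs(np.diff(xr)), np.abs(np.diff(yr)))
        cuts = np.flatnonzero(gaps > blk_size) + 1
        frags = np.split(np.arange(len(sub)), cuts)
        merged: list[np.ndarray] = []
        for f in frags:
            if merged and len(f) < blk_size:
                merged[-1] = np.concatenate([merged[-1], f])
            else:
                merged.append(f)
        if len(merged) > 1 and len(merged[0]) < blk_size:
            merged[1] = np.concatenate([merged[0], merged[1]])
            merged = merged[1:]
        for j, f in enumerate(merged):
            for ix in sub.index.to_numpy()[f]:
                blk[pos[ix]] = f"{chain}.{j}"
    return blk


def _resolve_block_overlaps(rsub: pd.DataFrame, blk_of: np.ndarray,
                            blk_size: int) -> np.ndarray:
    """Majority-run reassignment of anchors where two blocks of one region
    overlap on the query axis: overlap anchors go to the block holding the
    longest consecutive run there; a loser split into disjoint remainders
    becomes separate blocks (small remainders join the winner)."""
    out = blk_of.copy()
    df = rsub.assign(b=pd.Series(list(blk_of), index=rsub.index))
    df = df.sort_values(["xr", "yr"], kind="mergesort")
    changed = True
    guard = 0
    while changed and guard < 10:
        changed = False
        guard += 1
        spans = {}
        for b in pd.unique(df["b"]):
            xs = df.loc[df["b"] == b, "xr"]
            spans[b] = (xs.min(), xs.max())
        bl = sorted(spans, key=lambda b: (spans[b], str(b)))
        for i in range(len(bl)):
            for j in range(i + 1, len(bl)):
                b1, b2 = bl[i], bl[j]
                lo = max(spans[b1][0], spans[b2][0])
                hi = min(spans[b1][1], spans[b2][1])
                if lo > hi:
                    continue
                inwin = df.loc[(df["xr"] >= lo) & (df["xr"] <= hi)
                               & df["b"].isin([b1, b2])]
                runs = (inwin["b"] != inwin["b"].shift()).cumsum()
                run_len = inwin.groupby(runs).agg(b=("b", "first"),
                                                  n=("b", "size"))
                winner = run_len.sort_values(["n"], ascending=False).iloc[0]["b"]
                loser = b2 if winner == b1 else b1
                move = inwin.index[inwin["b"] == loser]
                if len(move) == 0:
                    continue
                df.loc[move, "b"] = winner
                changed = True
                # split loser remainder into contiguous pieces
                rem = df.loc[df["b"] == loser].sort_values("xr")
                if len(rem):
                    gaps = np.flatnonzero(
                        np.diff(rem["xr"].to_numpy()) > blk_size) + 1
                    pieces = np.split(np.arange(len(rem)), gaps)
                    for k, piece in enumerate(pieces[1:], start=1):
                        ids = rem.index.to_numpy()[piece]
                        if len(ids) >= blk_size:
                            df.loc[ids, "b"] = f"{loser}.s{k}"
                        else:
                            df.loc[ids, "b"] = winner
                break
            if changed:
                break
    final = df["b"]
    pos = {ix: i for i, ix in enumerate(rsub.index)}
    for ix, b in final.items():
        out[pos[ix]] = b
    return out


def _blocks_from_anchors(hits: pd.DataFrame, meta: pd.DataFrame,
                         gq: str, gt: str) -> pd.DataFrame:
    """Block table with rank and bp bounds computed from bounding anchors."""
    anchors = hits.loc[hits["is_anchor"]]
    if len(anchors) == 0 or len(meta) == 0:
        return _empty_blocks()
    agg = anchors.groupby("blk_id").agg(
        n_anchors=("blk_id", "size"),
        min_ord_q=("array_ord_q", "min"), max_ord_q=("array_ord_q", "max"),
        min_ord_t=("array_ord_t", "min"), max_ord_t=("array_ord_t", "max"),
        start_bp_q=("start_q", "min"), end_bp_q=("end_q", "max"),
        start_bp_t=("start_t", "min"), end_bp_t=("end_t", "max"))
    meta = meta.drop_duplicates("blk_id").set_index("blk_id")
    blocks = meta.join(agg, how="inner").reset_index()
    blocks["genome_q"], blocks["genome_t"] = gq, gt
    blocks["is_secondary"] = False
    blocks["is_self"] = False
    return blocks[BLOCK_COLUMNS].sort_values("blk_id").reset_index(drop=True)


# ------------------------------------------------------------ finalization

def finalize_hits(hits: pd.DataFrame, blocks: pd.DataFrame, params,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag every hit within Chebyshev ``syn_buff`` of an anchor as
    ``in_buffer`` and give it the nearest anchor's region id (ties to the
    lexicographically lower region id). Block coordinates are already the
    bounding-anchor extrema; region coordinates come from their blocks."""
    h = hits.copy()
    h["in_buffer"] = False
    for (cq, ct), grp in h.groupby(["chrom_q", "chrom_t"], sort=True):
        anchors = grp.loc[grp["is_anchor"]]
        if len(anchors) == 0:
            continue
        apts = anchors[["array_ord_q", "array_ord_t"]].to_numpy(float)
        regs = anchors["reg_id"].to_numpy()
        tree = cKDTree(apts)
        pts = grp[["array_ord_q", "array_ord_t"]].to_numpy(float)
        neighbor_lists = tree.query_ball_point(pts, r=params.syn_buff, p=np.inf)
        in_buf = np.zeros(len(grp), dtype=bool)
        reg_assign = np.empty(len(grp), dtype=object)
        for i, nb in enumerate(neighbor_lists):
            if not nb:
                reg_assign[i] = None
                continue
            d = np.max(np.abs(apts[nb] - pts[i]), axis=1)
            dmin = d.min()
            cand = sorted(regs[np.asarray(nb)[d == dmin]])
            in_buf[i] = True
            reg_assign[i] = cand[0]
        idx = grp.index
        h.loc[idx, "in_buffer"] = in_buf
        anchored = h.loc[idx, "is_anchor"].to_numpy()
        keep_reg = np.where(anchored, h.loc[idx, "reg_id"].to_numpy(), reg_assign)
        h.loc[idx, "reg_id"] = keep_reg
    return h, blocks


def region_table(blocks: pd.DataFrame) -> pd.DataFrame:
    """Region coordinates aggregated over member blocks."""
    if len(blocks) == 0:
        return pd.DataFrame(columns=[
            "reg_id", "genome_q", "genome_t", "chrom_q", "chrom_t",
            "n_blocks", "n_anchors", "min_ord_q", "max_ord_q", "min_ord_t",
            "max_ord_t", "start_bp_q", "end_bp_q", "start_bp_t", "end_bp_t"])
    agg = blocks.groupby("reg_id").agg(
        genome_q=("genome_q", "first"), genome_t=("genome_t", "first"),
        chrom_q=("chrom_q", "first"), chrom_t=("chrom_t", "first"),
        n_blocks=("blk_id", "size"), n_anchors=("n_anchors", "sum"),
        min_ord_q=("min_ord_q", "min"), max_ord_q=("max_ord_q", "max"),
        min_ord_t=("min_ord_t", "min"), max_ord_t=("max_ord_t", "max"),
        start_bp_q=("start_bp_q", "min"), end_bp_q=("end_bp_q", "max"),
        start_bp_t=("start_bp_t", "min"), end_bp_t=("end_bp_t", "max"))
    return agg.reset_index().sort_values("reg_id").reset_index(drop=True)


# -------------------------------------------------------------- pair scan

def run_pair_scan(hits: pd.DataFrame, params,
                  mask: pd.Series | np.ndarray | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steps 5-7 on an annotated hit table: potential anchors, initial
    chaining, block refinement and buffer finalization."""
    h = flag_potential_anchors(hits, params, mask=mask)
    h = define_initial_anchors(h, params)
    h, blocks = refine_blocks(h, params)
    h, blocks = finalize_hits(h, blocks, params)
    return h, blocks


# ----------------------------------------------------------- self synteny

def self_synteny(genes: pd.DataFrame, hits: pd.DataFrame | None, params,
                 genome: str) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Intragenomic synteny.

    Haploid genomes get identity blocks only (one per chromosome, ids =
    chromosome ids). For ploidy p > 1, hits within ``self_mask_radius`` of
    the identity diagonal are masked and the standard scan is rerun with
    p - 1 hits per gene to recover homeologous blocks.
    """
    p = params.ploidy_of(genome)
    if p < 1:
        raise ValueError(f"{genome}: ploidy must be >= 1")
    g = genes.loc[genes["genome"] == genome]
    rows = []
    for chrom, sub in g.groupby("chrom", sort=True):
        reps = sub.loc[sub["is_array_rep"]]
        rows.append({
            "blk_id": str(chrom), "reg_id": str(chrom), "genome_q": genome,
            "genome_t": genome, "chrom_q": chrom, "chrom_t": chrom,
            "orientation": "+", "n_anchors": int(len(reps)),
            "min_ord_q": float(reps["array_ord"].min()),
            "max_ord_q": float(reps["array_ord"].max()),
            "min_ord_t": float(reps["array_ord"].min()),
            "max_ord_t": float(reps["array_ord"].max()),
            "start_bp_q": int(sub["start"].min()), "end_bp_q": int(sub["end"].max()),
            "start_bp_t": int(sub["start"].min()), "end_bp_t": int(sub["end"].max()),
            "is_secondary": False, "is_self": True})
    identity = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    if p == 1 or hits is None:
        return hits, identity
    h = annotate_hits(hits, genes, genes)
    same_chrom = h["chrom_q"] == h["chrom_t"]
    mask = same_chrom & ((h["array_ord_q"] - h["array_ord_t"]).abs()
                         <= params.self_mask_radius)
    p_self = replace(params, n_hits1=p - 1, n_hits2=p - 1)
    h, blocks = run_pair_scan(h, p_self, mask=mask.to_numpy())
    blocks = blocks.assign(is_self=True)
    return h, pd.concat([identity, blocks], ignore_index=True)


# --------------------------------------------------------- secondary scan

def secondary_hits_scan(hits: pd.DataFrame, params,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paralog (e.g. WGD homeolog) scan: mask everything inside the primary
    syntenic buffer, then rerun the scan with the secondary parameter set
    and without requiring shared orthogroups."""
    if params.n_secondary_hits == 0:
        return hits.iloc[0:0].copy(), _empty_blocks()
    mask = hits["in_buffer"].to_numpy(bool)
    h = hits.copy()
    for col, val in HIT_FLAG_DEFAULTS.items():
        h[col] = val
    # score ranks recomputed on unmasked hits only
    um = ~mask
    h["scr_rank_q"] = np.iinfo(np.int32).max
    h["scr_rank_t"] = np.iinfo(np.int32).max
    h.loc[um, "scr_rank_q"] = (h.loc[um].groupby("query")["bitscore"]
                               .rank(method="dense", ascending=False).astype(int))
    h.loc[um, "scr_rank_t"] = (h.loc[um].groupby("target")["bitscore"]
                               .rank(method="dense", ascending=False).astype(int))
    h, blocks = run_pair_scan(h, params.secondary(), mask=mask)
    blocks = blocks.assign(is_secondary=True)
    blocks["blk_id"] = "sec:" + blocks["blk_id"].astype(str)
    blocks["reg_id"] = "sec:" + blocks["reg_id"].astype(str)
    for col in ("blk_id", "reg_id"):
        has = h[col].notna()
        h.loc[has, col] = "sec:" + h.loc[has, col].astype(str)
    return h, blocks
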