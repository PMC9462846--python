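"""Tandem-array detection and collapsing.

Physically proximate members of one orthogroup on one chromosome are
condensed to a single representative gene, and gene rank order is
recomputed over representatives (``array_ord``). This masks copy-number
noise from local duplications before synteny inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class TandemArray:
    array_id: str
    genome: str
    chrom: str
    og: str
    member_gene_ids: list[str]
    representative: str


def _gap_split(ords: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split sorted 1-D positions wherever an adjacent gap exceeds max_gap.

    Equivalent to DBSCAN in one dimension with eps=max_gap and minPts=1
    (chain reachability along the sorted axis).
    """
    if len(ords) == 0:
        return []
    cuts = np.flatnonzero(np.diff(ords) > max_gap) + 1
    return np.split(np.arange(len(ords)), cuts)


def find_tandem_arrays(genes: pd.DataFrame, params,
                       peptide_lengths: Mapping[str, int] | None = None,
                       ) -> tuple[list[TandemArray], pd.DataFrame]:
    """Detect tandem arrays and choose representatives.

    Candidate arrays are orthogroups with >1 gene on one (genome, chrom);
    candidates are split into separate arrays wherever the rank gap between
    adjacent members exceeds ``syn_buff``; clusters of >= 2 genes become
    arrays. The representative is the member closest to the median rank of
    the array, ties broken by longest peptide (if lengths are given) then
    lexicographically smallest gene id. Singletons stay their own
    representative.
    """
    genes = genes.copy()
    genes["is_array_rep"] = True
    genes["array_id"] = None
    arrays: list[TandemArray] = []
    has_og = genes["og"].notna()
    grouped = genes.loc[has_og].groupby(["genome", "chrom", "og"], sort=True)
    for (genome, chrom, og), grp in grouped:
        if len(grp) < 2:
            continue
        grp = grp.sort_values("ord", kind="mergesort")
        ords = grp["ord"].to_numpy()
        for k, cluster in enumerate(_gap_split(ords, params.syn_buff)):
            if len(cluster) < 2:
                continue
            members = grp.iloc[cluster]
            rep = _choose_representative(members, peptide_lengths)
            array_id = f"arr_{genome}_{chrom}_{og}_{k}"
            idx = members.index
            genes.loc[idx, "array_id"] = array_id
            genes.loc[idx, "is_array_rep"] = False
            genes.loc[genes["gene_id"] == rep, "is_array_rep"] = True
            arrays.append(TandemArray(
                array_id=array_id, genome=genome, chrom=chrom, og=og,
                member_gene_ids=list(members["gene_id"]), representative=rep))
    return arrays, genes


def _choose_representative(members: pd.DataFrame,
                           peptide_lengths: Mapping[str, int] | None) -> str:
    med = float(np.median(members["ord"].to_numpy()))
    dist = (members["ord"] - med).abs()
    if peptide_lengths:
        plen = members["gene_id"].map(lambda g: peptide_lengths.get(g, 0))
    else:
        plen = pd.Series(0, index=members.index)
    order = pd.DataFrame({
        "dist": dist, "neg_len": -plen, "gene_id": members["gene_id"]})
    order = order.sort_values(["dist", "neg_len", "gene_id"], kind="mergesort")
    return str(order["gene_id"].iloc[0])


def assign_array_ord(genes: pd.DataFrame) -> pd.DataFrame:
    """Recompute rank order over array representatives.

    Representatives get ``array_ord`` 1..m per (genome, chrom) sorted by
    ``ord``; non-representative members get null ``array_ord`` but an
    ``array_ord_eff`` equal to their representative's rank so that every
    gene has a position on the collapsed axis.
    """
    genes = genes.copy()
    genes["array_ord"] = np.nan
    reps = genes["is_array_rep"]
    genes.loc[reps, "array_ord"] = (
        genes.loc[reps].sort_values("ord", kind="mergesort")
        .groupby(["genome", "chrom"], sort=False).cumcount() + 1)
    # effective position: members borrow their representative's rank
    rep_of_array = genes.loc[reps & genes["array_id"].notna()].set_index("array_id")["array_ord"]
    eff = genes["array_ord"].copy()
    in_array = genes["array_id"].notna() & ~reps
    eff.loc[in_array] = genes.loc[in_array, "array_id"].map(rep_of_array)
    genes["array_ord_eff"] = eff
    return genes


def arrays_table(arrays: list[TandemArray]) -> pd.DataFrame:
    """Tandem arrays as a writable table."""
    rows = [{
        "array_id": a.array_id, "genome": a.genome, "chrom": a.chrom,
        "og": a.og, "n_members": len(a.member_gene_ids),
        "representative": a.representative,
        "members": ",".join(a.member_gene_ids),
    } for a in arrays]
    cols = ["array_id", "genome", "chrom", "og", "n_members",
            "representative", "members"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("array_id", kind="mergesort").reset_index(drop=True)
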