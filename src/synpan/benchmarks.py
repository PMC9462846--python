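"""Ground-truth validation experiments on simulated genomes.

Each function builds a simulated multi-genome dataset with a known
evolutionary history, runs the pipeline on it, and scores the result
against the simulator's truth. They are used by the test suite and by the
reproduction script; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline, simulate as sim, synteny
from .pangenome import interpolate_positions, ref_anchor_pairs
from .params import SyntenyParams
from .summaries import single_copy_rate


def _rep_sets(run: pipeline.SyntenyRun) -> dict[str, set]:
    return {name: set(df.loc[df["is_array_rep"], "gene_id"])
            for name, df in run.genomes.items()}


def single_copy_benchmark(seed: int, *, n_chrom: int = 2,
                          genes_per_chrom: int = 500) -> dict:
    """Three haploid genomes with rearrangements, tandem duplication and
    gene loss: fraction of genes placed in exactly one syntenic region per
    pair, and anchor recall over truth ortholog pairs (evaluated between
    tandem-array representatives, since arrays are collapsed by design)."""
    res = sim.simulate_scenario(sim.default_scenario(
        seed, n_chrom=n_chrom, genes_per_chrom=genes_per_chrom))
    run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                SyntenyParams())
    reps = _rep_sets(run)
    rates, recalls = {}, {}
    for key, h in run.hits.items():
        rates[key] = single_copy_rate(h)
        gq, gt = h["genome_q"].iat[0], h["genome_t"].iat[0]
        tp = sim.ortholog_pairs(res.genomes[gq], res.genomes[gt])
        tp = tp.loc[(tp["relation"] == "ortholog")
                    & tp["gene_a"].isin(reps[gq])
                    & tp["gene_b"].isin(reps[gt])]
        anchors = set(map(tuple, h.loc[h["is_anchor"],
                                       ["query", "target"]].to_numpy()))
        hit = sum((a, b) in anchors
                  for a, b in zip(tp["gene_a"], tp["gene_b"]))
        recalls[key] = hit / len(tp) if len(tp) else float("nan")
    n_genes = sum(len(df) for df in res.genomes.values())
    return {"single_copy_rate": min(rates.values()),
            "anchor_recall": min(recalls.values()),
            "per_pair_single_copy": rates, "per_pair_recall": recalls,
            "n_genes": n_genes}


def wgd_benchmark(seed: int, *, genes_per_chrom: int = 500,
                  paralog_decay: float = 0.7) -> dict:
    """Shared pre-speciation WGD analyzed in haploid mode: fraction of
    primary anchors on true ortholog (not cross-homeolog) pairs, and the
    fraction of cross-homeolog representative pairs covered by the
    secondary (paralog) scan's syntenic buffer."""
    res = sim.simulate_scenario(sim.wgd_scenario(
        seed, genes_per_chrom=genes_per_chrom, paralog_decay=paralog_decay))
    params = SyntenyParams(n_secondary_hits=1, orthofinder_in_blk=False)
    run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map, params)
    (key,) = run.hits
    h = run.hits[key]
    gq, gt = h["genome_q"].iat[0], h["genome_t"].iat[0]
    tp = sim.ortholog_pairs(res.genomes[gq], res.genomes[gt])
    rel = tp.set_index(["gene_a", "gene_b"])["relation"]
    anch = h.loc[h["is_anchor"], ["query", "target"]]
    anno = [rel.get((q, t)) for q, t in anch.to_numpy()]
    primary_ortholog = float(np.mean([r == "ortholog" for r in anno]))
    reps = _rep_sets(run)
    wgd_pairs = tp.loc[(tp["relation"] == "wgd")
                       & tp["gene_a"].isin(reps[gq])
                       & tp["gene_b"].isin(reps[gt])]
    h2 = run.secondary_hits[key]
    buf = set(map(tuple, h2.loc[h2["in_buffer"],
                                ["query", "target"]].to_numpy()))
    cov = sum((a, b) in buf
              for a, b in zip(wgd_pairs["gene_a"], wgd_pairs["gene_b"]))
    return {"primary_ortholog_fraction": primary_ortholog,
            "secondary_coverage": cov / len(wgd_pairs),
            "n_anchors": int(len(anch)), "n_wgd_pairs": int(len(wgd_pairs))}


def exhaustive_best_chain_score(x, y, n_gaps: int) -> int:
    """Brute-force search over every valid collinear chain (the
    independent oracle for the chaining DP)."""
    n = len(x)
    g = n_gaps + 1
    best = 0

    def extend(last, sign, length):
        nonlocal best
        best = max(best, length)
        for j in range(n):
            dx = x[j] - x[last]
            dy = (y[j] - y[last]) * sign
            if 1 <= dx <= g and 1 <= dy <= g:
                extend(j, sign, length + 1)

    for i in range(n):
        for s in (1, -1):
            extend(i, s, 1)
    return best


def chain_oracle_benchmark(seed: int, *, n_instances: int = 200,
                           max_hits: int = 12) -> dict:
    """Random small instances: the greedy DP's top-chain score must equal
    the exhaustive-search optimum."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_hits + 1))
        n_gaps = int(rng.integers(1, 7))
        pts = set()
        while len(pts) < n:
            pts.add((int(rng.integers(1, 15)), int(rng.integers(1, 15))))
        pts = {p for p in pts if sum(q[0] == p[0] for q in pts) == 1}
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        chains = synteny.chain_collinear(x, y, blk_size=1, n_gaps=n_gaps)
        top = max((len(c[0]) for c in chains), default=0)
        agree += int(top == exhaustive_best_chain_score(x, y, n_gaps))
    return {"agreement": agree / n_instances, "n_instances": n_instances}


def tandem_benchmark(seed: int, *, n_scenarios: int = 100) -> dict:
    """Seeded tandem-only scenarios with known arrays: membership must be
    recovered exactly and representatives must satisfy the median rule
    (checked against an independent brute-force chooser)."""
    from . import tandem as td
    rng = np.random.default_rng(seed)
    scen_seeds = rng.integers(0, 2**31 - 1, size=n_scenarios)
    exact = 0
    for s in scen_seeds:
        sc = sim.EvolutionScenario(
            seed=int(s), n_chrom=1, genes_per_chrom=60,
            branches=[sim.Branch("anc", "g",
                                 sim.BranchEvents(tandem_rate=0.08,
                                                  tandem_copies=(1, 2)))])
        res = sim.simulate_scenario(sc)
        genes = res.genomes["g"].copy()
        genes["og"] = genes["gene_id"].map(res.og_map)
        arrays, _ = td.find_tandem_arrays(genes, SyntenyParams())
        truth = {}
        for (chrom, anc), sub in genes.groupby(["chrom", "anc_id"]):
            if len(sub) > 1:
                truth[(chrom, anc)] = frozenset(sub["gene_id"])
        got = {frozenset(a.member_gene_ids) for a in arrays}
        ok = got == set(truth.values())
        for a in arrays:
            members = genes.loc[genes["gene_id"].isin(a.member_gene_ids)]
            med = float(np.median(members["ord"]))
            want = min(zip(members["gene_id"], members["ord"]),
                       key=lambda m: (abs(m[1] - med), m[0]))[0]
            ok = ok and a.representative == want
        exact += int(ok)
    return {"exact_fraction": exact / n_scenarios,
            "n_scenarios": n_scenarios}


def interpolation_benchmark(seed: int, *, genes_per_chrom: int = 500,
                            withhold: float = 0.10) -> dict:
    """Withhold a fraction of reference genes, rerun the pipeline, and
    re-derive their rank via the other genome: fraction recovered within
    +/-1 rank among genes in rearrangement-free segments."""
    sc = sim.default_scenario(seed, genes_per_chrom=genes_per_chrom,
                              genomes=("genR", "genB"))
    res = sim.simulate_scenario(sc)
    affected = set()
    for log in res.event_logs.values():
        affected |= sim.affected_anc_ids(res.states["anc"], log)
    rng = np.random.default_rng(seed + 10_000)
    gR = res.genomes["genR"]
    wh = rng.random(len(gR)) < withhold
    withheld = gR.loc[wh]
    gR2 = gR.loc[~wh].sort_values(["chrom", "ord"]).copy()
    gR2["ord"] = gR2.groupby("chrom").cumcount() + 1
    wset = set(withheld["gene_id"])
    hits = {k: h.loc[~h["query"].isin(wset) & ~h["target"].isin(wset)]
            for k, h in res.hits.items()}
    run = pipeline.run_pipeline({"genR": gR2, "genB": res.genomes["genB"]},
                                hits, res.og_map, SyntenyParams())
    anchors = ref_anchor_pairs(run.hits[next(iter(run.hits))], "genR")
    ip = interpolate_positions(anchors, run.genomes["genB"],
                               run.params).set_index("gene_id")
    tp = sim.ortholog_pairs(res.genomes["genR"], res.genomes["genB"])
    partner = dict(zip(tp.loc[tp["relation"] == "ortholog", "gene_a"],
                       tp.loc[tp["relation"] == "ortholog", "gene_b"]))
    reps = run.genomes["genR"].loc[run.genomes["genR"]["is_array_rep"]]
    orig = dict(zip(gR["gene_id"], gR["ord"]))
    gb = run.genomes["genB"].set_index("gene_id")
    errs = []
    for _, w in withheld.iterrows():
        if w["anc_id"] in affected:
            continue
        b = partner.get(w["gene_id"])
        if b is None or b not in gb.index or not gb.loc[b, "is_array_rep"]:
            continue
        rr = reps.loc[reps["chrom"] == w["chrom"]]
        true_pos = sum(orig[g] < w["ord"] for g in rr["gene_id"]) + 0.5
        err = np.inf
        if b in ip.index:
            r = ip.loc[b]
            if isinstance(r, pd.DataFrame):
                r = r.loc[r["ref_chrom"] == w["chrom"]]
                r = r.iloc[0] if len(r) else None
            if r is not None and r["ref_chrom"] == w["chrom"]:
                err = abs(float(r["ref_ord"]) - true_pos)
        errs.append(err)
    errs = np.asarray(errs)
    return {"within_one_fraction": float((errs <= 1).mean()),
            "n_withheld": int(len(errs))}


def pav_benchmark(seed: int, *, genes_per_chrom: int = 500,
                  loss_rate: float = 0.05, ref: str = "genA") -> dict:
    """Independent gene loss across three genomes: sensitivity/precision
    of "absent" pan-genome cells against truth, plus conservation checks
    (no gene in two entries; unplaced genes have no syntenic partner)."""
    sc = sim.EvolutionScenario(
        seed=seed, n_chrom=2, genes_per_chrom=genes_per_chrom,
        branches=[sim.Branch("anc", g, sim.BranchEvents(loss_rate=loss_rate))
                  for g in ("genA", "genB", "genC")])
    res = sim.simulate_scenario(sc)
    run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                SyntenyParams())
    pgr = run.pangenome(ref)
    long = pgr.entries_long
    pav, _cnv = pgr.pav_cnv()
    gene_anc = {}
    for df in res.genomes.values():
        gene_anc.update(zip(df["gene_id"], df["anc_id"]))
    present = {g: set(df["anc_id"]) for g, df in res.genomes.items()}
    ent_anc = long.groupby("pg_id")["gene_id"].first().map(gene_anc)
    genomes = sorted(res.genomes)
    tp = fp = fn = 0
    for pgid, anc in ent_anc.items():
        for g in genomes:
            pred_abs = (g not in pav.columns) or (not pav.loc[pgid, g])
            true_abs = anc not in present[g]
            tp += pred_abs and true_abs
            fp += pred_abs and not true_abs
            fn += (not pred_abs) and true_abs
    dup = int(long["gene_id"].duplicated().sum())
    anc_count = pd.Series(
        [a for s in present.values() for a in s]).value_counts()
    bad_unplaced = sum(1 for g in pgr.unplaced
                       if anc_count.get(gene_anc[g], 0) > 1)
    return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "n_absent_cells": int(tp + fn),
            "duplicated_entries": dup,
            "unplaced_with_partner": int(bad_unplaced),
            "n_unplaced": len(pgr.unplaced)}


def permutation_benchmark(seed: int, *, genes_per_chrom: int = 500) -> dict:
    """Shuffling the target genome's gene order must destroy essentially
    all syntenic anchors."""
    sc = sim.default_scenario(seed, genes_per_chrom=genes_per_chrom,
                              genomes=("genA", "genB"))
    res = sim.simulate_scenario(sc)
    rng = np.random.default_rng(seed + 20_000)
    parts = []
    for _, sub in res.genomes["genB"].groupby("chrom"):
        sub = sub.copy()
        sub["ord"] = rng.permutation(len(sub)) + 1
        sub = sub.sort_values("ord")
        sub["start"] = np.arange(len(sub)) * 5000
        sub["end"] = sub["start"] + 3000
        parts.append(sub)
    gB = pd.concat(parts, ignore_index=True)
    run = pipeline.run_pipeline({"genA": res.genomes["genA"], "genB": gB},
                                res.hits, res.og_map, SyntenyParams())
    h = next(iter(run.hits.values()))
    return {"anchor_rate": float(h["is_anchor"].mean()),
            "n_hits": int(len(h))}


def determinism_benchmark(seed: int, *, genes_per_chrom: int = 300) -> dict:
    """Two end-to-end runs on the same fixture must write byte-identical
    block, hit and pan-genome tables."""
    def one_run(outdir: Path):
        res = sim.simulate_scenario(sim.default_scenario(
            seed, genes_per_chrom=genes_per_chrom))
        run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                    SyntenyParams())
        pipeline.write_run(run, outdir)
        pipeline.write_pangenome(run.pangenome("genA"), outdir)

    with tempfile.TemporaryDirectory() as tmp:
        d1, d2 = Path(tmp) / "r1", Path(tmp) / "r2"
        one_run(d1)
        one_run(d2)
        names = sorted(p.name for p in d1.iterdir())
        names2 = sorted(p.name for p in d2.iterdir())
        identical = names == names2 and all(
            filecmp.cmp(d1 / n, d2 / n, shallow=False) for n in names)
    return {"identical": bool(identical), "n_files": len(names)}
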