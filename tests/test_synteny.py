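import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synpan import pipeline, simulate as sim, synteny
from synpan.params import SyntenyParams
from synpan.summaries import single_copy_rate

from conftest import make_gene_table, make_hits, oriented_truth_pairs


# ------------------------------------------------------ chaining oracle

def brute_force_best_chain(x, y, n_gaps):
    """Exhaustive search over every valid collinear chain; returns the
    maximum hit count (independent oracle for the DP)."""
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
        for sign in (1, -1):
            extend(i, sign, 1)
    return best


class TestChainCollinear:
    def test_perfect_diagonal(self):
        xy = np.arange(1, 6)
        chains = synteny.chain_collinear(xy, xy, blk_size=5, n_gaps=5)
        assert len(chains) == 1
        idx, orient = chains[0]
        assert orient == "+" and len(idx) == 5

    def test_antidiagonal_inversion(self):
        x = np.arange(1, 6)
        y = np.arange(5, 0, -1)
        chains = synteny.chain_collinear(x, y, blk_size=5, n_gaps=5)
        assert len(chains) == 1
        assert chains[0][1] == "-" and len(chains[0][0]) == 5

    def test_chain_below_blk_size_discarded(self):
        xy = np.arange(1, 5)
        assert synteny.chain_collinear(xy, xy, blk_size=5, n_gaps=5) == []

    def test_gap_cap_respected(self):
        # gap of n_gaps+2 on x breaks the chain
        x = np.array([1, 2, 3, 11, 12, 13])
        y = np.array([1, 2, 3, 4, 5, 6])
        chains = synteny.chain_collinear(x, y, blk_size=3, n_gaps=5)
        assert sorted(len(c[0]) for c in chains) == [3, 3]

    def test_every_hit_in_at_most_one_chain(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(30) + 1
        y = rng.permutation(30) + 1
        chains = synteny.chain_collinear(x, y, blk_size=2, n_gaps=5)
        used = np.concatenate([c[0] for c in chains]) if chains else []
        assert len(used) == len(set(used))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000), st.integers(1, 6))
    def test_top_chain_score_matches_exhaustive_search(self, n, seed, n_gaps):
        rng = np.random.default_rng(seed)
        pts = set()
        while len(pts) < n:
            pts.add((int(rng.integers(1, 15)), int(rng.integers(1, 15))))
        pts = {p for p in pts if sum(q[0] == p[0] for q in pts) == 1}
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        chains = synteny.chain_collinear(x, y, blk_size=1, n_gaps=n_gaps)
        top = max((len(c[0]) for c in chains), default=0)
        assert top == brute_force_best_chain(x, y, n_gaps)


# ------------------------------------------------------------ annotation

@pytest.fixture()
def toy_pair():
    gq = make_gene_table("Q", {"chr1": [(f"g{i}", f"OG{i}")
                                        for i in range(1, 9)]})
    gt = make_gene_table("T", {"chr1": [(f"h{i}", f"OG{i}")
                                        for i in range(1, 9)]})
    return gq, gt


class TestAnnotateHits:
    def test_score_rank_is_dense(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300), ("g1", "h2", 250),
                          ("g1", "h3", 250), ("g1", "h4", 100)])
        h = synteny.annotate_hits(hits, gq, gt)
        ranks = h.set_index("target")["scr_rank_q"]
        assert (ranks["h1"], ranks["h2"], ranks["h3"], ranks["h4"]) \
            == (1, 2, 2, 3)

    def test_single_hit_rank_one_both_sides(self, toy_pair):
        gq, gt = toy_pair
        h = synteny.annotate_hits(make_hits([("g1", "h1", 300)]), gq, gt)
        assert h.loc[0, "scr_rank_q"] == 1 and h.loc[0, "scr_rank_t"] == 1

    def test_orthogroup_match_flag(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300), ("g1", "h2", 200)])
        h = synteny.annotate_hits(hits, gq, gt).set_index("target")
        assert bool(h.loc["h1", "is_og"]) is True   # OG1 x OG1
        assert bool(h.loc["h2", "is_og"]) is False  # OG1 x OG2

    def test_qc_dropped_genes_silently_excluded(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300), ("gX", "h1", 200)])
        h = synteny.annotate_hits(hits, gq, gt)
        assert list(h["query"]) == ["g1"]


class TestFlagPotentialAnchors:
    def test_score_rank_cap(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300), ("g1", "h2", 250)])
        h = synteny.annotate_hits(hits, gq, gt)
        h = synteny.flag_potential_anchors(h, SyntenyParams(only_og_anchors=False))
        pot = h.set_index("target")["is_potential"]
        assert bool(pot["h1"]) and not bool(pot["h2"])

    def test_auto_hit_counts_follow_ploidy(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300), ("g1", "h2", 250)])
        h = synteny.annotate_hits(hits, gq, gt)
        p = SyntenyParams(only_og_anchors=False, ploidy={"T": 2})
        h = synteny.flag_potential_anchors(h, p)
        assert h["is_potential"].sum() == 2  # top-2 eligible vs tetraploid

    def test_mask_excludes_hits(self, toy_pair):
        gq, gt = toy_pair
        hits = make_hits([("g1", "h1", 300)])
        h = synteny.annotate_hits(hits, gq, gt)
        h = synteny.flag_potential_anchors(h, SyntenyParams(),
                                           mask=np.array([True]))
        assert not h["is_potential"].any()


# ----------------------------------------------------- simulated genomes

class TestAnchorsOnSimulation:
    def test_colinear_pair_recovers_all_ortholog_hits(self):
        sc = sim.EvolutionScenario(
            seed=9, n_chrom=2, genes_per_chrom=120,
            branches=[sim.Branch("anc", g) for g in ("genA", "genB")])
        res = sim.simulate_scenario(sc)
        run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                    SyntenyParams())
        key, = run.hits
        h = run.hits[key]
        tp = oriented_truth_pairs(res, run, key)
        anchors = set(map(tuple, h.loc[h["is_anchor"],
                                       ["query", "target"]].to_numpy()))
        truth = set(map(tuple, tp.loc[tp["relation"] == "ortholog",
                                      ["gene_a", "gene_b"]].to_numpy()))
        assert truth <= anchors

    def test_inversion_recovered_with_negative_orientation(self):
        sc = sim.EvolutionScenario(
            seed=13, n_chrom=1, genes_per_chrom=150,
            branches=[sim.Branch("anc", "genA"),
                      sim.Branch("anc", "genB",
                                 sim.BranchEvents(inversions=1,
                                                  inversion_size=(20, 20)))])
        res = sim.simulate_scenario(sc)
        run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                    SyntenyParams())
        blocks = run.blocks
        neg = blocks.loc[blocks["orientation"] == "-"]
        assert len(neg) >= 1
        # the inverted segment is 20 genes; the "-" block must cover >= 80%
        assert neg["n_anchors"].max() >= 16

    def test_micro_inversion_splits_blocks_not_regions(self):
        sc = sim.EvolutionScenario(
            seed=21, n_chrom=1, genes_per_chrom=110,
            branches=[sim.Branch("anc", "genA"),
                      sim.Branch("anc", "genB",
                                 sim.BranchEvents(inversions=1,
                                                  inversion_size=(6, 6)))])
        res = sim.simulate_scenario(sc)
        run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map,
                                    SyntenyParams())
        blocks = run.blocks
        assert blocks["reg_id"].nunique() == 1
        assert len(blocks) >= 2
        assert set(blocks["orientation"]) == {"+", "-"}

    def test_shuffled_target_order_yields_no_anchors(self):
        sc = sim.default_scenario(7, genes_per_chrom=300,
                                  genomes=("genA", "genB"))
        res = sim.simulate_scenario(sc)
        gB = res.genomes["genB"].copy()
        rng = np.random.default_rng(0)
        parts = []
        for _, sub in gB.groupby("chrom"):
            sub = sub.copy()
            sub["ord"] = rng.permutation(len(sub)) + 1
            sub = sub.sort_values("ord")
            sub["start"] = np.arange(len(sub)) * 5000
            sub["end"] = sub["start"] + 3000
            parts.append(sub)
        gB2 = pd.concat(parts, ignore_index=True)
        run = pipeline.run_pipeline({"genA": res.genomes["genA"],
                                     "genB": gB2},
                                    res.hits, res.og_map, SyntenyParams())
        h, = run.hits.values()
        assert h["is_anchor"].mean() < 0.001


class TestRefineAndFinalize:
    def test_parallel_chains_separated_by_more_than_synbuff(self):
        # two diagonals offset by 60 on the target axis, syn_buff=20
        gq = make_gene_table("Q", {"c1": [(f"g{i}", f"OG{i}")
                                          for i in range(1, 31)]})
        gt = make_gene_table("T", {"c1": [(f"h{i}", f"OG{i%100}")
                                          for i in range(1, 101)]})
        rows = [(f"g{i}", f"h{i}", 300) for i in range(1, 31)]
        rows += [(f"g{i}", f"h{i + 60}", 290) for i in range(1, 31)]
        h = synteny.annotate_hits(make_hits(rows), gq, gt)
        # permit both hits per query gene, no og requirement
        p = SyntenyParams(syn_buff=20, only_og_anchors=False,
                          n_hits1=2, n_hits2=2)
        h, blocks = synteny.run_pair_scan(h, p)
        assert len(blocks) == 2
        assert blocks["reg_id"].nunique() == 2

    def test_no_initial_anchors_gives_zero_blocks(self, toy_pair):
        gq, gt = toy_pair
        h = synteny.annotate_hits(make_hits([("g1", "h5", 100)]), gq, gt)
        h, blocks = synteny.run_pair_scan(h, SyntenyParams())
        assert len(blocks) == 0 and not h["is_anchor"].any()

    def test_in_buffer_radius(self):
        n = 60
        gq = make_gene_table("Q", {"c1": [(f"g{i}", f"OG{i}")
                                          for i in range(1, n + 1)]})
        gt = make_gene_table("T", {"c1": [(f"h{i}", f"OG{i}")
                                          for i in range(1, n + 1)]})
        rows = [(f"g{i}", f"h{i}", 300) for i in range(1, 11)]
        rows += [(f"g13", "h14", 80)]   # 4 rank units off the diagonal end
        rows += [(f"g{n}", "h1", 70)]   # far from every anchor
        h = synteny.annotate_hits(make_hits(rows), gq, gt)
        h, blocks = synteny.run_pair_scan(h, SyntenyParams(syn_buff=5))
        byt = h.set_index(["query", "target"])
        assert bool(byt.loc[("g13", "h14"), "in_buffer"])
        assert not bool(byt.loc[(f"g{n}", "h1"), "in_buffer"])
        assert byt.loc[("g13", "h14"), "reg_id"] == blocks["reg_id"].iat[0]

    def test_block_coordinates_match_bounding_anchors(self, demo_run):
        for (gq, gt), h in demo_run.hits.items():
            anchors = h.loc[h["is_anchor"]]
            blocks = demo_run.blocks
            for blk_id, sub in anchors.groupby("blk_id"):
                row = blocks.loc[blocks["blk_id"] == blk_id].iloc[0]
                assert row["min_ord_q"] == sub["array_ord_q"].min()
                assert row["max_ord_q"] == sub["array_ord_q"].max()
                assert row["start_bp_q"] == sub["start_q"].min()
                assert row["end_bp_q"] == sub["end_q"].max()
                assert row["start_bp_t"] == sub["start_t"].min()

    def test_anchor_subset_chain(self, demo_run):
        for h in demo_run.hits.values():
            assert (h.loc[h["is_anchor"], "is_potential"]).all()
            assert (h.loc[h["is_anchor"], "in_buffer"]).all()

    def test_anchors_strictly_monotone_within_block(self, demo_run):
        for h in demo_run.hits.values():
            for (blk, orient), sub in h.loc[h["is_anchor"]].groupby(
                    ["blk_id", "orientation"]):
                sub = sub.sort_values("array_ord_q")
                assert sub["array_ord_q"].is_monotonic_increasing
                dy = np.diff(sub["array_ord_t"].to_numpy())
                if len(dy):
                    assert (dy > 0).all() if orient == "+" else (dy < 0).all()


class TestSelfSynteny:
    def test_haploid_identity_blocks(self, demo_run):
        g = demo_run.genomes["genA"]
        _, blocks = synteny.self_synteny(g, None, SyntenyParams(), "genA")
        assert len(blocks) == g["chrom"].nunique()
        assert blocks["is_self"].all()
        assert list(blocks["blk_id"]) == sorted(g["chrom"].unique())

    def test_autotetraploid_recovers_homeolog_blocks(self):
        sc = sim.EvolutionScenario(
            seed=5, n_chrom=2, genes_per_chrom=200,
            branches=[sim.Branch("anc", "genX", sim.BranchEvents(wgd=True))])
        res = sim.simulate_scenario(sc)
        params = SyntenyParams(ploidy={"genX": 2})
        genomes, _ = pipeline.prepare_genomes(
            {"genX": res.genomes["genX"]}, res.og_map, params)
        selfh = res.self_hits("genX")
        _, blocks = synteny.self_synteny(genomes["genX"], selfh, params,
                                         "genX")
        off_diag = blocks.loc[blocks["chrom_q"] != blocks["chrom_t"]]
        pairs = set(map(frozenset,
                        off_diag[["chrom_q", "chrom_t"]].to_numpy()))
        assert pairs == {frozenset({"chr1", "chr1w"}),
                         frozenset({"chr2", "chr2w"})}

    def test_identity_diagonal_masked(self):
        sc = sim.EvolutionScenario(
            seed=5, n_chrom=1, genes_per_chrom=150,
            branches=[sim.Branch("anc", "genX", sim.BranchEvents(wgd=True))])
        res = sim.simulate_scenario(sc)
        params = SyntenyParams(ploidy={"genX": 2}, self_mask_radius=500)
        genomes, _ = pipeline.prepare_genomes(
            {"genX": res.genomes["genX"]}, res.og_map, params)
        h, blocks = synteny.self_synteny(genomes["genX"],
                                         res.self_hits("genX"), params,
                                         "genX")
        anchors = h.loc[h["is_anchor"]]
        same = anchors.loc[anchors["chrom_q"] == anchors["chrom_t"]]
        assert ((same["array_ord_q"] - same["array_ord_t"]).abs()
                > params.self_mask_radius).all()

    def test_invalid_ploidy_fatal(self, demo_run):
        p = SyntenyParams()
        p.ploidy = {"genA": 0}
        with pytest.raises(ValueError):
            synteny.self_synteny(demo_run.genomes["genA"], None, p, "genA")


class TestSecondaryScan:
    def test_wgd_paralog_blocks_recovered(self, wgd_result, wgd_run):
        sec = wgd_run.blocks.loc[wgd_run.blocks["is_secondary"]]
        assert len(sec) > 0
        # secondary blocks join chromosomes across WGD copies
        crossed = (sec["chrom_q"].str.endswith("w")
                   != sec["chrom_t"].str.endswith("w"))
        assert crossed.all()

    def test_no_wgd_means_no_secondary_blocks(self):
        sc = sim.default_scenario(3, genes_per_chrom=150,
                                  genomes=("genA", "genB"))
        res = sim.simulate_scenario(sc)
        params = SyntenyParams(n_secondary_hits=1)
        run = pipeline.run_pipeline(res.genomes, res.hits, res.og_map, params)
        sec = run.blocks.loc[run.blocks["is_secondary"]]
        assert sec["n_anchors"].sum() <= 0.01 * sum(
            len(g) for g in res.genomes.values())

    def test_zero_secondary_hits_is_noop(self, demo_run):
        h, = [demo_run.hits[k] for k in list(demo_run.hits)[:1]]
        h2, blocks2 = synteny.secondary_hits_scan(h, SyntenyParams())
        assert len(blocks2) == 0 and len(h2) == 0

    def test_relaxed_secondary_parameters_accepted(self):
        p = SyntenyParams(n_secondary_hits=1, n_gaps_second=10,
                          blk_size_second=5)
        sp = p.secondary()
        assert sp.n_gaps == 10 and sp.blk_size == 5
        assert sp.only_og_anchors is False and sp.n_hits1 == 1


def test_single_copy_property(demo_run):
    """Haploid pairs with rearrangements but no WGD: >= 99% of genes sit in
    exactly one syntenic region per pair."""
    for h in demo_run.hits.values():
        assert single_copy_rate(h) >= 0.99


def test_pipeline_is_deterministic(demo_result, demo_run, tmp_path):
    run2 = pipeline.run_pipeline(demo_result.genomes, demo_result.hits,
                                 demo_result.og_map, SyntenyParams())
    pd.testing.assert_frame_equal(run2.blocks, demo_run.blocks)
    for k in demo_run.hits:
        pd.testing.assert_frame_equal(run2.hits[k], demo_run.hits[k])
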