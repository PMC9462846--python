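import numpy as np
import pandas as pd
import pytest

from synpan import pipeline, simulate as sim
from synpan.params import SyntenyParams
from synpan import tandem


def make_gene_table(genome: str, chrom_genes: dict) -> pd.DataFrame:
    """Build a normalized gene table from {chrom: [(gene_id, og), ...]}
    lists (rank order = list order) and compute collapsed array ranks."""
    rows = []
    for chrom, genes in chrom_genes.items():
        for i, (gid, og) in enumerate(genes):
            start = i * 5000
            rows.append((gid, genome, chrom, start, start + 3000, "+",
                         i + 1, og, True, None, np.nan))
    df = pd.DataFrame(rows, columns=[
        "gene_id", "genome", "chrom", "start", "end", "strand", "ord", "og",
        "is_array_rep", "array_id", "array_ord"])
    _, df = tandem.find_tandem_arrays(df, SyntenyParams())
    return tandem.assign_array_ord(df)


def make_hits(rows) -> pd.DataFrame:
    """outfmt-6-shaped table from (query, target, bitscore[, pident])."""
    recs = []
    for r in rows:
        q, t, bs = r[0], r[1], r[2]
        pid = r[3] if len(r) > 3 else 90.0
        recs.append((q, t, pid, 300, 10, 0, 1, 300, 1, 300, 1e-50, bs))
    from synpan.genome_io import OUTFMT6_COLUMNS
    return pd.DataFrame(recs, columns=OUTFMT6_COLUMNS)


@pytest.fixture(scope="session")
def demo_result():
    """Three haploid genomes with inversions, a translocation, tandem
    duplication and gene loss (ground truth attached)."""
    return sim.simulate_scenario(sim.default_scenario(1, genes_per_chrom=200))


@pytest.fixture(scope="session")
def demo_run(demo_result):
    return pipeline.run_pipeline(demo_result.genomes, demo_result.hits,
                                 demo_result.og_map, SyntenyParams())


@pytest.fixture(scope="session")
def wgd_result():
    """Two genomes sharing a pre-speciation WGD, analyzed as haploid."""
    return sim.simulate_scenario(sim.wgd_scenario(2, genes_per_chrom=250))


@pytest.fixture(scope="session")
def wgd_run(wgd_result):
    params = SyntenyParams(n_secondary_hits=1, orthofinder_in_blk=False)
    return pipeline.run_pipeline(wgd_result.genomes, wgd_result.hits,
                                 wgd_result.og_map, params)


def oriented_truth_pairs(result, run, pair_key):
    """Simulator truth pairs oriented to a hit table's (query, target)."""
    h = run.hits[pair_key]
    gq, gt = h["genome_q"].iat[0], h["genome_t"].iat[0]
    return sim.ortholog_pairs(result.genomes[gq], result.genomes[gt])
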