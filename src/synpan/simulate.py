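"""Multi-genome evolution simulator with known orthology/synteny truth.

A shared ancestral gene order evolves along a user-defined tree through
inversions, translocations, tandem duplications, gene losses and optional
whole-genome duplication (WGD). The simulator emits annotations, truth
orthogroups, and bitscore-realistic similarity hits (orthologs score higher
than WGD paralogs; spurious low-score hits are sprinkled in), giving every
pipeline stage a ground truth to be tested against.

Only gene rank order matters to the pipeline, so genes get fixed-size bp
coordinates (3 kb genes, 2 kb spacing) and no sequences are simulated.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io

GENE_LEN = 3000
GENE_SPACING = 2000

#: genome state: chrom -> ordered list of (anc_id, copy_label, tandem_idx)
GenomeState = dict


@dataclass
class BranchEvents:
    inversions: int = 0
    inversion_size: tuple[int, int] = (20, 50)
    translocations: int = 0
    translocation_size: tuple[int, int] = (20, 20)
    tandem_rate: float = 0.0
    tandem_copies: tuple[int, int] = (1, 1)
    loss_rate: float = 0.0
    wgd: bool = False

    def __post_init__(self) -> None:
        for r in (self.tandem_rate, self.loss_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        for lo, hi in (self.inversion_size, self.translocation_size,
                       self.tandem_copies):
            if lo < 1 or hi < lo:
                raise ValueError("sizes must satisfy 1 <= lo <= hi")


@dataclass
class Branch:
    parent: str
    child: str
    events: BranchEvents = field(default_factory=BranchEvents)


@dataclass
class HitNoise:
    ortholog_mean: float = 500.0
    ortholog_sd: float = 50.0
    paralog_decay: float = 0.7
    spurious_rate: float = 0.05
    spurious_score: tuple[float, float] = (30.0, 60.0)

    def __post_init__(self) -> None:
        if not 0 <= self.spurious_rate <= 1:
            raise ValueError("spurious_rate must be in [0, 1]")
        if not 0 < self.paralog_decay <= 1:
            raise ValueError("paralog_decay must be in (0, 1]")


@dataclass
class EvolutionScenario:
    seed: int
    branches: list[Branch]
    n_chrom: int = 2
    genes_per_chrom: int = 500
    noise: HitNoise = field(default_factory=HitNoise)
    root: str = "anc"

    def leaves(self) -> list[str]:
        parents = {b.parent for b in self.branches}
        return sorted(b.child for b in self.branches if b.child not in parents)


def default_scenario(seed: int = 0, *, n_chrom: int = 2,
                     genes_per_chrom: int = 500,
                     genomes: tuple[str, ...] = ("genA", "genB", "genC"),
                     ) -> EvolutionScenario:
    """Three haploid genomes radiating from one ancestor; each branch gets
    2 inversions (20-50 genes), 1 translocation (20 genes), 2% gene loss
    and 1% tandem duplication."""
    ev = dict(inversions=2, inversion_size=(20, 50),
              translocations=1, translocation_size=(20, 20),
              tandem_rate=0.01, loss_rate=0.02)
    return EvolutionScenario(
        seed=seed, n_chrom=n_chrom, genes_per_chrom=genes_per_chrom,
        branches=[Branch("anc", g, BranchEvents(**ev)) for g in genomes])


def wgd_scenario(seed: int = 0, *, n_chrom: int = 2, genes_per_chrom: int = 500,
                 loss_rate: float = 0.02, inversions: int = 1,
                 paralog_decay: float = 0.7,
                 genomes: tuple[str, str] = ("genA", "genB"),
                 ) -> EvolutionScenario:
    """A WGD on the root branch shared by two descendant genomes, so every
    gene has both an ortholog and a cross-genome WGD paralog (homeolog)."""
    branches = [Branch("anc", "postwgd", BranchEvents(wgd=True))]
    branches += [Branch("postwgd", g,
                        BranchEvents(inversions=inversions,
                                     inversion_size=(20, 50),
                                     loss_rate=loss_rate))
                 for g in genomes]
    return EvolutionScenario(
        seed=seed, n_chrom=n_chrom, genes_per_chrom=genes_per_chrom,
        branches=branches, noise=HitNoise(paralog_decay=paralog_decay))


# ---------------------------------------------------------------- ancestor

def simulate_ancestor(scenario: EvolutionScenario) -> GenomeState:
    """n_chrom x genes_per_chrom genes with sequential ancestral ids."""
    state: GenomeState = {}
    nxt = 0
    for c in range(1, scenario.n_chrom + 1):
        state[f"chr{c}"] = [(nxt + i, "a", 0)
                            for i in range(scenario.genes_per_chrom)]
        nxt += scenario.genes_per_chrom
    return state


# ------------------------------------------------------- event primitives

def _op_inversion(state: GenomeState, chrom: str, start: int, length: int) -> None:
    seg = state[chrom][start:start + length]
    state[chrom][start:start + length] = seg[::-1]


def _op_translocation(state: GenomeState, src: str, start: int, length: int,
                      dst: str, insert_at: int) -> None:
    seg = state[src][start:start + length]
    del state[src][start:start + length]
    state[dst][insert_at:insert_at] = seg


def _op_tandem(state: GenomeState, insertions: list[list]) -> None:
    # insertions: [chrom, index, k]; applied high-index first per chrom
    for chrom, idx, k in sorted(insertions, key=lambda t: (t[0], -t[1])):
        anc, copy, _ = state[chrom][idx]
        children = [(anc, copy, j + 1) for j in range(k)]
        state[chrom][idx + 1:idx + 1] = children


def _op_loss(state: GenomeState, removals: list[list]) -> None:
    for chrom, idx in sorted(removals, key=lambda t: (t[0], -t[1])):
        del state[chrom][idx]


def _op_wgd(state: GenomeState) -> None:
    for chrom in sorted(state):
        state[chrom + "w"] = [(anc, copy + "b", tid)
                              for anc, copy, tid in state[chrom]]


_OPS = {
    "inversion": _op_inversion,
    "translocation": _op_translocation,
    "tandem": _op_tandem,
    "loss": _op_loss,
    "wgd": _op_wgd,
}


def affected_anc_ids(parent: GenomeState, log: list[dict],
                     margin: int = 2) -> set[int]:
    """Ancestral ids of genes inside (or within ``margin`` genes of) any
    inverted or translocated segment of a branch's event log. Replays the
    log, so the ids are taken at each event's application time. Useful to
    restrict evaluations to rearrangement-free segments."""
    state = {c: list(g) for c, g in parent.items()}
    out: set[int] = set()

    def grab(chrom, lo, hi):
        seg = state[chrom][max(0, lo):hi]
        out.update(anc for anc, _c, _t in seg)

    for entry in log:
        op, args = entry["op"], entry["args"]
        if op == "inversion":
            chrom, start, length = args
            grab(chrom, start - margin, start + length + margin)
        elif op == "translocation":
            chrom, start, length, dst, at = args
            grab(chrom, start - margin, start + length + margin)
            grab(dst, at - margin, at + margin)
        _OPS[op](state, *args)
    return out


def apply_events(parent: GenomeState, log: list[dict]) -> GenomeState:
    """Replay a logged event list onto a parent genome (deterministic)."""
    state = {c: list(g) for c, g in parent.items()}
    for entry in log:
        _OPS[entry["op"]](state, *entry["args"])
    return state


def evolve_branch(parent: GenomeState, events: BranchEvents,
                  rng: np.random.Generator) -> tuple[GenomeState, list[dict]]:
    """Apply one branch's events in seeded random order; return the child
    state and a replayable event log with concrete coordinates."""
    state = {c: list(g) for c, g in parent.items()}
    ops = (["wgd"] * int(events.wgd)
           + ["inversion"] * events.inversions
           + ["translocation"] * events.translocations
           + (["tandem"] if events.tandem_rate > 0 else [])
           + (["loss"] if events.loss_rate > 0 else []))
    ops = list(rng.permutation(ops)) if ops else []
    log: list[dict] = []

    def segment(size_range: tuple[int, int], need_margin: bool):
        lo, hi = size_range
        chroms = sorted(c for c, g in state.items() if len(g) > hi + 2)
        if not chroms:
            raise ValueError("event size exceeds chromosome length")
        chrom = chroms[rng.integers(len(chroms))]
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(state[chrom]) - size + 1))
        return chrom, start, size

    for op in ops:
        if op == "wgd":
            entry = {"op": "wgd", "args": []}
        elif op == "inversion":
            chrom, start, size = segment(events.inversion_size, False)
            entry = {"op": "inversion", "args": [chrom, start, size]}
        elif op == "translocation":
            chrom, start, size = segment(events.translocation_size, False)
            others = sorted(c for c in state if c != chrom)
            if not others:
                continue
            dst = others[rng.integers(len(others))]
            at = int(rng.integers(0, len(state[dst]) + 1))
            entry = {"op": "translocation", "args": [chrom, start, size, dst, at]}
        elif op == "tandem":
            insertions = []
            for chrom in sorted(state):
                n = len(state[chrom])
                hit = np.flatnonzero(rng.random(n) < events.tandem_rate)
                for idx in hit:
                    k = int(rng.integers(events.tandem_copies[0],
                                         events.tandem_copies[1] + 1))
                    insertions.append([chrom, int(idx), k])
            entry = {"op": "tandem", "args": [insertions]}
        else:  # loss
            removals = []
            for chrom in sorted(state):
                n = len(state[chrom])
                hit = np.flatnonzero(rng.random(n) < events.loss_rate)
                removals.extend([chrom, int(idx)] for idx in hit)
            entry = {"op": "loss", "args": [removals]}
        _OPS[entry["op"]](state, *entry["args"])
        log.append(entry)
    return state, log


# --------------------------------------------------------------- finalize

def _natural_key(chrom: str):
    import re
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom)]


def genome_table(state: GenomeState, name: str) -> pd.DataFrame:
    """Materialize a genome state as a normalized gene table with truth
    columns (``anc_id``, ``copy``, ``tandem_idx``)."""
    rows = []
    i = 0
    for chrom in sorted(state, key=_natural_key):
        for pos, (anc, copy, tid) in enumerate(state[chrom]):
            start = pos * (GENE_LEN + GENE_SPACING)
            rows.append((f"{name}_{i:05d}", name, chrom, start, start + GENE_LEN,
                         "+", pos + 1, anc, copy, tid))
            i += 1
    df = pd.DataFrame(rows, columns=[
        "gene_id", "genome", "chrom", "start", "end", "strand", "ord",
        "anc_id", "copy", "tandem_idx"])
    df["og"] = None
    df["is_array_rep"] = True
    df["array_id"] = None
    df["array_ord"] = np.nan
    return df


def truth_orthogroups(genomes: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Truth orthogroups are the connected components of descent: all extant
    copies of one ancestral gene share an orthogroup."""
    og_map = {}
    for df in genomes.values():
        for gid, anc in zip(df["gene_id"], df["anc_id"]):
            og_map[gid] = f"OG{anc:06d}"
    return og_map


def ortholog_pairs(ga: pd.DataFrame, gb: pd.DataFrame) -> pd.DataFrame:
    """All cross-genome gene pairs sharing an ancestral gene, classified as
    ``ortholog`` (same WGD copy, both original lineage members), ``tandem``
    (same copy, >= 1 tandem child) or ``wgd`` (different WGD copies)."""
    a = ga[["gene_id", "anc_id", "copy", "tandem_idx"]].rename(
        columns={"gene_id": "gene_a", "copy": "copy_a", "tandem_idx": "tid_a"})
    b = gb[["gene_id", "anc_id", "copy", "tandem_idx"]].rename(
        columns={"gene_id": "gene_b", "copy": "copy_b", "tandem_idx": "tid_b"})
    m = a.merge(b, on="anc_id")
    rel = np.where(m["copy_a"] != m["copy_b"], "wgd",
                   np.where((m["tid_a"] == 0) & (m["tid_b"] == 0),
                            "ortholog", "tandem"))
    m["relation"] = rel
    return m


# -------------------------------------------------------------------- hits

def emit_hits(ga: pd.DataFrame, gb: pd.DataFrame, noise: HitNoise,
              rng: np.random.Generator) -> pd.DataFrame:
    """Similarity hits between two (possibly identical) genomes.

    Pairs sharing an ancestral gene get bitscore ~ Normal(mean, sd),
    multiplied by ``paralog_decay`` when related only through a WGD;
    spurious random pairs are added at ``spurious_rate`` with low scores.
    pident is a monotone function of bitscore.
    """
    pairs = ortholog_pairs(ga, gb)
    if ga is gb or ga["genome"].iloc[0] == gb["genome"].iloc[0]:
        pairs = pairs.loc[pairs["gene_a"] != pairs["gene_b"]]
    n = len(pairs)
    score = rng.normal(noise.ortholog_mean, noise.ortholog_sd, size=n)
    score = np.where(pairs["relation"] == "wgd", score * noise.paralog_decay, score)
    score = np.clip(score, 1.0, None)
    hits = pd.DataFrame({"query": pairs["gene_a"].to_numpy(),
                         "target": pairs["gene_b"].to_numpy(),
                         "bitscore": np.round(score, 1)})
    n_spur = int(round(noise.spurious_rate * n))
    if n_spur:
        qi = rng.integers(0, len(ga), size=n_spur)
        ti = rng.integers(0, len(gb), size=n_spur)
        spur = pd.DataFrame({
            "query": ga["gene_id"].to_numpy()[qi],
            "target": gb["gene_id"].to_numpy()[ti],
            "bitscore": np.round(rng.uniform(*noise.spurious_score, size=n_spur), 1),
            "anc_q": ga["anc_id"].to_numpy()[qi],
            "anc_t": gb["anc_id"].to_numpy()[ti]})
        spur = spur.loc[(spur["anc_q"] != spur["anc_t"])
                        & (spur["query"] != spur["target"]),
                        ["query", "target", "bitscore"]]
        hits = pd.concat([hits, spur], ignore_index=True)
    hits = (hits.sort_values(["query", "target", "bitscore"],
                             ascending=[True, True, False], kind="mergesort")
                .drop_duplicates(["query", "target"]))
    top = noise.ortholog_mean + 3 * noise.ortholog_sd
    pident = np.clip(100.0 * hits["bitscore"] / top, 1.0, 100.0).round(2)
    out = pd.DataFrame({
        "query": hits["query"], "target": hits["target"], "pident": pident,
        "length": 300, "mismatch": np.round(300 * (1 - pident / 100)).astype(int),
        "gap_open": 0, "q_start": 1, "q_end": 300, "t_start": 1, "t_end": 300,
        "evalue": 1e-50, "bitscore": hits["bitscore"]})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------- scenario

@dataclass
class SimResult:
    scenario: EvolutionScenario
    ancestor: GenomeState
    states: dict[str, GenomeState]
    genomes: dict[str, pd.DataFrame]
    og_map: dict[str, str]
    event_logs: dict[str, list]
    hits: dict[tuple[str, str], pd.DataFrame]

    def self_hits(self, genome: str, seed_offset: int = 77) -> pd.DataFrame:
        rng = np.random.default_rng(self.scenario.seed + seed_offset)
        g = self.genomes[genome]
        return emit_hits(g, g, self.scenario.noise, rng)


def simulate_scenario(scenario: EvolutionScenario) -> SimResult:
    """Run the whole scenario: ancestor, branch evolution in listed order,
    leaf gene tables, truth orthogroups and pairwise hit tables. One seeded
    RNG stream drives every draw, so identical scenarios give identical
    output."""
    rng = np.random.default_rng(scenario.seed)
    states: dict[str, GenomeState] = {scenario.root: simulate_ancestor(scenario)}
    logs: dict[str, list] = {}
    for br in scenario.branches:
        if br.parent not in states:
            raise ValueError(f"branch parent {br.parent!r} not yet simulated "
                             "(branches must be listed parent-first)")
        child, log = evolve_branch(states[br.parent], br.events, rng)
        states[br.child] = child
        logs[br.child] = log
    leaves = scenario.leaves()
    genomes = {name: genome_table(states[name], name) for name in leaves}
    og_map = truth_orthogroups(genomes)
    hits = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            hits[(a, b)] = emit_hits(genomes[a], genomes[b], scenario.noise, rng)
    return SimResult(scenario=scenario, ancestor=states[scenario.root],
                     states=states, genomes=genomes, og_map=og_map,
                     event_logs=logs, hits=hits)


# ---------------------------------------------------------------- fixtures

def write_fixture(result: SimResult, outdir: str | Path, *,
                  force: bool = False) -> dict:
    """Write a complete on-disk fixture: per-genome GFF3 + BED, truth
    orthogroups TSV, pairwise hits TSVs, event log JSON and a manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"genomes": sorted(result.genomes), "annotations": {},
                "bed": {}, "hits": {}, "ploidy": {}}
    for name, df in result.genomes.items():
        gff = outdir / f"{name}.gff3"
        bed = outdir / f"{name}.bed"
        genome_io.write_annotation(df, gff, fmt="gff3")
        genome_io.write_annotation(df, bed, fmt="bed")
        manifest["annotations"][name] = gff.name
        manifest["bed"][name] = bed.name
        manifest["ploidy"][name] = 1
    og_path = outdir / "orthogroups.tsv"
    genome_io.write_orthogroups(
        result.og_map, {n: df["gene_id"] for n, df in result.genomes.items()},
        og_path)
    manifest["orthogroups"] = og_path.name
    for (a, b), hits in sorted(result.hits.items()):
        p = outdir / f"{a}__vs__{b}.hits.tsv"
        genome_io.write_hits(hits, p)
        manifest["hits"][f"{a}__{b}"] = p.name
    with open(outdir / "event_log.json", "w") as fh:
        json.dump(result.event_logs, fh, indent=1)
    with open(outdir / "scenario.json", "w") as fh:
        json.dump(asdict(result.scenario), fh, indent=1, default=list)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
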