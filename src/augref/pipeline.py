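"""End-to-end experiment orchestration.

Runs the full study design from a single configuration: generate a
synthetic genome and multi-population panel once, then for every
replicate simulate reads from one target individual and map them to a
set of reference structures (personalized / own-population / pan /
across-breed / random / empty graphs and major-allele consensus
sequences), collecting mapping-accuracy statistics per cell. A second
entry point runs the reference-allele-bias experiment (graph vs linear
pileups at heterozygous sites).

Replicates share the genome and panel but re-draw variant subsampling
and read simulation, mirroring the repeated-selection design of the
underlying study; the replicate seed is ``base_seed + replicate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .consensus import build_consensus
from .genotyper import Filters, PileupSite, pileup_and_call
from .graphbuild import (
    VariantSet,
    build_graph,
    embed_haplotypes,
    graph_stats,
    select_variants,
)
from .mapper import MapIndex, Scoring, build_index, map_reads
from .readsim import SimParams, SimulatedRead, annotate_reads, extract_haplotype, simulate_reads
from .synthpop import (
    DEFAULT_SFS,
    ReferenceSequence,
    RepeatSpec,
    VariantPanel,
    generate_reference,
    simulate_population,
)

GRAPH_MODES = (
    "personalized",
    "targeted",
    "pan",
    "across",
    "random",
    "empty",
    "consensus",
    "consensus_snp",
)


def default_threshold_grid() -> list[float]:
    """0 to 0.1 in steps of 0.01, then 0.1 to 1 in steps of 0.1."""
    fine = [round(0.01 * i, 2) for i in range(0, 10)]
    coarse = [round(0.1 * i, 1) for i in range(1, 11)]
    return fine + coarse


@dataclass
class ExperimentConfig:
    genome_length: int = 200_000
    gc_content: float = 0.42
    repeats: RepeatSpec | None = field(default_factory=RepeatSpec)
    pops: list[tuple[str, int]] = field(default_factory=lambda: [("A", 20), ("B", 20)])
    n_variants: int = 2000
    sfs: tuple[float, ...] = DEFAULT_SFS
    indel_fraction: float = 0.10
    max_indel: int = 49
    shared_fraction: float = 0.7
    target_pop: str = "A"
    modes: list[str] = field(default_factory=lambda: ["empty", "targeted"])
    af_threshold: float = 0.03  # threshold for the graph-type comparison
    thresholds: list[float] | None = None  # sweep grid for mode 'threshold'
    sim: SimParams = field(default_factory=lambda: SimParams(n_pairs=20_000))
    n_replicates: int = 10
    base_seed: int = 0
    max_node_len: int = 32
    seed_len: int = 21
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for t in self.thresholds or []:
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.thresholds is not None:
            self.thresholds = sorted(self.thresholds)
        known = set(GRAPH_MODES) | {"threshold"}
        for m in self.modes:
            if m not in known:
                raise ValueError(f"unknown mode {m!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key == "repeats":
                val = RepeatSpec(**val) if val else None
            elif key == "sim":
                val = SimParams(**val)
            elif key == "pops":
                val = [(str(p["label"]), int(p["n"])) for p in val]
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class ExperimentData:
    """Shared inputs of one experiment: genome, panel, target haplotypes."""

    ref: ReferenceSequence
    panel: VariantPanel
    sample: str
    scoring: Scoring


def prepare(config: ExperimentConfig) -> ExperimentData:
    ref = generate_reference(
        config.genome_length, config.gc_content, seed=config.base_seed,
        repeats=config.repeats,
    )
    panel = simulate_population(
        ref, config.pops, config.n_variants, sfs=config.sfs,
        indel_fraction=config.indel_fraction, max_indel=config.max_indel,
        shared_fraction=config.shared_fraction, seed=config.base_seed + 1,
    )
    sample = next(sid for sid, pop in panel.samples if pop == config.target_pop)
    scoring = Scoring(frag_mean=config.sim.frag_mean, frag_sd=config.sim.frag_sd)
    return ExperimentData(ref, panel, sample, scoring)


def random_variant_catalog(
    ref: ReferenceSequence, panel: VariantPanel, n_novel: int, seed: int
) -> list:
    """Panel variants plus novel decoy variants of unknown provenance.

    Emulates drawing "random" variants from a large external catalog in
    which most entries do not segregate in the study populations: the
    returned pool is the panel's variants plus ``n_novel`` synthetic
    SNPs at positions not overlapping any panel variant.
    """
    from .synthpop import Variant

    rng = np.random.default_rng(seed)
    occupied = np.zeros(ref.length, dtype=bool)
    for v in panel.variants:
        occupied[max(0, v.pos - 1) : v.end + 1] = True
    pool = list(panel.variants)
    tries = 0
    made = 0
    while made < n_novel and tries < 50 * n_novel:
        tries += 1
        p = int(rng.integers(5, ref.length - 5))
        if occupied[p]:
            continue
        occupied[max(0, p - 1) : p + 2] = True
        base = ref.sequence[p]
        alts = [b for b in "ACGT" if b != base]
        pool.append(Variant(ref.name, p, base, alts[int(rng.integers(3))]))
        made += 1
    return pool


def _other_pop(panel: VariantPanel, target: str) -> str:
    for pop in panel.populations:
        if pop != target:
            return pop
    return target


def _select_for_mode(
    data: ExperimentData, config: ExperimentConfig, mode: str,
    threshold: float, seed: int,
) -> VariantSet:
    panel, sample = data.panel, data.sample
    exclude = [sample]
    pops = panel.populations
    if mode == "personalized":
        return select_variants(panel, "personalized", sample=sample)
    if mode == "empty":
        return select_variants(panel, "empty")
    if mode == "targeted":
        return select_variants(
            panel, "count_matched", pop=[config.target_pop] + [
                p for p in pops if p != config.target_pop
            ],
            threshold=threshold, exclude_samples=exclude, seed=seed,
        )
    if mode == "across":
        other = _other_pop(panel, config.target_pop)
        return select_variants(
            panel, "count_matched", pop=[other] + [
                p for p in pops if p != other
            ],
            threshold=threshold, exclude_samples=exclude, seed=seed,
        )
    if mode == "pan":
        n_match = len(
            select_variants(
                panel, "count_matched", pop=pops, threshold=threshold,
                exclude_samples=exclude, seed=seed,
            )
        )
        return select_variants(
            panel, "pan", threshold=threshold, n_target=min(
                n_match,
                len(select_variants(panel, "pan", threshold=threshold,
                                    exclude_samples=exclude)),
            ),
            exclude_samples=exclude, seed=seed,
        )
    if mode == "random":
        n_match = len(
            select_variants(
                panel, "count_matched", pop=pops, threshold=threshold,
                exclude_samples=exclude, seed=seed,
            )
        )
        # pool emulating an external catalog: most entries do not
        # segregate in the study populations and none carry phase
        pool = random_variant_catalog(data.ref, panel, 3 * panel.n_variants, seed)
        rng = np.random.default_rng(seed + 7)
        idx = np.sort(rng.choice(len(pool), size=min(n_match, len(pool)),
                                 replace=False))
        return VariantSet([pool[i] for i in idx], idx, "random_pool", seed=seed)
    if mode == "threshold":
        return select_variants(
            panel, "threshold", pop=config.target_pop, threshold=threshold,
            exclude_samples=exclude, seed=seed,
        )
    raise ValueError(f"unknown graph mode {mode!r}")


def build_reference_structure(
    data: ExperimentData, config: ExperimentConfig, mode: str,
    threshold: float, seed: int,
):
    """Return (index, truth_shift_chain, vset) for one mapping cell.

    ``truth_shift_chain`` is non-None for consensus references, whose
    coordinate system differs from the simulation reference.
    """
    if mode in ("consensus", "consensus_snp"):
        cons, chain, _ = build_consensus(
            data.ref, data.panel, config.target_pop,
            snp_only=(mode == "consensus_snp"),
        )
        return build_index(cons, k=config.seed_len), chain, None
    vset = _select_for_mode(data, config, mode, threshold, seed)
    if mode == "empty":
        return build_index(data.ref, k=config.seed_len), None, vset
    graph = build_graph(data.ref, vset, config.max_node_len)
    if mode == "personalized":
        embed = [data.sample]
    elif mode == "random":
        embed = []  # random variants carry no phase information
    else:
        embed = [s for s, _ in data.panel.samples if s != data.sample]
    hapindex = embed_haplotypes(graph, data.panel, embed)
    return build_index((graph, hapindex), k=config.seed_len), None, vset


def _shift_truth(
    reads: list[SimulatedRead], chain
) -> list[SimulatedRead]:
    """Project truth coordinates onto a consensus coordinate system."""
    out = []
    for r in reads:
        r2 = dataclasses.replace(
            r,
            true_ref_start=chain.project(r.true_ref_start, "forward"),
            true_ref_end=chain.project(max(r.true_ref_start, r.true_ref_end - 1),
                                       "forward") + 1,
        )
        out.append(r2)
    return out


def run_cell(
    data: ExperimentData, config: ExperimentConfig,
    reads: list[SimulatedRead], mode: str, threshold: float, seed: int,
) -> dict:
    """Map one replicate's reads to one reference structure and evaluate."""
    index, chain, vset = build_reference_structure(
        data, config, mode, threshold, seed
    )
    alns = map_reads(reads, index, data.scoring)
    truth = reads if chain is None else _shift_truth(reads, chain)
    evals = ev.classify_alignments(alns, truth, k=config.sim.read_len)
    summary = ev.mapping_summary(alns, evals)
    summary.update(
        mode=mode, threshold=threshold,
        n_graph_variants=len(vset) if vset is not None else 0,
    )
    return summary


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the configured cells for all replicates; return the report.

    One row per (mode, threshold, replicate). When ``outdir`` is set the
    per-cell report and a mean +- s.e. aggregate are written as TSV.
    """
    data = prepare(config)
    rows = []
    for rep in range(config.n_replicates):
        rep_seed = config.base_seed + rep
        sim = dataclasses.replace(config.sim, seed=rep_seed)
        haps = [
            extract_haplotype(data.ref, data.panel, data.sample, h) for h in (1, 2)
        ]
        reads = simulate_reads(haps, sim)
        annotate_reads(reads, data.panel, data.ref.features or None)
        for mode in config.modes:
            if mode == "threshold":
                grid = config.thresholds or default_threshold_grid()
                for thr in grid:
                    row = run_cell(data, config, reads, mode, thr, rep_seed)
                    row["replicate"] = rep
                    rows.append(row)
            else:
                row = run_cell(data, config, reads, mode, config.af_threshold,
                               rep_seed)
                row["replicate"] = rep
                rows.append(row)
    report = pd.DataFrame(rows)
    if config.outdir:
        from .io import ensure_dir

        outdir = ensure_dir(config.outdir)
        report.to_csv(f"{outdir}/cells.tsv", sep="\t", index=False)
        agg = (
            report.groupby(["mode", "threshold"])["error_rate"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        agg.to_csv(f"{outdir}/summary.tsv", sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# reference-allele-bias experiment


@dataclass
class BiasResult:
    graph_bins: list
    linear_bins: list
    het_snp_ratio_graph: float
    het_snp_ratio_sem: float
    n_het_snps: int
    graph_pileups: list[PileupSite]
    linear_pileups: list[PileupSite]


def run_bias_experiment(
    genome_length: int = 200_000,
    n_variants: int = 1200,
    indel_fraction: float = 0.25,
    max_indel: int = 40,
    coverage: float = 30.0,
    read_len: int = 150,
    sub_rate: float = 0.01,
    indel_rate: float = 0.002,
    seed: int = 0,
    graph_variants: str = "personalized",
) -> BiasResult:
    """Graph vs linear allelic ratios at heterozygous sites of one diploid.

    Simulates unbiased reads from a synthetic diploid, maps them to a
    graph containing the sample's variants and to the linear reference,
    piles both up at the truly heterozygous sites, and summarizes the
    allelic ratio by signed variant length. The elevated indel fraction
    relative to a natural panel populates the length bins the bias
    profile stratifies on.
    """
    ref = generate_reference(genome_length, seed=seed)
    panel = simulate_population(
        ref, [("A", 8)], n_variants, indel_fraction=indel_fraction,
        max_indel=max_indel, shared_fraction=1.0, seed=seed + 1,
    )
    sample = panel.samples[0][0]
    gt = panel.genotypes(sample)
    het_idx = np.nonzero(gt == 1)[0]
    het_sites = [panel.variants[i] for i in het_idx]
    het_positions = {v.pos for v in het_sites}

    haps = [extract_haplotype(ref, panel, sample, h) for h in (1, 2)]
    n_pairs = int(coverage * genome_length / (2 * read_len))
    sim = SimParams(
        read_len=read_len, n_pairs=n_pairs, sub_rate=sub_rate,
        indel_rate=indel_rate, seed=seed + 2,
    )
    reads = simulate_reads(haps, sim)

    vset = select_variants(panel, graph_variants, sample=sample)
    graph = build_graph(ref, vset)
    hapindex = embed_haplotypes(graph, panel, [sample])
    gindex = build_index((graph, hapindex))
    lindex = build_index(ref)
    graph_positions = {v.pos for v in vset.variants}

    filters = Filters(min_qd=0.0, min_mq=0.0, min_dp=0)
    g_calls = pileup_and_call(map_reads(reads, gindex), ref, het_sites, filters)
    l_calls = pileup_and_call(map_reads(reads, lindex), ref, het_sites, filters)
    g_pile = [c.site for c in g_calls]
    l_pile = [c.site for c in l_calls]
    g_bins = ev.allelic_ratio_profile(g_pile, het_positions, graph_positions)
    l_bins = ev.allelic_ratio_profile(l_pile, het_positions, graph_positions)

    snp_ratios = [
        p.allelic_ratio
        for p in g_pile
        if p.variant.vclass == "SNP" and p.allelic_ratio is not None
        and p.dp >= 20 and p.variant.pos in graph_positions
    ]
    arr = np.asarray(snp_ratios, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return BiasResult(
        g_bins, l_bins,
        float(arr.mean()) if len(arr) else float("nan"), sem, len(arr),
        g_pile, l_pile,
    )
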