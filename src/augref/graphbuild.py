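"""Variation-graph construction from a linear backbone plus variants.

The graph model matches the one used for population-augmented
references built from biallelic SNPs and short indels: backbone nodes
spell the linear reference in chunks of at most ``max_node_len`` bases,
every variant contributes a bubble (a parallel single-allele node for
SNPs, an extra node for insertions, a bypass edge for deletions), and
phased haplotypes are embedded as source-to-sink walks. All edges are
forward-strand; the graph is a DAG by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthpop import ReferenceSequence, Variant, VariantPanel

DEFAULT_MAX_NODE_LEN = 32


# ---------------------------------------------------------------------------
# variant selection


@dataclass
class VariantSet:
    """A selected subset of a panel's variants plus its provenance."""

    variants: list[Variant]
    indices: np.ndarray
    mode: str
    pop: str | None = None
    threshold: float | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.variants)


def _private_to(panel: VariantPanel, sample_ids: list[str]) -> np.ndarray:
    """Mask of variants whose alternate alleles occur only in ``sample_ids``."""
    rows = []
    for sid in sample_ids:
        i = panel.sample_index(sid)
        rows += [2 * i, 2 * i + 1]
    others = np.setdiff1d(np.arange(panel.haplotypes.shape[0]), rows)
    carried = panel.haplotypes.sum(axis=0) > 0
    outside = panel.haplotypes[others].sum(axis=0) > 0
    return carried & ~outside


def select_variants(
    panel: VariantPanel,
    mode: str,
    pop: str | list[str] | None = None,
    threshold: float = 0.0,
    n_target: int | None = None,
    sample: str | None = None,
    exclude_samples: list[str] | None = None,
    seed: int = 0,
) -> VariantSet:
    """Select variants for graph construction.

    Modes
    -----
    ``threshold``
        alternate allele frequency strictly greater than ``threshold``
        in population ``pop``.
    ``count_matched``
        as ``threshold`` for each population in ``pop`` (a list, first
        entry is the target); the target's passing set is randomly
        subsampled to the minimum passing count across populations.
    ``pan``
        threshold applied to the frequency pooled over all populations.
    ``random_pool``
        ``n_target`` variants drawn uniformly, ignoring frequency and
        phase.
    ``personalized``
        exactly the variants carried by ``sample``.
    ``empty``
        no variants.

    Alleles observed only in ``exclude_samples`` are removed from the
    candidate pool of every mode except ``personalized``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    eligible = np.ones(panel.n_variants, dtype=bool)
    if exclude_samples and mode != "personalized":
        eligible &= ~_private_to(panel, list(exclude_samples))

    if mode == "empty":
        idx = np.array([], dtype=np.int64)
    elif mode == "personalized":
        if sample is None:
            raise ValueError("personalized mode needs a sample id")
        i = panel.sample_index(sample)
        carried = panel.haplotypes[2 * i] + panel.haplotypes[2 * i + 1]
        idx = np.nonzero(carried > 0)[0]
    elif mode == "random_pool":
        pool = np.nonzero(eligible)[0]
        if n_target is None or n_target > len(pool):
            raise ValueError("n_target missing or exceeds pool size")
        idx = np.sort(rng.choice(pool, size=n_target, replace=False))
    elif mode == "pan":
        idx = np.nonzero(eligible & (panel.af(None) > threshold))[0]
        if n_target is not None:
            if n_target > len(idx):
                raise ValueError("n_target exceeds passing set")
            idx = np.sort(rng.choice(idx, size=n_target, replace=False))
    elif mode == "threshold":
        if not isinstance(pop, str):
            raise ValueError("threshold mode needs a single population label")
        idx = np.nonzero(eligible & (panel.af(pop) > threshold))[0]
        if n_target is not None:
            if n_target > len(idx):
                raise ValueError("n_target exceeds passing set")
            idx = np.sort(rng.choice(idx, size=n_target, replace=False))
    elif mode == "count_matched":
        pops = [pop] if isinstance(pop, str) else list(pop or panel.populations)
        passing = {
            p: np.nonzero(eligible & (panel.af(p) > threshold))[0] for p in pops
        }
        m = min(len(v) for v in passing.values())
        target = passing[pops[0]]
        idx = target if len(target) == m else np.sort(
            rng.choice(target, size=m, replace=False)
        )
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return VariantSet(
        [panel.variants[i] for i in idx],
        idx.astype(np.int64),
        mode,
        pop=pop if isinstance(pop, str) else (pop[0] if pop else None),
        threshold=threshold,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# graph construction


@dataclass
class Bubble:
    kind: str  # SNP | INS | DEL
    variant: Variant
    alt_node: int | None  # parallel/insertion node; None for deletions
    pred: int | None  # backbone node preceding the bubble
    succ: int | None  # backbone node following the bubble
    deleted: tuple[int, ...] = ()  # backbone nodes bypassed by a deletion


@dataclass
class VariationGraph:
    nodes: dict[int, str]
    edges: set[tuple[int, int]]
    backbone: list[int]
    ref_offset: dict[int, tuple[int, int] | None]
    bubbles: dict[Variant, Bubble]
    ref_name: str = "chrS"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def spell(self, walk: list[int]) -> str:
        return "".join(self.nodes[n] for n in walk)

    def successors(self, node: int) -> list[int]:
        return sorted(v for u, v in self.edges if u == node)

    def node_ref_start(self, node: int) -> int | None:
        iv = self.ref_offset.get(node)
        return None if iv is None else iv[0]

    def topo_order(self) -> list[int]:
        indeg = {n: 0 for n in self.nodes}
        adj: dict[int, list[int]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            indeg[v] += 1
        stack = sorted((n for n, d in indeg.items() if d == 0), reverse=True)
        order = []
        while stack:
            n = stack.pop()
            order.append(n)
            for v in sorted(adj[n], reverse=True):
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order


@dataclass
class HaplotypeIndex:
    """Embedded haplotype walks, the functional analog of a GBWT index."""

    walks: dict[tuple[str, int], list[int]]


@dataclass
class GraphStats:
    n_nodes: int
    n_edges: int
    edge_node_ratio: float
    total_length: int
    kmer_paths: int | None = None
    capped: bool = False


def _chunk(length: int, max_node_len: int) -> list[int]:
    """Chunk sizes for a backbone segment; remainder merges into the last."""
    if length <= 0:
        return []
    full, rem = divmod(length, max_node_len)
    if full == 0:
        return [rem]
    sizes = [max_node_len] * full
    if rem:
        sizes[-1] += rem
    return sizes


def build_graph(
    ref: ReferenceSequence,
    variants: VariantSet | list[Variant],
    max_node_len: int = DEFAULT_MAX_NODE_LEN,
) -> VariationGraph:
    """Build a variation graph from a reference and non-overlapping variants."""
    vlist = variants.variants if isinstance(variants, VariantSet) else list(variants)
    vlist = sorted(vlist, key=lambda v: v.pos)
    L = ref.length
    breaks = {0, L}
    prev_end = -1
    for v in vlist:
        if v.pos < 0 or v.end > L:
            raise ValueError(f"variant at {v.pos} outside reference")
        if v.pos < prev_end:
            raise ValueError(f"overlapping variants near {v.pos}")
        prev_end = v.end
        if v.vclass == "SNP":
            breaks.update((v.pos, v.pos + 1))
        elif v.vclass == "INS":
            breaks.add(v.pos + 1)
        else:  # DEL: bubble spans the deleted bases after the anchor
            breaks.update((v.pos + 1, v.end))
    bounds = sorted(breaks)

    nodes: dict[int, str] = {}
    ref_offset: dict[int, tuple[int, int] | None] = {}
    backbone: list[int] = []
    start_of: dict[int, int] = {}  # ref start -> node id
    end_of: dict[int, int] = {}  # ref end -> node id
    nid = 0
    for seg_start, seg_end in zip(bounds, bounds[1:]):
        pos = seg_start
        for size in _chunk(seg_end - seg_start, max_node_len):
            nodes[nid] = ref.sequence[pos : pos + size]
            ref_offset[nid] = (pos, pos + size)
            start_of[pos] = nid
            end_of[pos + size] = nid
            backbone.append(nid)
            pos += size
            nid += 1
    edges = {(a, b) for a, b in zip(backbone, backbone[1:])}

    bubbles: dict[Variant, Bubble] = {}
    for v in vlist:
        if v.vclass == "SNP":
            pred = end_of.get(v.pos)
            succ = start_of.get(v.pos + 1)
            alt = nid
            nodes[alt] = v.alt
            ref_offset[alt] = None
            nid += 1
            if pred is not None:
                edges.add((pred, alt))
            if succ is not None:
                edges.add((alt, succ))
            bubbles[v] = Bubble("SNP", v, alt, pred, succ)
        elif v.vclass == "INS":
            pred = end_of.get(v.pos + 1)
            succ = start_of.get(v.pos + 1)
            alt = nid
            nodes[alt] = v.alt[1:]
            ref_offset[alt] = None
            nid += 1
            if pred is not None:
                edges.add((pred, alt))
            if succ is not None:
                edges.add((alt, succ))
            bubbles[v] = Bubble("INS", v, alt, pred, succ)
        else:  # DEL
            pred = end_of.get(v.pos + 1)
            succ = start_of.get(v.end)
            deleted = []
            p = v.pos + 1
            while p < v.end:
                n = start_of[p]
                deleted.append(n)
                p = ref_offset[n][1]
            if pred is not None and succ is not None:
                edges.add((pred, succ))
            bubbles[v] = Bubble("DEL", v, None, pred, succ, tuple(deleted))
    graph = VariationGraph(nodes, edges, backbone, ref_offset, bubbles, ref.name)
    return graph


# ---------------------------------------------------------------------------
# haplotype embedding


def embed_haplotypes(
    graph: VariationGraph,
    panel: VariantPanel,
    samples: list[str] | None = None,
) -> HaplotypeIndex:
    """Embed sample haplotypes as walks through the graph.

    Variants carried by a haplotype but absent from the graph are
    traversed via the reference allele, so every haplotype always has a
    walk.
    """
    samples = samples if samples is not None else [s for s, _ in panel.samples]
    node_at = {graph.ref_offset[n]: n for n in graph.backbone}
    walks: dict[tuple[str, int], list[int]] = {}
    for sid in samples:
        for hap in (1, 2):
            ind = panel.sample_haplotype(sid, hap)
            carried = [
                panel.variants[j]
                for j in np.nonzero(ind)[0]
                if panel.variants[j] in graph.bubbles
            ]
            replace: dict[int, int] = {}
            skip: set[int] = set()
            insert_after: dict[int, list[int]] = {}
            for v in carried:
                b = graph.bubbles[v]
                if b.kind == "SNP":
                    replace[node_at[(v.pos, v.pos + 1)]] = b.alt_node
                elif b.kind == "INS":
                    insert_after.setdefault(b.pred, []).append(b.alt_node)
                else:
                    skip.update(b.deleted)
            walk: list[int] = []
            for n in graph.backbone:
                if n in skip:
                    continue
                walk.append(replace.get(n, n))
                for alt in insert_after.get(n, ()):
                    walk.append(alt)
            walks[(sid, hap)] = walk
    return HaplotypeIndex(walks)


# ---------------------------------------------------------------------------
# statistics


def _count_kmer_paths(graph: VariationGraph, k: int, cap: int) -> tuple[int, bool]:
    """Count k-length sequence paths (start base + node chain) with a cap."""
    succs = {n: graph.successors(n) for n in graph.nodes}
    memo: dict[tuple[int, int], int] = {}

    def ext(node: int, need: int) -> int:
        if need <= 0:
            return 1
        key = (node, need)
        if key in memo:
            return memo[key]
        total = 0
        for s in succs[node]:
            total += ext(s, need - len(graph.nodes[s]))
            if total > cap:
                break
        memo[key] = total
        return total

    total = 0
    for n, seq in graph.nodes.items():
        for off in range(len(seq)):
            total += ext(n, k - (len(seq) - off))
            if total > cap:
                return cap, True
    return total, False


def _count_walk_kmers(
    graph: VariationGraph, hapindex: HaplotypeIndex, k: int, cap: int
) -> tuple[int, bool]:
    """Distinct k-length windows over embedded haplotype walks."""
    seen: set[tuple] = set()
    for walk in hapindex.walks.values():
        lens = [len(graph.nodes[n]) for n in walk]
        starts = np.concatenate([[0], np.cumsum(lens)])
        total = int(starts[-1])
        wi = 0
        for off in range(total - k + 1):
            while starts[wi + 1] <= off:
                wi += 1
            wj = wi
            while starts[wj + 1] < off + k:
                wj += 1
            seen.add((off - int(starts[wi]), tuple(walk[wi : wj + 1])))
            if len(seen) >= cap:
                return cap, True
    return len(seen), False


def graph_stats(
    graph: VariationGraph,
    hapindex: HaplotypeIndex | None = None,
    k: int | None = None,
    cap: int = 10_000_000,
) -> GraphStats:
    """Node/edge counts, edge-to-node ratio and (optionally) k-mer paths."""
    n_nodes = graph.n_nodes
    n_edges = graph.n_edges
    total_length = sum(len(s) for s in graph.nodes.values())
    kmer_paths = None
    capped = False
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        if hapindex is not None:
            kmer_paths, capped = _count_walk_kmers(graph, hapindex, k, cap)
        else:
            kmer_paths, capped = _count_kmer_paths(graph, k, cap)
    return GraphStats(
        n_nodes,
        n_edges,
        n_edges / n_nodes if n_nodes else 0.0,
        total_length,
        kmer_paths,
        capped,
    )
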