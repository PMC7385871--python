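"""Haplotype-aware simulation of short sequencing reads.

Reads are drawn from phased haplotype sequences (reference plus applied
alleles) with truth annotation carried along: the source haplotype, the
error-free fragment interval and its liftover onto reference
coordinates, the strand, and whether the read covers a non-reference
allele of its source haplotype. Defaults follow common short-read
simulation settings: 2 x 150 bp pairs, fragment length 500 +- 50, a 1%
substitution and 0.2% indel error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .coords import ChainMap, apply_alleles
from .synthpop import ReferenceSequence, Variant, VariantPanel

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HaplotypeSequence:
    sample: str
    hap: int
    sequence: str
    coord_map: ChainMap  # reference (source) -> haplotype (target)
    variants: list[Variant] = field(default_factory=list)  # applied alleles

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimParams:
    read_len: int = 150
    n_pairs: int = 10_000  # total fragments across all haplotypes
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    sub_rate: float = 0.01
    indel_rate: float = 0.002
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("error rates must lie in [0, 1)")
        if self.read_len < 1 or self.n_pairs < 0:
            raise ValueError("read_len and n_pairs must be positive")


@dataclass
class SimulatedRead:
    id: str
    mate: int  # 1 | 2; 0 for single-end
    sequence: str
    sample: str
    hap: int
    true_ref_start: int
    true_ref_end: int
    strand: str  # '+' | '-'
    hap_start: int  # error-free segment start on the haplotype
    frag_len: int
    n_sub_err: int = 0
    n_indel_err: int = 0
    contains_nonref: bool | None = None
    region_labels: frozenset[str] = frozenset()


def extract_haplotype(
    ref: ReferenceSequence, panel: VariantPanel, sample: str, hap: int
) -> HaplotypeSequence:
    """Apply a sample haplotype's alternate alleles to the reference."""
    ind = panel.sample_haplotype(sample, hap)
    carried = [panel.variants[j] for j in np.nonzero(ind)[0]]
    seq, chain = apply_alleles(ref, carried)
    return HaplotypeSequence(sample, hap, seq, chain, carried)


def _inject_errors(
    seg: str, read_len: int, sub_rate: float, indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Inject substitution and 1-bp indel errors, keeping read_len bases.

    ``seg`` carries a few buffer bases past read_len so deletions can be
    refilled from the true downstream sequence.
    """
    n_sub = int(rng.binomial(read_len, sub_rate)) if sub_rate else 0
    n_ind = int(rng.binomial(read_len, indel_rate)) if indel_rate else 0
    if not n_sub and not n_ind:
        return seg[:read_len], 0, 0
    bases = list(seg)
    if n_sub:
        for p in rng.choice(read_len, size=n_sub, replace=False):
            old = bases[p]
            alts = [b for b in "ACGT" if b != old]
            bases[p] = alts[int(rng.integers(3))]
    for _ in range(n_ind):
        p = int(rng.integers(min(read_len, len(bases))))
        if rng.random() < 0.5:  # 1-bp insertion of a random base
            bases.insert(p, "ACGT"[int(rng.integers(4))])
        elif len(bases) > 1:  # 1-bp deletion, refilled from the buffer
            del bases[p]
    out = "".join(bases[:read_len])
    if len(out) < read_len:  # ran out of buffer; pad with random bases
        out += "".join("ACGT"[i] for i in rng.integers(0, 4, size=read_len - len(out)))
    return out, n_sub, n_ind


def _truth_interval(chain: ChainMap, h0: int, h1: int) -> tuple[int, int]:
    """Reference interval of a haplotype segment (first/last mappable base)."""
    start = None
    for p in range(h0, h1):
        start = chain.reverse(p)
        if start is not None:
            break
    end = None
    for p in range(h1 - 1, h0 - 1, -1):
        end = chain.reverse(p)
        if end is not None:
            break
    if start is None or end is None:  # fully inside inserted material
        start = end = chain.project(min(h0, chain.tgt_len - 1), "reverse")
    return start, end + 1


def simulate_reads(
    haps: list[HaplotypeSequence], params: SimParams
) -> list[SimulatedRead]:
    """Simulate reads with truth annotation from haplotype sequences.

    Fragments are drawn uniformly along each haplotype (equal fragment
    counts per haplotype) with Normal(frag_mean, frag_sd) lengths
    truncated at read_len. Mate 1 is the 5' end on the forward strand,
    mate 2 the 3' end reverse-complemented. Truth coordinates refer to
    the error-free segment, lifted to reference coordinates.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    min_len = int(params.frag_mean + 4 * params.frag_sd)
    for h in haps:
        if h.length < min_len:
            raise ValueError(f"haplotype {h.sample}/{h.hap} shorter than {min_len} bp")
    reads: list[SimulatedRead] = []
    n_haps = len(haps)
    per_hap = [params.n_pairs // n_haps] * n_haps
    for i in range(params.n_pairs - sum(per_hap)):
        per_hap[i] += 1
    counter = 0
    for h, n_frag in zip(haps, per_hap):
        L = h.length
        for _ in range(n_frag):
            flen = int(round(rng.normal(params.frag_mean, params.frag_sd)))
            flen = max(rl, min(flen, L))
            start = int(rng.integers(0, L - flen + 1))
            rid = f"sim{counter:07d}_{h.sample}_h{h.hap}"
            counter += 1
            if params.paired:
                specs = [(1, start, "+"), (2, start + flen - rl, "-")]
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                specs = [(0, start, strand)]
            for mate, s0, strand in specs:
                seg = h.sequence[s0 : s0 + rl + 8]
                if strand == "-":
                    seg = revcomp(h.sequence[max(0, s0 - 8) : s0 + rl])
                seq, n_sub, n_ind = _inject_errors(
                    seg, rl, params.sub_rate, params.indel_rate, rng
                )
                t0, t1 = _truth_interval(h.coord_map, s0, s0 + rl)
                reads.append(
                    SimulatedRead(
                        rid, mate, seq, h.sample, h.hap, t0, t1, strand,
                        s0, flen, n_sub, n_ind,
                    )
                )
    return reads


def annotate_reads(
    reads: list[SimulatedRead],
    panel: VariantPanel,
    annotations: list[tuple[int, int, str]] | None = None,
) -> list[SimulatedRead]:
    """Flag reads covering non-reference alleles; attach region labels.

    ``contains_nonref`` is true iff the source haplotype carries at least
    one alternate allele whose reference span overlaps the read's truth
    interval. Region labels are assigned by the truth midpoint.
    """
    pos = panel.positions
    ends = np.array([v.end for v in panel.variants], dtype=np.int64)
    hap_cache: dict[tuple[str, int], np.ndarray] = {}
    tree = None
    if annotations:
        tree = IntervalTree()
        for s, e, label in annotations:
            if e > s:
                tree.addi(s, e, label)
    for r in reads:
        key = (r.sample, r.hap)
        if key not in hap_cache:
            hap_cache[key] = panel.sample_haplotype(r.sample, r.hap)
        ind = hap_cache[key]
        lo = np.searchsorted(ends, r.true_ref_start, side="right")
        hi = np.searchsorted(pos, r.true_ref_end, side="left")
        r.contains_nonref = bool(ind[lo:hi].any())
        if tree is not None:
            mid = (r.true_ref_start + r.true_ref_end) // 2
            r.region_labels = frozenset(iv.data for iv in tree.at(mid))
    return reads
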