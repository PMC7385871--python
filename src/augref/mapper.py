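"""Deterministic seed-and-extend read mapping to linear and graph references.

The mapper is deliberately minimal but captures the behaviours the
evaluation statistics depend on:

* exact k-mer seeding with diagonal clustering;
* extension by an edit-distance-optimal path (edlib) re-scored with
  affine-gap constants (match +1, mismatch -4, gap open -6, extend -1);
* end clipping whenever a trimmed sub-alignment out-scores the
  full-length one -- the mechanism that suppresses reads spanning long
  insertions on a linear reference;
* graph-aware extension: candidate windows are evaluated under local
  allele combinations of the graph's variants (combinations observed in
  the embedded haplotype walks, plus all-reference and all-alternate),
  and the winning alignment is surjected back to linear coordinates;
* phred-scaled mapping quality MQ = min(60, 6 * (best - second best)),
  zero on exact ties, with a fragment-length prior in paired mode.

Mapping is fully deterministic: ties are broken towards the lowest
reference position.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .graphbuild import HaplotypeIndex, VariationGraph
from .readsim import SimulatedRead, revcomp
from .synthpop import ReferenceSequence, Variant

DEFAULT_SEED_LEN = 21


@dataclass
class Scoring:
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    min_score: int = 40  # below this a read is reported unmapped
    seed_stride: int = 7
    max_candidates: int = 8
    max_seed_hits: int = 100
    max_combos: int = 12
    locus_radius: int = 30  # candidates closer than this are one locus
    secondary_margin: int = 18
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    pair_bonus: float = 6.0


@dataclass
class AlignmentRecord:
    read_id: str
    mate: int
    mapped: bool
    ref_pos: int | None = None  # leftmost aligned reference base (0-based)
    ref_end: int | None = None  # end (exclusive) of the aligned span
    strand: str = "+"
    score: float = 0.0
    mq: int = 0
    edit_distance: int = 0
    soft_clip: int = 0
    n_secondary: int = 0
    seq_fwd: str = ""  # read sequence oriented to the reference forward strand


def walk_alleles(graph: VariationGraph, walk: list[int]) -> np.ndarray:
    """0/1 alternate-allele indicators of a walk over the graph's bubbles."""
    nodes = set(walk)
    out = np.zeros(len(graph.bubbles), dtype=np.int8)
    for j, (v, b) in enumerate(
        sorted(graph.bubbles.items(), key=lambda kv: kv[0].pos)
    ):
        if b.kind == "DEL":
            out[j] = 1 if (b.deleted and b.deleted[0] not in nodes) else 0
        else:
            out[j] = 1 if b.alt_node in nodes else 0
    return out


@dataclass
class MapIndex:
    kind: str  # 'linear' | 'graph'
    k: int
    ref: ReferenceSequence
    seeds: dict[str, list[int]]
    variants: list[Variant]  # graph bubbles, position-sorted (empty if linear)
    var_pos: np.ndarray
    var_end: np.ndarray
    hap_alleles: np.ndarray | None = None  # walks x variants indicators
    capped: bool = False

    @property
    def n_seed_positions(self) -> int:
        return sum(len(v) for v in self.seeds.values())


def _seed_table(seq: str, k: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        table.setdefault(seq[i : i + k], []).append(i)
    return table


def build_index(
    target: ReferenceSequence | tuple[VariationGraph, HaplotypeIndex | None],
    k: int = DEFAULT_SEED_LEN,
    cap: int | None = None,
) -> MapIndex:
    """Build a seed index over a linear reference or a variation graph.

    For graphs, the linear backbone is indexed at every position and each
    bubble contributes the k-mers of its alternate-allele context
    (k-1 bases of reference flank on both sides), assigned to the
    surrounding reference coordinates. ``cap`` bounds the total number of
    seed positions; the index is marked capped when it is hit.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if isinstance(target, ReferenceSequence):
        if k > target.length:
            raise ValueError("k exceeds target length")
        return MapIndex(
            "linear", k, target, _seed_table(target.sequence, k),
            [], np.array([], dtype=np.int64), np.array([], dtype=np.int64),
        )
    graph, hapindex = target
    ref_seq = graph.spell(graph.backbone)
    ref = ReferenceSequence(graph.ref_name, ref_seq)
    if k > ref.length:
        raise ValueError("k exceeds target length")
    table = _seed_table(ref_seq, k)
    variants = sorted(graph.bubbles, key=lambda v: v.pos)
    capped = False
    total = sum(len(v) for v in table.values())
    for v in variants:
        left = ref_seq[max(0, v.pos - (k - 1)) : v.pos]
        right = ref_seq[v.end : v.end + (k - 1)]
        ctx = left + v.alt + right
        base = v.pos - len(left)
        for i in range(len(ctx) - k + 1):
            table.setdefault(ctx[i : i + k], []).append(min(base + i, ref.length - 1))
            total += 1
            if cap is not None and total >= cap:
                capped = True
                break
        if capped:
            break
    hap_alleles = None
    if hapindex is not None and hapindex.walks:
        hap_alleles = np.unique(
            np.stack([walk_alleles(graph, w) for w in hapindex.walks.values()]),
            axis=0,
        )
    return MapIndex(
        "graph", k, ref, table, variants,
        np.array([v.pos for v in variants], dtype=np.int64),
        np.array([v.end for v in variants], dtype=np.int64),
        hap_alleles, capped,
    )


# ---------------------------------------------------------------------------
# alignment scoring


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            ops.append((n, ch))
            n = 0
    return ops


def _score_ops(ops: list[tuple[int, str]], sc: Scoring):
    """Affine score of an alignment path plus its best end-trimmed version.

    Returns (full_score, best) with best = (score, read_clip_left,
    read_clip_right, tgt_trim_left, tgt_trim_right, edit_distance).
    """
    run_score = []
    for n, op in ops:
        if op == "=":
            run_score.append(n * sc.match)
        elif op == "X":
            run_score.append(-n * sc.mismatch)
        else:  # I or D
            run_score.append(-(sc.gap_open + n * sc.gap_extend))
    full = sum(run_score)
    # max-scoring contiguous run range (Kadane); clipping is free
    best_sum, best_range = 0.0, None
    cur, cur_start = 0.0, 0
    for i, s in enumerate(run_score):
        if cur <= 0:
            cur, cur_start = s, i
        else:
            cur += s
        if cur > best_sum:
            best_sum, best_range = cur, (cur_start, i)
    if best_range is None or best_sum <= full:
        ed = sum(n for n, op in ops if op != "=")
        return full, (full, 0, 0, 0, 0, ed)
    i0, i1 = best_range
    rl = sum(n for n, op in ops[:i0] if op in "=XI")
    rr = sum(n for n, op in ops[i1 + 1 :] if op in "=XI")
    tl = sum(n for n, op in ops[:i0] if op in "=XD")
    tr = sum(n for n, op in ops[i1 + 1 :] if op in "=XD")
    ed = sum(n for n, op in ops[i0 : i1 + 1] if op != "=")
    return full, (best_sum, rl, rr, tl, tr, ed)


@dataclass
class _Hit:
    score: float
    ref_pos: int
    ref_end: int
    strand: str
    edit_distance: int
    soft_clip: int
    seq_fwd: str


def _splice_window(
    index: MapIndex, wstart: int, wend: int, combo: np.ndarray, lo: int, hi: int
) -> tuple[str, list[tuple[int, int, int]]]:
    """Window sequence under an allele combination plus target->ref blocks."""
    ref = index.ref.sequence
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []  # (tgt_start, ref_start, len)
    cur_ref = wstart
    cur_tgt = 0
    for j in range(lo, hi):
        if not combo[j - lo]:
            continue
        v = index.variants[j]
        if v.pos < cur_ref:
            continue
        seg = ref[cur_ref : v.pos]
        if seg:
            blocks.append((cur_tgt, cur_ref, len(seg)))
            pieces.append(seg)
            cur_tgt += len(seg)
            cur_ref = v.pos
        if v.length_delta == 0:
            pieces.append(v.alt)
            blocks.append((cur_tgt, cur_ref, 1))
            cur_tgt += 1
            cur_ref += 1
        else:
            anchor = min(len(v.ref), len(v.alt))
            pieces.append(v.alt)
            blocks.append((cur_tgt, cur_ref, anchor))
            cur_tgt += len(v.alt)
            cur_ref = v.end
    seg = ref[cur_ref:wend]
    if seg:
        blocks.append((cur_tgt, cur_ref, len(seg)))
        pieces.append(seg)
    return "".join(pieces), blocks


def _tgt_to_ref(blocks: list[tuple[int, int, int]], t: int) -> int:
    """Map a window-target coordinate to reference (surjection rule).

    Coordinates inside inserted material take the preceding aligned base.
    """
    prev = blocks[0][1]
    for ts, rs, ln in blocks:
        if t < ts:
            return prev
        if t < ts + ln:
            return rs + (t - ts)
        prev = rs + ln - 1
    return prev


class _CandidateEvaluator:
    def __init__(self, index: MapIndex, sc: Scoring):
        self.index = index
        self.sc = sc
        self.pad = 60

    def evaluate(self, seq: str, diag: int, strand: str) -> _Hit | None:
        index, sc = self.index, self.sc
        L = index.ref.length
        wstart = max(0, diag - self.pad)
        wend = min(L, diag + len(seq) + self.pad)
        targets: list[tuple[str, list[tuple[int, int, int]] | None]] = []
        if index.kind == "graph" and len(index.var_pos):
            lo = int(np.searchsorted(index.var_end, wstart, side="right"))
            hi = int(np.searchsorted(index.var_pos, wend, side="left"))
        else:
            lo = hi = 0
        if hi > lo:
            n = hi - lo
            combos = [np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)]
            if index.hap_alleles is not None:
                local = np.unique(index.hap_alleles[:, lo:hi], axis=0)
                combos.extend(local[: self.sc.max_combos])
            seen = set()
            for combo in combos:
                key = combo.tobytes()
                if key in seen:
                    continue
                seen.add(key)
                targets.append(_splice_window(index, wstart, wend, combo, lo, hi))
        else:
            targets.append((index.ref.sequence[wstart:wend], None))
        best: _Hit | None = None
        for tseq, blocks in targets:
            if len(tseq) < len(seq) - self.pad:
                continue
            res = edlib.align(seq, tseq, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            t0, _t1 = res["locations"][0]
            ops = _parse_cigar(res["cigar"])
            _full, (score, rl, rr, tl, tr, ed) = _score_ops(ops, sc)
            t_start = t0 + tl
            t_len = sum(n for n, op in ops if op in "=XD") - tl - tr
            if blocks is None:
                ref_pos = wstart + t_start
                ref_end = wstart + t_start + t_len
            else:
                if not blocks:
                    continue
                ref_pos = _tgt_to_ref(blocks, t_start)
                ref_end = _tgt_to_ref(blocks, max(t_start, t_start + t_len - 1)) + 1
            hit = _Hit(score, ref_pos, ref_end, strand, ed, rl + rr, seq)
            if best is None or (hit.score, -hit.ref_pos) > (best.score, -best.ref_pos):
                best = hit
        return best


def _candidate_diagonals(
    seq: str, index: MapIndex, sc: Scoring
) -> list[tuple[int, int]]:
    """Cluster seed hits by diagonal; return [(diag, n_hits)] sorted."""
    k = index.k
    votes: dict[int, int] = {}
    for off in range(0, len(seq) - k + 1, sc.seed_stride):
        hits = index.seeds.get(seq[off : off + k])
        if hits is None or len(hits) > sc.max_seed_hits:
            continue
        for p in hits:
            d = p - off
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return []
    clusters: list[tuple[int, int]] = []
    for d in sorted(votes):
        if clusters and d - clusters[-1][0] <= 16:
            prev_d, prev_n = clusters[-1]
            best_d = d if votes[d] > prev_n else prev_d
            clusters[-1] = (best_d, prev_n + votes[d])
        else:
            clusters.append((d, votes[d]))
    clusters.sort(key=lambda c: (-c[1], c[0]))
    return clusters[: sc.max_candidates]


def _align_single(seq: str, index: MapIndex, ev: _CandidateEvaluator,
                  sc: Scoring) -> list[_Hit]:
    """Best hit per locus, both strands, sorted by (score desc, pos asc)."""
    hits: list[_Hit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for diag, _n in _candidate_diagonals(s, index, sc):
            h = ev.evaluate(s, diag, strand)
            if h is not None:
                hits.append(h)
    hits.sort(key=lambda h: (-h.score, h.ref_pos, h.strand))
    # collapse hits within locus_radius to the best one
    loci: list[_Hit] = []
    for h in hits:
        if all(abs(h.ref_pos - o.ref_pos) > sc.locus_radius for o in loci):
            loci.append(h)
    return loci


def _record(read: SimulatedRead, hit: _Hit | None, mq: int, n_sec: int) -> AlignmentRecord:
    if hit is None:
        return AlignmentRecord(read.id, read.mate, False, seq_fwd=read.sequence)
    return AlignmentRecord(
        read.id, read.mate, True, hit.ref_pos, hit.ref_end, hit.strand,
        hit.score, mq, hit.edit_distance, hit.soft_clip,
        n_sec, hit.seq_fwd,  # already oriented to the forward target strand
    )


def _mq(best: float, second: float, sc: Scoring) -> int:
    if best <= second:
        return 0
    return min(60, int(6 * (best - second)))


def map_reads(
    reads: list[SimulatedRead],
    index: MapIndex,
    params: Scoring | None = None,
) -> list[AlignmentRecord]:
    """Map simulated reads; mates sharing a read id are scored jointly.

    Paired candidates on opposite strands receive a fragment-length
    bonus decaying linearly to zero at six standard deviations from the
    mean. Reads whose best score falls below ``min_score`` (or with no
    seed hit) are reported unmapped.
    """
    sc = params or Scoring()
    if reads and len(reads[0].sequence) < index.k:
        raise ValueError("read length shorter than the index seed length")
    ev = _CandidateEvaluator(index, sc)
    by_id: dict[str, list[SimulatedRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.id not in by_id:
            order.append(r.id)
            by_id[r.id] = []
        by_id[r.id].append(r)
    out: list[AlignmentRecord] = []
    for rid in order:
        group = sorted(by_id[rid], key=lambda r: r.mate)
        if len(group) == 2:
            out.extend(_map_pair(group[0], group[1], index, ev, sc))
        else:
            for r in group:
                out.append(_map_one(r, index, ev, sc))
    return out


def _map_one(read: SimulatedRead, index: MapIndex, ev, sc: Scoring) -> AlignmentRecord:
    loci = _align_single(read.sequence, index, ev, sc)
    loci = [h for h in loci if h.score >= sc.min_score]
    if not loci:
        return _record(read, None, 0, 0)
    best = loci[0]
    second = loci[1].score if len(loci) > 1 else 0.0
    n_sec = sum(1 for h in loci[1:] if h.score >= best.score - sc.secondary_margin)
    return _record(read, best, _mq(best.score, second, sc), n_sec)


def _pair_bonus(h1: _Hit, h2: _Hit, sc: Scoring) -> float:
    if h1.strand == h2.strand:
        return 0.0
    d = max(h1.ref_end, h2.ref_end) - min(h1.ref_pos, h2.ref_pos)
    return sc.pair_bonus * max(0.0, 1.0 - abs(d - sc.frag_mean) / (6 * sc.frag_sd))


def _map_pair(r1: SimulatedRead, r2: SimulatedRead, index: MapIndex, ev,
              sc: Scoring) -> list[AlignmentRecord]:
    l1 = _align_single(r1.sequence, index, ev, sc)
    l2 = _align_single(r2.sequence, index, ev, sc)
    if not l1 or not l2:
        return [_map_one(r1, index, ev, sc), _map_one(r2, index, ev, sc)]
    configs: list[tuple[float, _Hit, _Hit]] = []
    for h1 in l1:
        for h2 in l2:
            configs.append((h1.score + h2.score + _pair_bonus(h1, h2, sc), h1, h2))
    configs.sort(key=lambda c: (-c[0], c[1].ref_pos, c[2].ref_pos))
    bs, b1, b2 = configs[0]
    second1 = max(
        (s for s, h1, _ in configs if abs(h1.ref_pos - b1.ref_pos) > sc.locus_radius),
        default=0.0,
    )
    second2 = max(
        (s for s, _, h2 in configs if abs(h2.ref_pos - b2.ref_pos) > sc.locus_radius),
        default=0.0,
    )
    recs = []
    for read, hit, second, loci in ((r1, b1, second1, l1), (r2, b2, second2, l2)):
        if hit.score < sc.min_score:
            recs.append(_record(read, None, 0, 0))
            continue
        n_sec = sum(
            1
            for h in loci
            if h is not hit and h.score >= hit.score - sc.secondary_margin
        )
        recs.append(_record(read, hit, _mq(bs, second, sc), n_sec))
    return recs
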