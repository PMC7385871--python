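"""Pileup-based diploid genotyping from surjected alignments.

A deliberately transparent single-sample caller: per candidate site it
counts reads whose alignment spans the allele's reference interval and
whose sequence contains the reference or alternate allele with flanking
context, then genotypes by maximum likelihood under a binomial read
model (allele balance 0.5 for heterozygotes, error 0.01 for
homozygotes). No local realignment or soft-clip rescue is performed, so
reads clipped at indels simply drop out of the pileup -- which is
exactly the behaviour that produces reference allele bias on linear
alignments and its absence on graph alignments.

Site filters follow common hard-filter practice: quality-by-depth
QD > 10, mean mapping quality MQ > 40 and depth DP > 25 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mapper import AlignmentRecord
from .synthpop import ReferenceSequence, Variant

GENOTYPES = ("0/0", "0/1", "1/1")
#: alternate-allele probability per genotype in the binomial read model
_P_ALT = (0.01, 0.5, 0.99)

MIN_PILEUP_MQ = 10  # reads below this mapping quality are excluded
FLANK = 10  # bp of reference context required around an allele
SPAN_MARGIN = 1  # alignment must cover the allele span plus this margin


@dataclass
class Filters:
    min_qd: float = 10.0
    min_mq: float = 40.0
    min_dp: int = 25


@dataclass
class PileupSite:
    variant: Variant
    ad_ref: int
    ad_alt: int
    dp: int
    mean_mq: float

    @property
    def allelic_ratio(self) -> float | None:
        tot = self.ad_ref + self.ad_alt
        return None if tot == 0 else self.ad_alt / tot


@dataclass
class GenotypeCall:
    site: PileupSite
    genotype: str
    qual: float
    qd: float
    filter_status: str  # 'PASS' or semicolon-joined failure reasons
    reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"


def _genotype_likelihoods(ad_ref: int, ad_alt: int) -> np.ndarray:
    """Log-likelihoods of (0/0, 0/1, 1/1) from allele-support counts."""
    ll = np.empty(3)
    for g, p in enumerate(_P_ALT):
        ll[g] = ad_alt * math.log(p) + ad_ref * math.log(1.0 - p)
    return ll


def call_from_counts(ad_ref: int, ad_alt: int) -> tuple[str, float]:
    """Maximum-likelihood genotype and phred-scaled quality."""
    if ad_ref + ad_alt == 0:
        return "0/0", 0.0
    ll = _genotype_likelihoods(ad_ref, ad_alt)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    g = int(np.argmax(ll))
    err = max(1.0 - post[g], 1e-30)
    return GENOTYPES[g], min(-10.0 * math.log10(err), 300.0)


def _context_versions(
    seq: str, v: Variant, allele: str, neighbours: list[Variant]
) -> list[str]:
    """Context strings of ``allele`` at ``v`` under neighbouring-allele
    combinations (neighbours capped at three -> at most eight versions)."""
    from itertools import product

    neighbours = sorted(neighbours, key=lambda u: u.pos)[:3]
    left = [u for u in neighbours if u.end <= v.pos]
    right = [u for u in neighbours if u.pos >= v.end]
    lbase = max(0, v.pos - FLANK - 60)
    lseq0 = seq[lbase : v.pos]
    rseq0 = seq[v.end : v.end + FLANK + 60]
    versions = []
    for mask in product((0, 1), repeat=len(left) + len(right)):
        lmask, rmask = mask[: len(left)], mask[len(left) :]
        lseq = lseq0
        for u, on in sorted(zip(left, lmask), key=lambda t: -t[0].pos):
            if on and u.pos >= lbase:  # apply right-to-left: offsets stay valid
                s = u.pos - lbase
                lseq = lseq[:s] + u.alt + lseq[s + len(u.ref) :]
        rseq = rseq0
        for u, on in sorted(zip(right, rmask), key=lambda t: -t[0].pos):
            if on:
                s = u.pos - v.end
                rseq = rseq[:s] + u.alt + rseq[s + len(u.ref) :]
        versions.append(lseq[-FLANK:] + allele + rseq[:FLANK])
    return list(dict.fromkeys(versions))


def pileup_and_call(
    alignments: list[AlignmentRecord],
    ref: ReferenceSequence,
    sites: list[Variant],
    filters: Filters | None = None,
) -> list[GenotypeCall]:
    """Pile up alignments at candidate sites and call diploid genotypes.

    A read contributes to a site's depth if it is mapped with
    MQ >= 10 and its aligned span covers the allele's reference interval
    with one base of margin on both sides; it supports the reference or
    alternate allele if its sequence contains that allele embedded in
    10 bp of flanking context. Flanking context is enumerated over the
    allele combinations of neighbouring candidate sites so that nearby
    variants do not mask support. Reads matching neither context count
    towards DP only.
    """
    filters = filters or Filters()
    mapped = [
        a for a in alignments if a.mapped and a.mq >= MIN_PILEUP_MQ
    ]
    for a in mapped:
        if a.ref_pos < 0 or a.ref_end > ref.length:
            raise ValueError(f"alignment outside reference: {a.read_id}")
    starts = np.array([a.ref_pos for a in mapped], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    mapped = [mapped[i] for i in order]
    starts = starts[order]
    max_span = max((a.ref_end - a.ref_pos for a in mapped), default=0)

    calls: list[GenotypeCall] = []
    seq = ref.sequence
    sites_sorted = sorted(sites, key=lambda s: s.pos)
    for si, v in enumerate(sites_sorted):
        lo = v.pos - SPAN_MARGIN
        hi = v.end + SPAN_MARGIN
        neighbours = [
            u
            for u in sites_sorted[max(0, si - 4) : si + 5]
            if u is not v and u.end > v.pos - FLANK and u.pos < v.end + FLANK
        ]
        ref_ctxs = _context_versions(seq, v, v.ref, neighbours)
        alt_ctxs = _context_versions(seq, v, v.alt, neighbours)
        i0 = int(np.searchsorted(starts, lo - max_span, side="left"))
        i1 = int(np.searchsorted(starts, hi, side="right"))
        ad_ref = ad_alt = dp = 0
        mq_sum = 0.0
        for a in mapped[i0:i1]:
            if a.ref_pos > lo or a.ref_end < hi:
                continue
            dp += 1
            mq_sum += a.mq
            has_ref = any(c in a.seq_fwd for c in ref_ctxs)
            has_alt = any(c in a.seq_fwd for c in alt_ctxs)
            if has_ref and not has_alt:
                ad_ref += 1
            elif has_alt and not has_ref:
                ad_alt += 1
        mean_mq = mq_sum / dp if dp else 0.0
        site = PileupSite(v, ad_ref, ad_alt, dp, mean_mq)
        gt, qual = call_from_counts(ad_ref, ad_alt)
        qd = qual / dp if dp else 0.0
        reasons = []
        if qd <= filters.min_qd:
            reasons.append("QD")
        if mean_mq <= filters.min_mq:
            reasons.append("MQ")
        if dp <= filters.min_dp:
            reasons.append("DP")
        calls.append(
            GenotypeCall(
                site, gt, qual, qd,
                "PASS" if not reasons else ";".join(reasons), tuple(reasons),
            )
        )
    return calls
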