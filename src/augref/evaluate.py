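"""Evaluation statistics for read mapping and genotyping experiments.

Implements the full evaluation battery used to compare reference
structures: per-read mapping correctness (a read is correct when its
reported start lies within one read length of the truth start),
pseudo-ROC curves cumulated over descending mapping-quality thresholds,
perfect/unique mapping summaries, reference-allele-bias profiles binned
by signed variant length, and genotype-concordance metrics against a
truth set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyper import GenotypeCall, PileupSite
from .mapper import AlignmentRecord
from .readsim import SimulatedRead
from .synthpop import TruthGenotypes

MQ_THRESHOLDS = (60, 50, 40, 30, 20, 10, 0)


@dataclass
class MappingEval:
    read_id: str
    mate: int
    mapped: bool
    correct: bool
    mq: int
    contains_nonref: bool | None = None
    region_labels: frozenset[str] = frozenset()


def classify_alignments(
    alignments: list[AlignmentRecord],
    truth: list[SimulatedRead],
    k: int = 150,
) -> list[MappingEval]:
    """Mark each alignment correct/incorrect against simulated truth.

    A mapped read is correct iff |ref_pos - true_ref_start| <= k
    (k = read length by default, allowing for clipping at indels);
    unmapped reads are incorrect.
    """
    lookup = {(t.id, t.mate): t for t in truth}
    out = []
    for a in alignments:
        t = lookup.get((a.read_id, a.mate))
        if t is None:
            raise KeyError(f"read {a.read_id}/{a.mate} missing from truth")
        correct = a.mapped and abs(a.ref_pos - t.true_ref_start) <= k
        out.append(
            MappingEval(
                a.read_id, a.mate, a.mapped, bool(correct), a.mq,
                t.contains_nonref, t.region_labels,
            )
        )
    return out


def pseudo_roc(evals: list[MappingEval]) -> pd.DataFrame:
    """Cumulative TPR/FPR at MQ thresholds 60, 50, ..., 0.

    TP_k / FP_k count correctly / incorrectly mapped reads in the MQ
    bucket [k, next threshold); TPR_i and FPR_i cumulate buckets from 60
    down to i and divide by n, the total number of mapped reads.
    Unmapped reads never enter the ROC.
    """
    mapped = [e for e in evals if e.mapped]
    if not evals:
        raise ValueError("no reads to evaluate")
    n = len(mapped)
    tp = dict.fromkeys(MQ_THRESHOLDS, 0)
    fp = dict.fromkeys(MQ_THRESHOLDS, 0)
    for e in mapped:
        for thr in MQ_THRESHOLDS:
            if e.mq >= thr:
                bucket = thr
                break
        if e.correct:
            tp[bucket] += 1
        else:
            fp[bucket] += 1
    rows = []
    cum_tp = cum_fp = 0
    for thr in MQ_THRESHOLDS:
        cum_tp += tp[thr]
        cum_fp += fp[thr]
        rows.append(
            {
                "threshold": thr,
                "TPR": cum_tp / n if n else 0.0,
                "FPR": cum_fp / n if n else 0.0,
                "TP": cum_tp,
                "FP": cum_fp,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def mapping_summary(
    alignments: list[AlignmentRecord], evals: list[MappingEval]
) -> dict:
    """Headline mapping proportions.

    perfect: mapped full-length with edit distance 0 and no clipping;
    unique: single primary alignment, or MQ 60 despite secondaries;
    error_rate: incorrect (unmapped included) over all reads, plus the
    splits by MQ > 10, by non-reference-allele content, and per region
    label.
    """
    n = len(alignments)
    if n == 0:
        return {"n_reads": 0}
    perfect = sum(
        1
        for a in alignments
        if a.mapped and a.edit_distance == 0 and a.soft_clip == 0
    )
    unique = sum(
        1 for a in alignments if a.mapped and (a.n_secondary == 0 or a.mq == 60)
    )
    mapped = sum(1 for a in alignments if a.mapped)
    wrong = [e for e in evals if not e.correct]
    n_wrong = len(wrong)
    wrong_mq_gt10 = sum(1 for e in wrong if e.mapped and e.mq > 10)
    wrong_nonref = sum(1 for e in wrong if e.contains_nonref)
    summary = {
        "n_reads": n,
        "mapped": mapped / n,
        "perfect": perfect / n,
        "unique": unique / n,
        "error_rate": n_wrong / n,
        "error_mq_gt10": wrong_mq_gt10 / n,
        "error_mq_le10": (n_wrong - wrong_mq_gt10) / n,
        "error_frac_mq_gt10": wrong_mq_gt10 / n_wrong if n_wrong else 0.0,
        "error_frac_nonref": wrong_nonref / n_wrong if n_wrong else 0.0,
    }
    labels = sorted({lbl for e in evals for lbl in e.region_labels})
    for lbl in labels:
        sub = [e for e in evals if lbl in e.region_labels]
        summary[f"error_rate_{lbl}"] = (
            sum(1 for e in sub if not e.correct) / len(sub) if sub else math.nan
        )
    return summary


# ---------------------------------------------------------------------------
# reference allele bias


@dataclass
class BiasBin:
    length: int  # signed: negative deletions, 0 SNPs, positive insertions
    in_graph: bool
    n_sites: int
    mean_ratio: float
    sem: float


def allelic_ratio_profile(
    pileups: list[PileupSite],
    het_positions: set[int],
    graph_positions: set[int] | None = None,
) -> list[BiasBin]:
    """Mean +- s.e.m. allelic ratio per signed variant length.

    ``pileups`` should cover truly heterozygous sites of the evaluated
    sample; sites with zero informative reads are skipped. When
    ``graph_positions`` is given, bins are additionally split by whether
    the site's alternate allele was present in the graph.
    """
    groups: dict[tuple[int, bool], list[float]] = {}
    for p in pileups:
        if p.variant.pos not in het_positions:
            continue
        r = p.allelic_ratio
        if r is None:
            continue
        in_graph = (
            True if graph_positions is None else p.variant.pos in graph_positions
        )
        groups.setdefault((p.variant.length_delta, in_graph), []).append(r)
    bins = []
    for (delta, in_graph), vals in sorted(groups.items()):
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        bins.append(BiasBin(delta, in_graph, len(arr), float(arr.mean()), sem))
    return bins


def bias_table(bins: list[BiasBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "length": b.length,
                "in_graph": b.in_graph,
                "n_sites": b.n_sites,
                "mean_ratio": b.mean_ratio,
                "sem": b.sem,
            }
            for b in bins
        ]
    )


# ---------------------------------------------------------------------------
# genotype concordance


@dataclass
class ConcordanceReport:
    genotype_concordance: float
    nr_sensitivity: float
    precision: float
    nr_discrepancy: float
    n_sites: int
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), int))


def concordance_from_matrix(m: np.ndarray) -> ConcordanceReport:
    """Concordance metrics from a 3x3 truth-by-call genotype matrix.

    Rows are truth, columns are calls, ordered (0/0, 0/1, 1/1):
    concordance = trace / total; non-reference sensitivity =
    genotype-matching variant calls over truth variants; precision =
    genotype-matching non-reference calls over all non-reference calls;
    non-reference discrepancy = discordant cells over total minus the
    concordant homozygous-reference cell.
    """
    m = np.asarray(m, dtype=np.int64)
    if m.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype confusion matrix")
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty genotype comparison")
    trace = int(np.trace(m))
    truth_var = int(m[1:, :].sum())
    match_var = int(m[1, 1] + m[2, 2])
    called_var = int(m[:, 1:].sum())
    denom_nr = total - int(m[0, 0])
    return ConcordanceReport(
        genotype_concordance=trace / total,
        nr_sensitivity=match_var / truth_var if truth_var else math.nan,
        precision=match_var / called_var if called_var else math.nan,
        nr_discrepancy=(total - trace) / denom_nr if denom_nr else 0.0,
        n_sites=total,
        confusion=m,
    )


def concordance_metrics(
    calls: list[GenotypeCall],
    truth: TruthGenotypes,
    positions: np.ndarray | None = None,
) -> ConcordanceReport:
    """Compare called genotypes with truth at the microarray-like subset."""
    if positions is None:
        positions = truth.subset_positions()
    wanted = set(int(p) for p in positions)
    truth_gt = {int(p): int(g) for p, g in zip(truth.positions, truth.genotypes)}
    m = np.zeros((3, 3), dtype=np.int64)
    for c in calls:
        pos = c.site.variant.pos
        if pos not in wanted or pos not in truth_gt:
            continue
        called = {"0/0": 0, "0/1": 1, "1/1": 2}[c.genotype]
        m[truth_gt[pos], called] += 1
    return concordance_from_matrix(m)


# ---------------------------------------------------------------------------
# optional plotting


def plot_error_curves(report: pd.DataFrame, path: str) -> None:
    """Error rate vs allele-frequency threshold, one line per mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, sub in report.groupby("mode"):
        agg = sub.groupby("threshold")["error_rate"].mean()
        ax.plot(agg.index, agg.values, marker="o", label=str(mode))
    ax.set_xlabel("alternate allele frequency threshold")
    ax.set_ylabel("proportion of incorrectly mapped reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
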