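"""Mapping-accuracy classification, pseudo-ROC, bias and concordance."""

from fractions import Fraction

import numpy as np
import pytest

from augref.evaluate import (
    MQ_THRESHOLDS,
    MappingEval,
    allelic_ratio_profile,
    classify_alignments,
    concordance_from_matrix,
    concordance_metrics,
    mapping_summary,
    pseudo_roc,
)
from augref.genotyper import PileupSite
from augref.mapper import AlignmentRecord
from augref.readsim import SimulatedRead
from augref.synthpop import TruthGenotypes, Variant


def mk_aln(rid, pos, mq=60, mapped=True, nm=0, clip=0, nsec=0):
    return AlignmentRecord(rid, 0, mapped, pos if mapped else None,
                           (pos + 150) if mapped else None, "+", 150.0, mq,
                           nm, clip, nsec, "")


def mk_truth(rid, start, nonref=False, labels=frozenset()):
    return SimulatedRead(rid, 0, "A" * 150, "s", 1, start, start + 150, "+",
                         start, 500, contains_nonref=nonref,
                         region_labels=labels)


class TestClassify:
    def test_distance_boundary(self):
        truth = [mk_truth(f"r{i}", 1000) for i in range(3)]
        alns = [mk_aln("r0", 1000), mk_aln("r1", 1150), mk_aln("r2", 1151)]
        evals = classify_alignments(alns, truth, k=150)
        assert [e.correct for e in evals] == [True, True, False]

    def test_unmapped_incorrect(self):
        evals = classify_alignments(
            [mk_aln("r0", 0, mapped=False)], [mk_truth("r0", 5)], k=150
        )
        assert not evals[0].correct and not evals[0].mapped

    def test_missing_truth_rejected(self):
        with pytest.raises(KeyError):
            classify_alignments([mk_aln("r0", 0)], [mk_truth("other", 0)])

    def test_agrees_with_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(17)
        truth = [mk_truth(f"r{i}", int(rng.integers(0, 10_000))) for i in range(1000)]
        alns = []
        for t in truth:
            if rng.random() < 0.05:
                alns.append(mk_aln(t.id, 0, mapped=False))
            else:
                alns.append(
                    mk_aln(t.id, int(t.true_ref_start + rng.integers(-400, 400)))
                )
        evals = classify_alignments(alns, truth, k=150)
        for a, t, e in zip(alns, truth, evals):
            expected = a.mapped and abs(a.ref_pos - t.true_ref_start) <= 150
            assert e.correct == expected


class TestPseudoRoc:
    def test_all_correct_mq60(self):
        truth = [mk_truth(f"r{i}", 0) for i in range(5)]
        alns = [mk_aln(t.id, 0) for t in truth]
        df = pseudo_roc(classify_alignments(alns, truth))
        assert (df["TPR"] == 1.0).all() and (df["FPR"] == 0.0).all()

    def test_hand_computed_cumulative_sums(self):
        evals = (
            [MappingEval(f"a{i}", 0, True, True, 60) for i in range(6)]
            + [MappingEval(f"b{i}", 0, True, True, 20) for i in range(2)]
            + [MappingEval(f"c{i}", 0, True, False, 0) for i in range(2)]
        )
        df = pseudo_roc(evals).set_index("threshold")
        assert df.loc[60, "TPR"] == pytest.approx(0.6)
        assert df.loc[20, "TPR"] == pytest.approx(0.8)
        assert df.loc[0, "FPR"] == pytest.approx(0.2)

    def test_threshold_list_and_monotonicity(self):
        rng = np.random.default_rng(3)
        evals = [
            MappingEval(f"r{i}", 0, True, bool(rng.random() < 0.8),
                        int(rng.integers(0, 61)))
            for i in range(500)
        ]
        df = pseudo_roc(evals)
        assert list(df["threshold"]) == list(MQ_THRESHOLDS)
        assert (df["TPR"].diff().dropna() >= 0).all()
        assert (df["FPR"].diff().dropna() >= 0).all()
        # every mapped read counted exactly once at threshold 0
        assert df.iloc[-1]["TPR"] + df.iloc[-1]["FPR"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pseudo_roc([])


class TestMappingSummary:
    def test_perfect_definition(self):
        truth = [mk_truth(f"r{i}", 0) for i in range(10)]
        alns = [mk_aln(t.id, 0) for t in truth]
        alns[3].soft_clip = 5  # one clipped read among ten
        evals = classify_alignments(alns, truth)
        s = mapping_summary(alns, evals)
        assert s["perfect"] == pytest.approx(0.9)

    def test_unique_counts_mq60_with_secondaries(self):
        truth = [mk_truth("r0", 0)]
        a = mk_aln("r0", 0, mq=60, nsec=2)
        s = mapping_summary([a], classify_alignments([a], truth))
        assert s["unique"] == 1.0
        a2 = mk_aln("r0", 0, mq=40, nsec=2)
        s2 = mapping_summary([a2], classify_alignments([a2], truth))
        assert s2["unique"] == 0.0

    def test_error_splits(self):
        truth = [
            mk_truth("r0", 0, nonref=True, labels=frozenset({"repeat"})),
            mk_truth("r1", 0),
            mk_truth("r2", 0),
        ]
        alns = [mk_aln("r0", 5000, mq=30), mk_aln("r1", 0), mk_aln("r2", 0)]
        s = mapping_summary(alns, classify_alignments(alns, truth))
        assert s["error_rate"] == pytest.approx(1 / 3)
        assert s["error_frac_mq_gt10"] == 1.0
        assert s["error_frac_nonref"] == 1.0
        assert s["error_rate_repeat"] == 1.0


class TestAllelicRatio:
    def test_simple_ratio_and_binning(self):
        sites = [
            Variant("c", 10, "A", "T"),
            Variant("c", 50, "A", "ATTTTT"),
            Variant("c", 90, "ACGT", "A"),
        ]
        piles = [
            PileupSite(sites[0], 10, 10, 20, 60.0),
            PileupSite(sites[1], 12, 4, 16, 60.0),
            PileupSite(sites[2], 9, 9, 18, 60.0),
        ]
        het = {10, 50, 90}
        bins = allelic_ratio_profile(piles, het)
        by_len = {b.length: b for b in bins}
        assert set(by_len) == {-3, 0, 5}
        assert by_len[0].mean_ratio == pytest.approx(0.5)
        assert by_len[5].mean_ratio == pytest.approx(0.25)

    def test_zero_depth_skipped_and_graph_split(self):
        v = Variant("c", 10, "A", "T")
        piles = [PileupSite(v, 0, 0, 0, 0.0), PileupSite(v, 5, 5, 10, 60.0)]
        bins = allelic_ratio_profile(piles, {10}, graph_positions=set())
        assert len(bins) == 1 and bins[0].in_graph is False
        assert bins[0].n_sites == 1


def oracle_concordance(m):
    """Rational-arithmetic concordance oracle."""
    m = [[int(x) for x in row] for row in m]
    total = sum(sum(r) for r in m)
    trace = m[0][0] + m[1][1] + m[2][2]
    truth_var = sum(m[1]) + sum(m[2])
    match_var = m[1][1] + m[2][2]
    called_var = sum(m[i][j] for i in range(3) for j in (1, 2))
    return {
        "conc": Fraction(trace, total),
        "nrs": Fraction(match_var, truth_var) if truth_var else None,
        "prec": Fraction(match_var, called_var) if called_var else None,
        "nrd": Fraction(total - trace, total - m[0][0]) if total != m[0][0] else Fraction(0),
    }


class TestConcordance:
    def test_perfect_agreement(self):
        r = concordance_from_matrix(np.diag([10, 5, 5]))
        assert r.genotype_concordance == 1.0
        assert r.nr_discrepancy == 0.0
        assert r.nr_sensitivity == 1.0 and r.precision == 1.0

    def test_worked_matrix(self):
        m = np.array([[8, 1, 0], [1, 6, 1], [0, 1, 7]])
        r = concordance_from_matrix(m)
        assert r.genotype_concordance == pytest.approx(21 / 25)
        assert r.nr_discrepancy == pytest.approx(4 / 17, abs=1e-4)
        assert r.nr_sensitivity == pytest.approx(13 / 16)
        assert r.precision == pytest.approx(13 / 16)

    def test_het_called_homalt_cell_semantics(self):
        # truth het, called hom-alt: hurts concordance and discrepancy
        m = np.array([[10, 0, 0], [0, 9, 1], [0, 0, 10]])
        r = concordance_from_matrix(m)
        assert r.genotype_concordance == pytest.approx(29 / 30)
        assert r.nr_discrepancy == pytest.approx(1 / 20)
        assert r.nr_sensitivity == pytest.approx(19 / 20)

    def test_twenty_random_matrices_vs_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            m = rng.integers(0, 30, size=(3, 3))
            if m.sum() == 0 or m.sum() == m[0, 0]:
                continue
            r = concordance_from_matrix(m)
            o = oracle_concordance(m)
            assert r.genotype_concordance == pytest.approx(float(o["conc"]))
            assert r.nr_discrepancy == pytest.approx(float(o["nrd"]))
            if o["nrs"] is not None:
                assert r.nr_sensitivity == pytest.approx(float(o["nrs"]))
            if o["prec"] is not None:
                assert r.precision == pytest.approx(float(o["prec"]))

    def test_concordance_metrics_restricts_to_subset(self):
        from augref.genotyper import GenotypeCall

        sites = [Variant("c", p, "A", "T") for p in (10, 20, 30)]
        calls = [
            GenotypeCall(PileupSite(v, 10, 10, 20, 60.0), "0/1", 99.0, 5.0, "PASS")
            for v in sites
        ]
        truth = TruthGenotypes(
            "s", np.array([10, 20, 30]), np.array([1, 1, 0]), np.array([0, 1])
        )
        r = concordance_metrics(calls, truth)
        assert r.n_sites == 2
        assert r.genotype_concordance == 1.0

    def test_empty_overlap_rejected(self):
        truth = TruthGenotypes("s", np.array([10]), np.array([1]), np.array([0]))
        with pytest.raises(ValueError):
            concordance_metrics([], truth)
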