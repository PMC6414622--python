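"""Fisher exact test, alteration matrices, Wilcoxon and relapse summary."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from clonevo import (CNASegment, PatientRecord, build_matrix, enrich,
                     fisher_exact_two_sided, relapse_specific_summary,
                     wilcoxon_signed_rank_paired)
from clonevo.stats import _wilcoxon_approx, _wilcoxon_exact
from conftest import make_variant


def fisher_oracle(a, b, c, d):
    """Exact-integer enumeration of all tables with the observed margins."""
    n1, k = a + b, a + c
    n = a + b + c + d
    if n1 == 0 or (c + d) == 0 or k == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, k - (c + d)), min(k, n1)
    weights = {x: math.comb(n1, x) * math.comb(n - n1, k - x)
               for x in range(lo, hi + 1)}
    w_obs = weights[a]
    # integer-exact comparison of w <= w_obs * (1 + 1e-7)
    qualifying = sum(w for w in weights.values()
                     if w * 10**7 <= w_obs * (10**7 + 1))
    return qualifying / sum(weights.values())


class TestFisher:
    @pytest.mark.parametrize("table,printed", [
        ((4, 22, 0, 24), 0.11),    # NT5C2, pediatric vs adult
        ((3, 23, 8, 16), 0.09),    # TP53
        ((7, 19, 0, 24), 0.01),    # NR3C1
        ((2, 23, 9, 16), 0.04),    # IKZF1, early vs late
        ((8, 17, 1, 24), 0.02),    # PRSS3
        ((0, 26, 4, 20), 0.05),    # EZH2
        ((1, 25, 6, 18), 0.05),    # KMT2D
        ((1, 25, 7, 17), 0.02),    # CREBBP
    ])
    def test_published_tables_reproduce_at_two_decimals(self, table, printed):
        assert round(fisher_exact_two_sided(*table), 2) == printed

    @pytest.mark.parametrize("table", [
        (13, 12, 2, 23),   # CDKN2B
        (13, 12, 3, 22),   # CDKN2A
        (7, 18, 0, 25),    # PTPRD
    ])
    def test_published_bounds_below_0_01(self, table):
        assert fisher_exact_two_sided(*table) < 0.01

    def test_empty_margin_is_one(self):
        assert fisher_exact_two_sided(0, 10, 0, 10) == 1.0
        assert fisher_exact_two_sided(0, 0, 5, 5) == 1.0

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(1.5, 2, 3, 4)

    def test_matches_exact_integer_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            p = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_oracle(int(a), int(b), int(c),
                                                    int(d)), abs=1e-9)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if (a + b) and (c + d) and (a + c) and (b + d):
                expected = sps.fisher_exact([[a, b], [c, d]]).pvalue
                assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                    expected, abs=1e-7)

    def test_symmetry_under_group_and_outcome_swaps(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            p = fisher_exact_two_sided(a, b, c, d)
            assert p == pytest.approx(fisher_exact_two_sided(c, d, a, b), abs=1e-12)
            assert p == pytest.approx(fisher_exact_two_sided(b, a, d, c), abs=1e-12)


def _patient(pid, variants=(), segments=(), age="adult", days=400.0):
    return PatientRecord(patient_id=pid, age_group=age, days_to_relapse=days,
                         variants=list(variants), segments=list(segments))


class TestAlterationMatrix:
    def test_deletion_at_rel_counts_over_both_timepoints(self):
        seg = CNASegment("P1", "REL", "9", 100, 5000, "loss_het", ("CDKN2A",))
        m = build_matrix([_patient("P1", segments=[seg])], ["CDKN2A"])
        assert m.df.loc["P1", "CDKN2A"] == "deletion"

    def test_mutation_plus_deletion_is_double_hit(self):
        v = make_variant("P1", gene="IKZF1", alt_id=40, depth_id=100)
        seg = CNASegment("P1", "ID", "7", 100, 5000, "loss_het", ("IKZF1",))
        m = build_matrix([_patient("P1", variants=[v], segments=[seg])], ["IKZF1"])
        assert m.df.loc["P1", "IKZF1"] == "double_hit"

    def test_silent_only_mutation_is_none(self):
        v = make_variant("P1", gene="TP53", effect="silent", alt_id=40,
                         depth_id=100)
        m = build_matrix([_patient("P1", variants=[v])], ["TP53"])
        assert m.df.loc["P1", "TP53"] == "none"

    def test_unknown_panel_gene_warns_and_stays_none(self):
        v = make_variant("P1", gene="KRAS", alt_id=40, depth_id=100)
        with pytest.warns(UserWarning, match="NOSUCH"):
            m = build_matrix([_patient("P1", variants=[v])], ["KRAS", "NOSUCH"])
        assert (m.df["NOSUCH"] == "none").all()

    def test_relapse_specific_mode_drops_stable_mutations(self):
        stable = make_variant("P1", pos=10, gene="TP53", alt_id=40,
                              depth_id=100, alt_rel=40, depth_rel=100)
        rel_only = make_variant("P1", pos=20, gene="NT5C2", alt_id=0,
                                depth_id=100, alt_rel=40, depth_rel=100)
        m = build_matrix([_patient("P1", variants=[stable, rel_only])],
                         ["TP53", "NT5C2"], relapse_specific=True)
        assert m.df.loc["P1", "TP53"] == "none"
        assert m.df.loc["P1", "NT5C2"] == "mutation"


class TestEnrich:
    def test_three_vs_zero_of_six_gives_point_one(self):
        patients = [
            _patient(f"P{i}", variants=[make_variant(f"P{i}", gene="GENEX",
                                                     alt_id=40, depth_id=100)])
            for i in range(1, 4)] + [_patient(f"P{i}") for i in range(4, 7)]
        grouping = {f"P{i}": ("g1" if i <= 3 else "g2") for i in range(1, 7)}
        m = build_matrix(patients, ["GENEX"])
        (res,) = enrich(m, grouping)
        assert round(res.p, 2) == 0.10  # 2/C(6,3) = 0.1 by enumeration
        assert (res.a, res.b, res.c, res.d) == (3, 0, 0, 3)
        assert res.odds_ratio == float("inf")

    def test_gene_altered_in_nobody_gives_one(self):
        patients = [_patient("P1"), _patient("P2")]
        with pytest.warns(UserWarning):
            m = build_matrix(patients, ["GENEX"])
        (res,) = enrich(m, {"P1": "a", "P2": "b"})
        assert res.p == 1.0

    def test_more_than_two_groups_rejected(self):
        patients = [_patient(f"P{i}") for i in range(1, 4)]
        with pytest.warns(UserWarning):
            m = build_matrix(patients, ["GENEX"])
        with pytest.raises(ValueError, match="two groups"):
            enrich(m, {"P1": "a", "P2": "b", "P3": "c"})


class TestWilcoxon:
    def test_three_concordant_pairs_enumerate_to_quarter(self):
        # all diffs one-signed: p = 2 * (1/2^3) = 0.25
        assert wilcoxon_signed_rank_paired([1, 2, 3], [2, 4, 6]) == 0.25

    def test_identical_vectors_give_one(self):
        assert wilcoxon_signed_rank_paired([1, 2, 3], [1, 2, 3]) == 1.0

    def test_branches_agree_at_crossover_sample_size(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=25)
            y = x + rng.normal(0.3, 1.0, size=25)
            worst = max(worst, abs(_wilcoxon_exact(y - x) - _wilcoxon_approx(x, y)))
        assert worst < 0.01

    def test_exact_branch_handles_ties_via_midranks(self):
        x = [0, 0, 0, 0]
        y = [1, 1, -1, 2]  # |diffs| = 1,1,1,2 -> midranks 2,2,2,4
        p = wilcoxon_signed_rank_paired(x, y)
        assert 0.0 < p <= 1.0

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=30)
            y = x + rng.normal(0.0, 1.0, size=30)
            pvals.append(wilcoxon_signed_rank_paired(x, y))
        d, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestRelapseSpecificSummary:
    def test_rel_only_panel_missense_flags_metabolism(self):
        v = make_variant("P1", gene="FPGS", alt_id=0, depth_id=100,
                         alt_rel=40, depth_rel=100)
        res = relapse_specific_summary([_patient("P1", variants=[v])])
        assert res.per_patient == {"P1": True}
        assert res.category_counts["metabolism"] == 1

    def test_stable_only_patient_not_flagged(self):
        v = make_variant("P1", gene="FPGS", alt_id=40, depth_id=100,
                         alt_rel=40, depth_rel=100)
        res = relapse_specific_summary([_patient("P1", variants=[v])])
        assert res.per_patient == {"P1": False}

    def test_rel_specific_loss_flags_without_mutation(self):
        seg = CNASegment("P1", "REL", "9", 100, 5000, "loss_het", ("CDKN2A",))
        res = relapse_specific_summary([_patient("P1", segments=[seg])])
        assert res.per_patient == {"P1": True}

    def test_loss_present_at_both_timepoints_not_relapse_specific(self):
        segs = [CNASegment("P1", tp, "9", 100, 5000, "loss_het", ("CDKN2A",))
                for tp in ("ID", "REL")]
        res = relapse_specific_summary([_patient("P1", segments=segs)])
        assert res.per_patient == {"P1": False}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            relapse_specific_summary([_patient("P1")], panel={})

    def test_generator_flag_probability_recovered(self, small_cohort):
        patients, _, truth = small_cohort
        res = relapse_specific_summary(patients)
        # flags were drawn Bernoulli(0.8); summary must match the draws
        assert res.per_patient == {pid: bool(f)
                                   for pid, f in truth.flagged.items()}
        sigma = math.sqrt(0.8 * 0.2 / len(patients))
        assert abs(res.fraction_flagged - 0.8) <= 3 * sigma + 1e-9
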