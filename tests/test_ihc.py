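"""IHC dichotomization, 2x2 statistics and diagnostic performance."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from tissuespec import (
    ContingencyTable2x2,
    IHCRecord,
    binary_auc,
    chi_square,
    contingency,
    cross_tabulate,
    dichotomize,
    g_test,
    ordinal_auc,
    phi_correlation,
    sens_spec,
)
from tissuespec.ihc import breakdown_table, collapse_cases, read_cohort

from conftest import ACOXL_TABLE, MEM_VS_CYTO_TABLE, TMEM79_TABLE


def random_table(rng, max_count=200):
    while True:
        a, b, c, d = rng.integers(0, max_count, size=4)
        t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        if all(m > 0 for m in (*t.row_totals, *t.col_totals)):
            return t


class TestDichotomize:
    @pytest.mark.parametrize("score,expected",
                             [(0, "low"), (1, "low"), (2, "high"), (3, "high")])
    def test_cut_between_1_and_2(self, score, expected):
        assert dichotomize(score) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            dichotomize(4)


class TestContingency:
    @staticmethod
    def membranous_cohort():
        """Per-class positives matching the published membranous-marker
        breakdown: benign 127/156, GG2 0/3, GG3 17/76, GG4 7/62, GG5 2/21,
        metastasis 3/15."""
        spec = {
            "benign": (156, 127), "GG2": (3, 0), "GG3": (76, 17),
            "GG4": (62, 7), "GG5": (21, 2), "metastasis": (15, 3),
        }
        records, i = [], 0
        for hist, (n, pos) in spec.items():
            for j in range(n):
                i += 1
                records.append(IHCRecord(f"c{i}", hist, 3 if j < pos else 0,
                                         "membranous"))
        return records

    def test_published_cohort_reproduces_2x2(self):
        t = contingency(self.membranous_cohort(), compartment="membranous")
        assert (t.a, t.b, t.c, t.d) == (29, 148, 127, 29)

    def test_empty_records(self):
        t = contingency([])
        assert t.n == 0

    def test_breakdown_matches_per_class_tallies(self):
        bd = breakdown_table(self.membranous_cohort())
        assert bd.loc["positive", "benign"] == 127
        assert bd.loc["negative", "GG3"] == 59
        assert bd.to_numpy().sum() == 333

    def test_replicate_cores_collapsed_by_max(self):
        recs = [
            IHCRecord("c1", "benign", 0, "membranous"),
            IHCRecord("c1", "benign", 3, "membranous"),
            IHCRecord("c2", "GG3", 1, "membranous"),
            IHCRecord("c2", "GG3", 1, "membranous"),
        ]
        cases = collapse_cases(recs)
        assert cases.loc["c1", "score"] == 3
        t = contingency(recs)
        assert (t.a, t.b, t.c, t.d) == (0, 1, 1, 0)

    def test_conflicting_histology_rejected(self):
        recs = [IHCRecord("c1", "benign", 1), IHCRecord("c1", "GG3", 1)]
        with pytest.raises(ValueError, match="conflicting"):
            collapse_cases(recs)


class TestChiSquare:
    def test_published_marker_tables(self):
        assert chi_square(TMEM79_TABLE)[0] == pytest.approx(140.80, abs=0.01)
        assert chi_square(ACOXL_TABLE)[0] == pytest.approx(111.52, abs=0.005)
        assert chi_square(MEM_VS_CYTO_TABLE)[0] == pytest.approx(19.39, abs=0.005)

    def test_independence_gives_zero(self):
        stat, p = chi_square(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = random_table(rng)
            stat, p = chi_square(t)
            ref = sps.chi2_contingency(t.as_array(), correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_is_undefined(self):
        stat, p = chi_square(ContingencyTable2x2(0, 0, 5, 5))
        assert math.isnan(stat) and math.isnan(p)

    def test_equals_n_phi_squared(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            t = random_table(rng)
            stat, _ = chi_square(t)
            phi, _ = phi_correlation(t)
            assert stat == pytest.approx(t.n * phi**2, rel=1e-10)

    def test_row_swap_flips_phi_not_chi(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            t = random_table(rng)
            swapped = ContingencyTable2x2(t.c, t.d, t.a, t.b)
            assert chi_square(t)[0] == pytest.approx(chi_square(swapped)[0])
            assert phi_correlation(t)[0] == pytest.approx(
                -phi_correlation(swapped)[0]
            )


class TestGTest:
    def test_independence_gives_zero(self):
        assert g_test(ContingencyTable2x2(10, 10, 10, 10)) == pytest.approx(0.0)

    def test_published_table_value(self):
        assert g_test(TMEM79_TABLE) == pytest.approx(152.6, abs=0.1)

    def test_empty_cell_uses_zero_limit(self):
        val = g_test(ContingencyTable2x2(0, 10, 10, 10))
        assert math.isfinite(val)
        ref = sps.chi2_contingency(
            np.array([[0, 10], [10, 10]]), correction=False,
            lambda_="log-likelihood",
        ).statistic
        assert val == pytest.approx(ref, rel=1e-12)


class TestPhiAndDiagnostics:
    def test_published_phi_values(self):
        assert phi_correlation(TMEM79_TABLE)[0] == pytest.approx(-0.65, abs=0.005)
        assert phi_correlation(ACOXL_TABLE)[0] == pytest.approx(-0.58, abs=0.005)
        assert phi_correlation(MEM_VS_CYTO_TABLE)[0] == pytest.approx(-0.24, abs=0.005)

    def test_perfect_benign_marker_gives_minus_one(self):
        assert phi_correlation(ContingencyTable2x2(0, 9, 9, 0))[0] == -1.0

    def test_spearman_equals_phi_on_binary_data(self):
        rng = np.random.default_rng(6)
        t = random_table(rng)
        phi, rho = phi_correlation(t)
        # expand the table into paired binary observations
        x = [0] * (t.a + t.b) + [1] * (t.c + t.d)
        y = [0] * t.a + [1] * t.b + [0] * t.c + [1] * t.d
        ref = sps.spearmanr(x, y).statistic
        assert rho == pytest.approx(ref, abs=1e-12)
        assert rho == phi

    def test_sens_spec_orientation(self):
        sens, spec = sens_spec(TMEM79_TABLE)
        assert sens == pytest.approx(127 / 156)
        assert spec == pytest.approx(148 / 177)
        assert sens_spec(ACOXL_TABLE)[0] == pytest.approx(132 / 154)

    def test_all_positive_marker(self):
        sens, spec = sens_spec(ContingencyTable2x2(0, 0, 50, 50))
        assert sens == 1.0 and spec == 0.0

    def test_binary_auc(self):
        assert binary_auc(TMEM79_TABLE) == pytest.approx(0.825, abs=5e-4)
        assert binary_auc(ContingencyTable2x2(5, 5, 5, 5)) == 0.5
        assert binary_auc(ContingencyTable2x2(0, 10, 10, 0)) == 1.0

    def test_empty_class_sentinels(self):
        sens, spec = sens_spec(ContingencyTable2x2(0, 10, 0, 0))
        assert math.isnan(sens) and spec == 1.0
        assert math.isnan(binary_auc(ContingencyTable2x2(0, 5, 0, 5)))


class TestOrdinalAuc:
    def brute_force(self, scores, cond):
        pairs = list(itertools.product(
            [s for s, c in zip(scores, cond) if c],
            [s for s, c in zip(scores, cond) if not c],
        ))
        wins = sum(1.0 for a, b in pairs if a > b)
        ties = sum(0.5 for a, b in pairs if a == b)
        return (wins + ties) / len(pairs)

    def test_identical_distributions_give_half(self):
        scores = [0, 1, 2, 3, 0, 1, 2, 3]
        cond = [True] * 4 + [False] * 4
        assert ordinal_auc(scores, cond) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert ordinal_auc([3, 3, 0, 0], [True, True, False, False]) == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 4, size=n).tolist()
            cond = rng.random(n) < 0.5
            if cond.all() or not cond.any():
                continue
            assert ordinal_auc(scores, cond) == pytest.approx(
                self.brute_force(scores, cond), abs=1e-12
            )

    def test_dichotomized_scores_match_binary_auc(self):
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 4, size=400)
        cond = rng.random(400) < 0.5  # condition = benign
        hi = scores >= 2
        t = ContingencyTable2x2(
            a=int((~hi & cond).sum()), b=int((~hi & ~cond).sum()),
            c=int((hi & cond).sum()), d=int((hi & ~cond).sum()),
        )
        assert ordinal_auc(hi.astype(int), cond) == pytest.approx(binary_auc(t))


class TestCrossTabulate:
    def test_published_membranous_vs_cytoplasmic(self):
        t, stats_ = cross_tabulate(
            [False] * 178 + [True] * 155,
            [False] * 105 + [True] * 73 + [False] * 126 + [True] * 29,
        )
        assert (t.a, t.b, t.c, t.d) == (105, 73, 126, 29)
        assert stats_.chi_square == pytest.approx(19.39, abs=0.005)
        assert stats_.pearson_r == pytest.approx(-0.24, abs=0.005)

    def test_identical_statuses_give_phi_one(self):
        status = [True] * 10 + [False] * 10
        _, stats_ = cross_tabulate(status, status)
        assert stats_.pearson_r == pytest.approx(1.0)


class TestReadCohort:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "cohort.tsv"
        p.write_text(
            "case_id\thistology\tcompartment\tscore\n"
            "c1\tbenign\tmembranous\t3\n"
            "c2\tGG3\tmembranous\t0\n"
        )
        recs = read_cohort(p)
        assert len(recs) == 2 and recs[0].score == 3

    def test_bad_score_names_row(self, tmp_path):
        p = tmp_path / "cohort.tsv"
        p.write_text(
            "case_id\thistology\tcompartment\tscore\n"
            "c1\tbenign\tmembranous\t5\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_cohort(p)

    def test_unknown_histology_names_row(self, tmp_path):
        p = tmp_path / "cohort.tsv"
        p.write_text(
            "case_id\thistology\tcompartment\tscore\n"
            "c1\tweird\tmembranous\t1\n"
        )
        with pytest.raises(ValueError, match="histology"):
            read_cohort(p)
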