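"""Wilcoxon signed-rank test, group comparison, and stratified tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ntcpselect.dvh import DoseMetricSet
from ntcpselect.records import PatientCovariates
from ntcpselect.selection import mbs_eligibility
from ntcpselect.stats import (build_cohort_table, compare_groups_cts,
                              dose_delta_summary, passing_rate_table,
                              round_half_up, wilcoxon_signed_rank)


def brute_force_wilcoxon_p(d):
    """Independent oracle: exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[list(signs)]) for signs in
          itertools.product([False, True], repeat=len(d))]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_same_sign_n6(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 2**6)
        assert r.significant

    def test_symmetric_pairs_null_center(self):
        r = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_all_zero_degenerate(self):
        r = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert r.degenerate and r.p_value == 1.0

    def test_zeros_dropped_before_ranking(self):
        a = wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5])
        b = wilcoxon_signed_rank([1.0, 2.0, -0.5])
        assert a.p_value == b.p_value and a.n == b.n == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_branch_matches_brute_force_enumeration(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(0.4, 1.0, 10)
        result = wilcoxon_signed_rank(d)
        assert result.method == "exact"
        assert result.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_exact_branch_with_ties_matches_brute_force(self):
        d = [1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 1.0, -2.0]
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            brute_force_wilcoxon_p(d), abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_exact_matches_scipy_exact(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(0.5, 1.0, 11)  # continuous: no ties, no zeros
        ours = wilcoxon_signed_rank(d).p_value
        theirs = sps.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    @pytest.mark.parametrize("n", [10, 11, 12])
    def test_exact_and_normal_branches_agree(self, n):
        r = np.random.default_rng(n)
        for _ in range(20):
            d = r.normal(0.3, 1.0, n)
            exact = wilcoxon_signed_rank(d).p_value
            approx = wilcoxon_signed_rank(d, exact_max_n=0).p_value
            assert approx == pytest.approx(exact, abs=0.01)

    def test_large_n_consistent_with_scipy_normal_approx(self):
        r = np.random.default_rng(5)
        d = r.normal(0.2, 1.0, 40)
        ours = wilcoxon_signed_rank(d)
        assert ours.method == "normal_approx"
        theirs = sps.wilcoxon(d, correction=True, method="approx").pvalue
        # scipy's plain normal approximation differs from the Edgeworth-
        # corrected one by its own approximation error; consistency only
        assert ours.p_value == pytest.approx(theirs, abs=0.01)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        g = compare_groups_cts([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert g.testable and g.p_value > 0.9
        assert g.mean_eligible == g.mean_not_eligible

    def test_shift_detected_at_cohort_scale(self):
        # eligible-group CTS shifted +3 at n=50: detect in >=95% of replicates
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(6.3, 1.4, 20)
            b = rng.normal(3.3, 1.4, 30)
            if compare_groups_cts(a, b).significant:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_empty_group_not_testable(self):
        g = compare_groups_cts([], [1.0, 2.0])
        assert not g.testable and g.p_value is None

    def test_single_patient_group_flagged(self):
        g = compare_groups_cts([5.0], [1.0, 2.0, 3.0])
        assert g.testable and "underpowered" in g.note

    def test_signed_rank_variant_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            compare_groups_cts([1.0, 2.0], [1.0], method="signed_rank")
        g = compare_groups_cts([2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                               [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                               method="signed_rank")
        assert g.method == "signed_rank" and g.testable


def _cohort(registry, pass_ids_by_patient, covs=None):
    """Build a cohort table from per-patient lists of passing model ids."""
    results = []
    covariates = []
    for i, pass_ids in enumerate(pass_ids_by_patient):
        pid = f"P{i:03d}"
        d = {m: 0.0 for m in registry.model_ids}
        for m in pass_ids:
            d[m] = registry[m].threshold_standard + 5.0
        results.append(mbs_eligibility(pid, d, registry.thresholds("standard"),
                                       registry.weights()))
        if covs is not None:
            c = covs[i]
        else:
            c = dict(t_stage=1, n_stage=0)
        covariates.append(PatientCovariates(pid, 50, c["t_stage"], c["n_stage"],
                                            "II", "RT-CHT"))
    return build_cohort_table(covariates, results)


class TestPassingRateTable:
    def test_twelve_of_fifty_is_24_percent(self, registry):
        passes = [["xerostomia_loizeau2021"]] * 12 + [[]] * 38
        table = passing_rate_table(_cohort(registry, passes))
        assert table.loc["xerostomia_loizeau2021", "all"] == 24.0

    def test_zero_pass_row(self, registry):
        table = passing_rate_table(_cohort(registry, [[]] * 10))
        assert table.loc["rion_palorini2019", "all"] == 0.0
        assert table.loc["eligibility", "all"] == 0.0

    def test_single_stratum_equals_all_column(self, registry):
        passes = [["xerostomia_loizeau2021"]] * 3 + [[]] * 7
        table = passing_rate_table(_cohort(registry, passes))
        # every synthetic patient is T1/N0 here
        assert (table["T1-T2"] == table["all"]).all()
        assert table.loc["xerostomia_loizeau2021", "T3-T4"] == "n=0"

    def test_all_column_is_size_weighted_stratum_average(self, registry):
        rng = np.random.default_rng(3)
        covs = [dict(t_stage=int(rng.integers(1, 5)),
                     n_stage=int(rng.integers(0, 4))) for _ in range(40)]
        passes = [["xerostomia_loizeau2021"] if rng.random() < 0.3 else []
                  for _ in range(40)]
        cohort = _cohort(registry, passes, covs)
        table = passing_rate_table(cohort)
        n1 = table.loc["n", "T1-T2"]
        n2 = table.loc["n", "T3-T4"]
        blended = (table.loc["single", "T1-T2"] * n1
                   + table.loc["single", "T3-T4"] * n2) / (n1 + n2)
        assert blended == pytest.approx(table.loc["single", "all"], abs=0.1)

    def test_rounding_half_away_from_zero(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(12.45, 1) == 12.5
        assert round_half_up(-0.25, 1) == -0.3


class TestDoseDeltaSummary:
    @staticmethod
    def _metrics(davg, d1):
        return DoseMetricSet(D99=0, D98=0, D95=0, D50=0, D2=0, D1=d1, Davg=davg)

    def test_identical_plans_zero(self):
        m = {"P1": {"cord": self._metrics(20.0, 38.0)}}
        out = dose_delta_summary(m, m).set_index("structure")
        assert out.loc["cord", "delta_davg_gy"] == 0.0
        assert out.loc["cord", "delta_d1_gy"] == 0.0

    def test_constant_fractional_sparing_recovered(self):
        photon = {f"P{i}": {"cord": self._metrics(20.0 + i, 40.0)}
                  for i in range(5)}
        proton = {p: {"cord": self._metrics(s["cord"].Davg * 0.86, 40.0)}
                  for p, s in photon.items()}
        out = dose_delta_summary(photon, proton).set_index("structure")
        assert out.loc["cord", "delta_davg_pct"] == pytest.approx(14.0, abs=1e-9)

    def test_one_patient_cohort_equals_its_deltas(self):
        photon = {"P1": {"cord": self._metrics(22.0, 40.0)}}
        proton = {"P1": {"cord": self._metrics(17.0, 36.0)}}
        out = dose_delta_summary(photon, proton).set_index("structure")
        assert out.loc["cord", "delta_davg_gy"] == pytest.approx(5.0)
        assert out.loc["cord", "delta_d1_gy"] == pytest.approx(4.0)
        assert out.loc["cord", "n"] == 1

    def test_missing_structure_averaged_over_available_pairs(self):
        photon = {"P1": {"cord": self._metrics(20.0, 40.0)},
                  "P2": {"cord": self._metrics(30.0, 50.0),
                         "brain": self._metrics(10.0, 45.0)}}
        proton = {"P1": {"cord": self._metrics(10.0, 40.0)},
                  "P2": {"cord": self._metrics(20.0, 50.0)}}
        out = dose_delta_summary(photon, proton).set_index("structure")
        assert out.loc["cord", "n"] == 2
        assert "brain" not in out.index
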