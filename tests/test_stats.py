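"""Cohort statistics: prevalence, correlation, two-group tests, survival."""

import numpy as np
import pytest

from conftest import make_call, make_profile
from stromaclone.stats import (
    ClinicalRecord,
    group_compare,
    km_curve,
    prevalence_table,
    survival_analysis,
    vaf_correlation,
)


def record(pid, dfs, event, group_noise=0.0, **kw):
    defaults = dict(
        age=65.0,
        sex="M",
        stage_ii_iv=False,
        tumor_size_gt4cm=False,
        poor_differentiation=False,
        lymph_node=False,
        nerve_invasion=True,
        vascular_invasion=False,
        adjuvant_chemo=True,
        tcf=0.5,
    )
    defaults.update(kw)
    return ClinicalRecord(patient_id=pid, dfs_months=dfs, event=event, **defaults)


class TestPrevalence:
    def test_single_patient_single_gene(self):
        table = prevalence_table([make_profile([make_call(gene="KRAS")])])
        row = table.iloc[0]
        assert (row.gene, row.n_patients, row.percent) == ("KRAS", 1, 100.0)

    def test_multiple_mutations_count_one_patient(self):
        prof = make_profile([make_call(pos=1, gene="KRAS"), make_call(pos=2, gene="KRAS")])
        table = prevalence_table([prof])
        assert table.iloc[0].n_patients == 1


class TestVafCorrelation:
    def test_monotone_pairs(self):
        rho, rho2, p = vaf_correlation([(0.1, 0.2), (0.2, 0.3), (0.3, 0.5), (0.4, 0.6)])
        assert rho2 == pytest.approx(1.0)
        assert rho > 0

    def test_antimonotone_pairs_report_negative_rho(self):
        rho, rho2, _ = vaf_correlation([(0.1, 0.6), (0.2, 0.5), (0.3, 0.2)])
        assert rho2 == pytest.approx(1.0)
        assert rho == pytest.approx(-1.0)

    def test_co_truncal_simulation_correlates(self):
        """Two truncal mutations sampled with binomial noise from a shared
        per-specimen allele dosage stay strongly rank-correlated."""
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(20):
            dosage = rng.uniform(0.1, 0.5)  # per-specimen TCF/2
            pairs.append(
                (
                    rng.binomial(1000, dosage) / 1000,
                    rng.binomial(1000, dosage) / 1000,
                )
            )
        _, rho2, p = vaf_correlation(pairs)
        assert rho2 > 0.5
        assert p < 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            vaf_correlation([(0.1, 0.2), (0.2, 0.3)])


class TestGroupCompare:
    def test_chi_square_matches_textbook_formula(self):
        """Pearson statistic on the clonality table equals sum((O-E)^2/E)."""
        table = np.array([[99, 15], [72, 62]], dtype=float)
        chi2, p = group_compare(table, test="chi_square")
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(by_hand)
        assert p < 1e-4

    def test_mann_whitney_detects_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.6, 0.1, 40)
        b = rng.normal(0.4, 0.1, 40)
        _, p = group_compare([a, b], test="mann_whitney")
        assert p < 1e-4

    def test_mann_whitney_null_is_calm(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 0.1, 40)
        b = rng.normal(0.5, 0.1, 40)
        _, p = group_compare([a, b], test="mann_whitney")
        assert p > 0.01

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.ones((3, 2)), test="chi_square")


class TestSurvival:
    def test_km_matches_hand_computed_product_limit(self):
        """Five patients, events at 1, 2 and 4, censored at 3 and 5."""
        curve = km_curve([1, 2, 3, 4, 5], [True, True, False, True, False])
        surv = dict(zip(curve.time, curve.survival))
        assert surv[1.0] == pytest.approx(4 / 5)
        assert surv[2.0] == pytest.approx(4 / 5 * 3 / 4)
        assert surv[4.0] == pytest.approx(4 / 5 * 3 / 4 * 1 / 2)

    def test_forced_medians(self):
        records = [record(f"A{i}", 1.0, True) for i in range(5)]
        records += [record(f"B{i}", 10.0, False) for i in range(5)]
        flags = {r.patient_id: r.patient_id.startswith("A") for r in records}
        res = survival_analysis(records, flags)
        assert res.median_dfs[0] == pytest.approx(1.0)
        assert res.median_dfs[1] is None  # unreached stays unreached

    def test_identical_groups_near_null(self):
        rng = np.random.default_rng(3)
        records = []
        flags = {}
        for i in range(120):
            t = float(rng.exponential(10.0))
            c = float(rng.uniform(0, 30))
            records.append(record(f"P{i}", min(t, c), t <= c))
            flags[f"P{i}"] = i % 2 == 0
        res = survival_analysis(records, flags)
        assert 0.6 < res.hazard_ratio < 1.7
        assert res.logrank_p > 0.05

    def test_cox_consistency_large_sample(self):
        """With no censoring and exponential times the Cox HR converges to
        the true value (checked within 10% at n=2000)."""
        rng = np.random.default_rng(4)
        true_hr = 2.5
        records = []
        flags = {}
        for i in range(2000):
            grp = i % 2 == 0
            rate = 0.1 * (true_hr if grp else 1.0)
            records.append(record(f"P{i}", float(rng.exponential(1 / rate)), True))
            flags[f"P{i}"] = grp
        res = survival_analysis(records, flags)
        assert res.hazard_ratio == pytest.approx(true_hr, rel=0.10)
        assert res.hr_ci[0] <= true_hr <= res.hr_ci[1]

    def test_multivariate_forward_selection_recovers_real_covariate(self):
        """A covariate with a genuine effect enters the forward-LR model."""
        rng = np.random.default_rng(6)
        records = []
        flags = {}
        for i in range(300):
            grp = i % 2 == 0
            node = rng.random() < 0.4
            rate = 0.05 * (3.0 if grp else 1.0) * (2.5 if node else 1.0)
            t = float(rng.exponential(1 / rate))
            c = float(rng.uniform(0, 40))
            records.append(record(f"P{i}", min(t, c), t <= c, lymph_node=node))
            flags[f"P{i}"] = grp
        res = survival_analysis(records, flags, multivariate=True)
        assert res.multivariate is not None
        assert "lymph_node" in res.multivariate.index

    def test_zero_events_rejected(self):
        records = [record(f"P{i}", 5.0, False) for i in range(4)]
        flags = {r.patient_id: i % 2 == 0 for i, r in enumerate(records)}
        with pytest.raises(ValueError, match="event"):
            survival_analysis(records, flags)

    def test_single_group_rejected(self):
        records = [record(f"P{i}", 5.0, True) for i in range(4)]
        flags = {r.patient_id: True for r in records}
        with pytest.raises(ValueError, match="two nonempty groups"):
            survival_analysis(records, flags)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        records = []
        flags = {}
        for i in range(60):
            t = float(rng.exponential(8.0))
            c = float(rng.uniform(0, 30))
            records.append(record(f"P{i}", min(t, c), t <= c))
            flags[f"P{i}"] = i < 30
        a = survival_analysis(records, flags)
        b = survival_analysis(records[::-1], flags)
        assert a.hazard_ratio == pytest.approx(b.hazard_ratio)
        assert a.logrank_p == pytest.approx(b.logrank_p)
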