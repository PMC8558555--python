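"""Generator properties: trees, stromal seeding, read sampling, outcomes."""

import dataclasses

import numpy as np
import pytest

from stromaclone.simulate import (
    PatientTruth,
    SimulationConfig,
    SubtypeNotRealizable,
    generate_patient,
    sample_reads,
    seed_stroma,
    simulate_clinical,
    simulate_clone_tree,
    simulate_cohort,
)


def truth_of(clones, private=(), subtype="A", tcf=0.6, pid="P001"):
    return PatientTruth(
        patient_id=pid,
        clones=clones,
        stroma_private=list(private),
        subtype=subtype,
        tcf=tcf,
    )


class TestCloneTree:
    def test_degenerate_single_clone_single_driver(self):
        config = SimulationConfig(
            clone_count_range=(1, 1),
            passengers_per_clone=0.0,
            trunk_driver_probs={"KRAS": 1.0},
        )
        clones = simulate_clone_tree(config, np.random.default_rng(0))
        assert len(clones) == 1
        assert clones[0].ccf_neoplasm == 1.0
        assert [m.gene for m in clones[0].mutations] == ["KRAS"]
        assert clones[0].mutations[0].is_driver

    def test_seeded_determinism(self):
        config = SimulationConfig(seed=7, n_patients=1)
        a = simulate_clone_tree(config, np.random.default_rng(7))
        b = simulate_clone_tree(config, np.random.default_rng(7))
        assert [dataclasses.asdict(c) for c in a] == [dataclasses.asdict(c) for c in b]

    def test_child_ccf_below_parent(self):
        config = SimulationConfig(clone_count_range=(4, 5))
        rng = np.random.default_rng(1)
        for _ in range(200):
            clones = simulate_clone_tree(config, rng)
            by_index = {c.index: c for c in clones}
            for c in clones:
                if c.parent is not None:
                    assert c.ccf_neoplasm <= by_index[c.parent].ccf_neoplasm + 1e-12

    def test_poisson_passenger_mean(self):
        """Law of large numbers: mean passengers per clone near the rate."""
        config = SimulationConfig(
            passengers_per_clone=3.0, trunk_driver_probs={}, clone_count_range=(2, 5)
        )
        rng = np.random.default_rng(12345)
        total = clones_n = 0
        for _ in range(10_000):
            clones = simulate_clone_tree(config, rng)
            clones_n += len(clones)
            total += sum(len(c.mutations) for c in clones)
        assert total / clones_n == pytest.approx(3.0, abs=0.1)


class TestSeedStroma:
    def _tree(self, seed=0, **kw):
        defaults = dict(clone_count_range=(3, 3), passengers_per_clone=2.0)
        defaults.update(kw)
        return simulate_clone_tree(SimulationConfig(**defaults), np.random.default_rng(seed))

    def test_c_zeroes_everything(self):
        clones = self._tree()
        seed_stroma(clones, "C", SimulationConfig(), np.random.default_rng(0))
        assert all(c.ccf_stroma == 0.0 for c in clones)

    def test_b_keeps_trunk_drops_a_descendant(self):
        clones = self._tree(seed=2)
        seed_stroma(clones, "B", SimulationConfig(), np.random.default_rng(0))
        assert clones[0].ccf_stroma > 0
        assert any(c.ccf_stroma == 0.0 and c.mutations for c in clones[1:])

    def test_single_clone_cannot_be_b(self):
        clones = self._tree(clone_count_range=(1, 1))
        with pytest.raises(SubtypeNotRealizable):
            seed_stroma(clones, "B", SimulationConfig(), np.random.default_rng(0))

    def test_stromal_ccf_never_exceeds_neoplastic(self):
        rng = np.random.default_rng(3)
        config = SimulationConfig()
        for target in "ABCD":
            for i in range(30):
                truth = generate_patient("P", target, config, np.random.default_rng(i))
                for c in truth.clones:
                    assert c.ccf_stroma <= c.ccf_neoplasm + 1e-12

    @pytest.mark.parametrize("target", ["A", "B", "C", "D"])
    def test_noise_free_subtype_predicate_holds(self, target):
        """True stromal seeding always satisfies the target's definition."""
        config = SimulationConfig()
        for i in range(40):
            truth = generate_patient("P", target, config, np.random.default_rng(100 + i))
            muts = [m for c in truth.clones for m in c.mutations]
            shared = {m.key for m in muts if m.ccf_stroma > 0}
            drivers = {m.key for m in muts if m.is_driver}
            clones_with_muts = [c for c in truth.clones if c.mutations]
            all_present = all(
                any(m.ccf_stroma > 0 for m in c.mutations) for c in clones_with_muts
            )
            trunk = truth.clones[0]
            trunk_drivers = {m.key for m in trunk.mutations if m.is_driver}
            if target == "A":
                assert all_present and drivers <= shared
            elif target == "B":
                assert any(m.ccf_stroma > 0 for m in trunk.mutations)
                assert trunk_drivers and trunk_drivers <= shared
                assert not all_present
            elif target == "C":
                assert not shared
            else:
                trunk_absent = all(m.ccf_stroma == 0 for m in trunk.mutations)
                drivers_absent = not (drivers & shared)
                assert shared and (trunk_absent or drivers_absent)


class TestSampleReads:
    def _one_mutation_truth(self, ccf_neoplasm, tcf):
        clones = simulate_clone_tree(
            SimulationConfig(
                clone_count_range=(1, 1),
                passengers_per_clone=0.0,
                trunk_driver_probs={"KRAS": 1.0},
            ),
            np.random.default_rng(0),
        )
        clones[0].ccf_neoplasm = ccf_neoplasm
        for m in clones[0].mutations:
            m.ccf_neoplasm = ccf_neoplasm
        return truth_of(clones, tcf=tcf)

    def test_zero_ccf_yields_no_reads(self):
        truth = self._one_mutation_truth(0.0, tcf=1.0)
        rng = np.random.default_rng(1)
        calls = sample_reads(truth, SimulationConfig(), rng, with_noise=False)
        assert calls["neoplasm"] == []

    def test_heterozygous_limit(self):
        """CCF=1 and TCF=1 pushes VAF toward one half at high depth."""
        truth = self._one_mutation_truth(1.0, tcf=1.0)
        config = SimulationConfig(mean_depth=100_000, depth_dispersion=1e6)
        rng = np.random.default_rng(2)
        vafs = []
        for _ in range(50):
            calls = sample_reads(truth, config, rng, with_noise=False)
            vafs.append(calls["neoplasm"][0].vaf)
        assert np.mean(vafs) == pytest.approx(0.5, abs=0.005)

    def test_binomial_expectation(self):
        """Mean VAF over many draws matches CCF x TCF / 2."""
        truth = self._one_mutation_truth(0.8, tcf=0.5)
        config = SimulationConfig()
        rng = np.random.default_rng(3)
        vafs = []
        for _ in range(10_000):
            calls = sample_reads(truth, config, rng, with_noise=False)
            vafs.append(calls["neoplasm"][0].vaf if calls["neoplasm"] else 0.0)
        assert np.mean(vafs) == pytest.approx(0.2, abs=0.005)

    def test_detection_calibration_at_five_percent_vaf(self):
        """Variants at true VAF 5% survive depth sampling and the read/VAF
        thresholds in >99% of draws at 1000x."""
        truth = self._one_mutation_truth(0.2, tcf=0.5)  # expected VAF 0.05
        config = SimulationConfig()
        rng = np.random.default_rng(4)
        detected = 0
        n = 3000
        for _ in range(n):
            calls = sample_reads(truth, config, rng, with_noise=False)
            if calls["neoplasm"]:
                c = calls["neoplasm"][0]
                detected += c.hq_alt_reads >= 5 and c.vaf >= 0.01
        assert detected / n > 0.99

    def test_germline_noise_lands_in_all_components(self):
        config = SimulationConfig(germline_snps_per_patient=4.0, seed=9)
        truth = generate_patient("P", "A", config, np.random.default_rng(5))
        calls = sample_reads(truth, config, np.random.default_rng(6))
        blood_keys = {c.key for c in calls["blood"]}
        assert blood_keys
        assert blood_keys <= {c.key for c in calls["normal"]} | blood_keys


class TestClinical:
    def test_zero_horizon_censors_everything(self):
        config = SimulationConfig(censoring_horizon=0.0)
        truths = [
            truth_of(
                simulate_clone_tree(SimulationConfig(), np.random.default_rng(i)),
                subtype="A",
                pid=f"P{i}",
            )
            for i in range(5)
        ]
        records = simulate_clinical(truths, config, np.random.default_rng(0))
        assert all(r.dfs_months == 0.0 and not r.event for r in records)

    def test_cox_recovers_simulated_hazard_ratio(self):
        """One cohort at true HR 3 estimates within a wide sanity band."""
        from stromaclone.stats import survival_analysis

        cohort = simulate_cohort(SimulationConfig(n_patients=200, seed=77))
        flags = {t.patient_id: t.neoplasm_like for t in cohort.truths}
        res = survival_analysis(cohort.clinical, flags)
        assert 2.0 <= res.hazard_ratio <= 4.5

    def test_null_hazard_ratio_is_flat(self):
        from stromaclone.stats import survival_analysis

        cohort = simulate_cohort(
            SimulationConfig(n_patients=200, neoplasm_like_hazard_ratio=1.0, seed=13)
        )
        flags = {t.patient_id: t.neoplasm_like for t in cohort.truths}
        res = survival_analysis(cohort.clinical, flags)
        assert 0.5 <= res.hazard_ratio <= 2.0


class TestCohort:
    def test_bit_reproducible(self):
        a = simulate_cohort(SimulationConfig(n_patients=4, seed=21))
        b = simulate_cohort(SimulationConfig(n_patients=4, seed=21))
        for pid in a.calls:
            for comp in a.calls[pid]:
                assert [dataclasses.asdict(x) for x in a.calls[pid][comp]] == [
                    dataclasses.asdict(x) for x in b.calls[pid][comp]
                ]
        assert [dataclasses.asdict(r) for r in a.clinical] == [
            dataclasses.asdict(r) for r in b.clinical
        ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="subtype_mix"):
            SimulationConfig(subtype_mix=(0.5, 0.5, 0.5, 0.5)).validate()
        with pytest.raises(ValueError, match="clone_count_range"):
            SimulationConfig(clone_count_range=(0, 3)).validate()
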