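"""Normalized-VAF clonality, partitioning, CCF arithmetic and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call, make_profile
from stromaclone.calls import MutationTableError
from stromaclone.clonality import (
    best_partition,
    brute_force_partition,
    cluster_clones,
    compute_ccf,
    map_partition_loglik,
    normalize_vafs,
    partition_mutations,
)


class TestNormalizeVafs:
    def test_single_mutation_is_clonal_by_definition(self):
        (nm,) = normalize_vafs(make_profile([make_call(vaf=0.07)]))
        assert nm.normalized_vaf == 1.0 and nm.clonal

    def test_direct_arithmetic(self):
        norms = normalize_vafs(
            make_profile([make_call(pos=1, vaf=0.40), make_call(pos=2, vaf=0.19)])
        )
        by_pos = {nm.key[1]: nm for nm in norms}
        assert by_pos[1].normalized_vaf == pytest.approx(1.0)
        assert by_pos[2].normalized_vaf == pytest.approx(0.475)
        assert by_pos[1].clonal and not by_pos[2].clonal

    def test_tie_at_half_is_clonal(self):
        norms = normalize_vafs(
            make_profile([make_call(pos=1, vaf=0.4), make_call(pos=2, vaf=0.2)])
        )
        assert all(nm.clonal for nm in norms)

    def test_empty_profile_yields_empty(self):
        assert normalize_vafs(make_profile([])) == []

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(min_value=0.05, max_value=1.0))
    def test_scale_invariance(self, scale):
        """Multiplying all VAFs by a constant changes nothing downstream."""
        vafs = [0.31, 0.22, 0.09, 0.45]
        base = normalize_vafs(
            make_profile([make_call(pos=i, vaf=v) for i, v in enumerate(vafs, 1)])
        )
        scaled = normalize_vafs(
            make_profile(
                [make_call(pos=i, vaf=v * scale) for i, v in enumerate(vafs, 1)]
            )
        )
        for a, b in zip(base, scaled):
            assert a.normalized_vaf == pytest.approx(b.normalized_vaf)
            assert a.clonal == b.clonal


class TestPartition:
    def test_identical_profiles_all_shared(self):
        s = make_profile([make_call(pos=i, component="stroma") for i in (1, 2)], "stroma")
        n = make_profile([make_call(pos=i) for i in (1, 2)])
        part = partition_mutations(s, n)
        assert len(part.shared) == 2
        assert not part.stroma_specific and not part.neoplasm_specific

    def test_disjoint_profiles_share_nothing(self):
        s = make_profile([make_call(pos=1, component="stroma")], "stroma")
        n = make_profile([make_call(pos=2)])
        part = partition_mutations(s, n)
        assert not part.shared
        assert len(part.stroma_specific) == len(part.neoplasm_specific) == 1

    def test_patient_mismatch_raises(self):
        s = make_profile([make_call(component="stroma", patient="P01")], "stroma", "P01")
        n = make_profile([make_call(patient="P02")], "neoplasm", "P02")
        with pytest.raises(MutationTableError, match="mismatch"):
            partition_mutations(s, n)

    def test_conservation(self, reference_cohort):
        """|shared| + |specific| equals each component's retained count."""
        for comps in reference_cohort.values():
            part = partition_mutations(comps["stroma"], comps["neoplasm"])
            assert len(part.shared) + len(part.stroma_specific) == len(comps["stroma"])
            assert len(part.shared) + len(part.neoplasm_specific) == len(
                comps["neoplasm"]
            )


class TestComputeCcf:
    def test_pure_diploid(self):
        assert compute_ccf(make_call(vaf=0.25), purity=1.0) == pytest.approx(0.5)

    def test_half_purity(self):
        assert compute_ccf(make_call(vaf=0.25), purity=0.5) == pytest.approx(1.0)

    def test_clipped_above_one(self):
        assert compute_ccf(make_call(vaf=0.6), purity=0.5) == 1.0

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            compute_ccf(make_call(), purity=0.0)


class TestClustering:
    def _profile(self, ccfs, depth=1000, seed=0):
        rng = np.random.default_rng(seed)
        calls = []
        for i, c in enumerate(ccfs, start=1):
            alt = int(rng.binomial(depth, c * 0.5))
            calls.append(make_call(pos=i, vaf=alt / depth, depth=depth, hq_alt_reads=alt))
        return make_profile(calls)

    def test_identical_ccfs_give_single_cluster(self):
        clusters = cluster_clones(self._profile([0.6] * 8), seed=1)
        assert len(clusters) == 1
        assert clusters[0].rank == 1

    def test_two_separated_groups_recovered(self):
        profile = self._profile([0.9] * 10 + [0.2] * 10, seed=2)
        clusters = cluster_clones(profile, seed=3)
        assert len(clusters) == 2
        top = clusters[0]
        assert {k[1] for k in top.member_keys} == set(range(1, 11))
        assert top.mean_ccf > clusters[1].mean_ccf

    def test_seeded_determinism(self):
        profile = self._profile([0.8] * 6 + [0.35] * 5 + [0.1] * 4, seed=4)
        a = cluster_clones(profile, seed=7)
        b = cluster_clones(profile, seed=7)
        assert [c.member_keys for c in a] == [c.member_keys for c in b]

    def test_single_mutation_single_cluster(self):
        clusters = cluster_clones(make_profile([make_call(vaf=0.3)]), seed=0)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_small_instances_match_exhaustive_oracle(self):
        """The fixed-K search attains the enumeration optimum on tiny inputs."""
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(2, 9))
            true = rng.uniform(0.05, 1.0, size=int(rng.integers(1, 4)))
            ccf = true[rng.integers(len(true), size=n)]
            depth = rng.integers(300, 1500, size=n).astype(float)
            alt = rng.binomial(depth.astype(int), ccf * 0.5).astype(float)
            factor = np.full(n, 0.5)
            _, em_ll = best_partition(alt, depth, factor, max_labels=3, seed=trial)
            _, opt_ll = brute_force_partition(alt, depth, factor, max_labels=3)
            assert em_ll >= opt_ll - 1e-6

    def test_partition_loglik_matches_manual_binomial(self):
        """Classification likelihood agrees with a direct computation."""
        from scipy.stats import binom

        alt = np.array([30.0, 60.0])
        depth = np.array([100.0, 100.0])
        factor = np.array([0.5, 0.5])
        # single cluster: MLE ccf = 90/100 = 0.9 -> p = 0.45
        expected = binom.logpmf(30, 100, 0.45) + binom.logpmf(60, 100, 0.45)
        assert map_partition_loglik([0, 0], alt, depth, factor) == pytest.approx(
            expected
        )
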