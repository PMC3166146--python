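import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cissat import (call_cis_eqtls, compute_maf, filter_snps_by_maf,
                    kruskal_wallis, permutation_fdr, scan_transcript)
from cissat.scan import _pick_lead
from cissat.io import MISSING


class TestMaf:
    @pytest.mark.parametrize("column, expected", [
        ([0, 0, 1, 2], 0.375),
        ([2, 2, 2, 2], 0.0),
        ([0, 0, 0, 0, 1], 0.1),
        ([0, 2, MISSING], 0.5),  # missing excluded from the denominator
    ])
    def test_values(self, column, expected):
        assert compute_maf(np.array(column)) == pytest.approx(expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_maf(np.array([MISSING, MISSING]))

    def test_filter_is_strict(self):
        # MAF exactly at the threshold is removed ("exceed" read strictly)
        column = np.array([1] + [0] * 9)  # 1 alt allele of 20 -> MAF 0.05
        mask = filter_snps_by_maf(column.reshape(-1, 1), threshold=0.05)
        assert not mask[0]
        assert filter_snps_by_maf(column.reshape(-1, 1), threshold=0.0)[0]

    def test_monomorphic_dropped_even_at_zero_threshold(self):
        mask = filter_snps_by_maf(np.zeros((6, 1), dtype=np.int8),
                                  threshold=0.0)
        assert not mask[0]

    def test_nested_subset_can_lose_a_snp(self):
        # the rare allele sits only in the back half: the SNP passes on the
        # full sample but fails when the first half is the subsample
        column = np.concatenate([np.zeros(50, dtype=np.int8),
                                 np.array([1] * 12 + [0] * 38, dtype=np.int8)])
        full = filter_snps_by_maf(column.reshape(-1, 1))
        subset = filter_snps_by_maf(column[:50].reshape(-1, 1))
        assert full[0] and not subset[0]


class TestKruskalWallis:
    def test_hand_computed_fixture(self):
        # ranks are 1..6; 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 4.5714
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])
        assert h == pytest.approx(4.5714, abs=1e-4)
        assert p == pytest.approx(0.1017, abs=1e-4)

    def test_constant_expression_not_testable(self):
        assert kruskal_wallis([5.0] * 6, [0, 0, 1, 1, 2, 2]) == (0.0, 1.0)

    def test_single_group_not_testable(self):
        assert kruskal_wallis([1.0, 2.0, 3.0], [1, 1, 1]) == (0.0, 1.0)

    def test_invariant_under_within_group_permutation(self):
        y = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        g = [0, 0, 1, 1, 2, 2]
        swapped = [1.0, 3.0, 1.5, 4.0, 2.6, 9.0]
        assert kruskal_wallis(y, g) == kruskal_wallis(swapped, g)

    def test_missing_genotypes_excluded_pairwise(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 99.0],
                              [0, 0, 1, 1, 2, 2, MISSING])
        assert (h, p) == pytest.approx(kruskal_wallis([1, 2, 3, 4, 5, 6],
                                                      [0, 0, 1, 1, 2, 2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=40)
        y = rng.normal(size=40)
        if seed % 2:  # inject ties
            y = np.round(y, 1)
        groups = [y[g == label] for label in np.unique(g)]
        expected = stats.kruskal(*groups)
        h, p = kruskal_wallis(y, g)
        assert h == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)


class TestScanTranscript:
    def _window(self, seed, n=50, m=20, span=2_000_000):
        rng = np.random.default_rng(seed)
        geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        pos = np.sort(rng.choice(span, size=m, replace=False)) + 1
        ids = np.array([f"snp{j:03d}" for j in range(m)], dtype=object)
        y = rng.normal(size=n) + 0.4 * geno[:, m // 2]
        return y, geno, ids, pos

    def test_single_snp_window_returned_regardless_of_p(self):
        y = np.zeros(6)  # constant -> p = 1, still the lead
        geno = np.array([[0], [0], [1], [1], [2], [2]], dtype=np.int8)
        lead = scan_transcript(y, geno, np.array(["only"], dtype=object),
                               np.array([500]), tss=400)
        assert lead == ("only", 0.0, 1.0, 100)

    def test_smaller_p_wins(self):
        rng = np.random.default_rng(0)
        n = 60
        g_weak = rng.integers(0, 3, size=n)
        g_strong = rng.integers(0, 3, size=n)
        y = 2.0 * g_strong + rng.normal(size=n, scale=0.5)
        geno = np.column_stack([g_weak, g_strong]).astype(np.int8)
        lead = scan_transcript(y, geno, np.array(["a", "b"], dtype=object),
                               np.array([100, 90_000]), tss=100)
        assert lead[0] == "b"

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_minimum(self, seed):
        # independent oracle: scipy KW per SNP + explicit tie-break rules
        y, geno, ids, pos = self._window(seed)
        tss = 1_000_000
        best = None
        for j in range(geno.shape[1]):
            groups = [y[geno[:, j] == g] for g in (0, 1, 2)
                      if (geno[:, j] == g).any()]
            if len(groups) < 2:
                h, p = 0.0, 1.0
            else:
                h, p = stats.kruskal(*groups)
            key = (p, abs(int(pos[j]) - tss), ids[j])
            if best is None or key < best[0]:
                best = (key, ids[j])
        lead = scan_transcript(y, geno, ids, pos, tss)
        assert lead[0] == best[1]

    def test_empty_window_returns_none(self):
        assert scan_transcript(np.zeros(5), np.zeros((5, 0), dtype=np.int8),
                               np.array([], dtype=object),
                               np.array([], dtype=np.int64), 100) is None

    def test_tie_break_distance_then_id(self):
        p = np.array([0.5, 0.5, 0.5])
        dist = np.array([100, 50, 50])
        id_rank = np.array([0, 2, 1])  # third id sorts before second
        assert _pick_lead(p, dist, id_rank) == 2


class TestPermutationFdr:
    def test_hand_enumerated_fixture(self):
        # FDR(0.001)=0/1, FDR(0.02)=0/2, FDR(0.5)=1/3 > 0.1 -> threshold 0.02
        observed = np.array([0.001, 0.02, 0.5])
        permuted = [np.array([0.3, 0.6, 0.9])]
        assert permutation_fdr(observed, permuted, 0.10) == pytest.approx(0.02)

    def test_target_one_keeps_everything(self):
        observed = np.array([0.2, 0.9, 0.5])
        permuted = [np.array([0.01, 0.02, 0.03])]
        assert permutation_fdr(observed, permuted, 1.0) == pytest.approx(0.9)

    def test_nothing_qualifies_gives_zero(self):
        observed = np.array([0.5, 0.9])
        permuted = [np.array([0.001, 0.002])]
        assert permutation_fdr(observed, permuted, 0.10) == 0.0

    def test_empty_observed_errors(self):
        with pytest.raises(ValueError, match="observed"):
            permutation_fdr(np.array([]), [np.array([0.5])])

    def test_monotone_in_p_despite_noisy_small_p_estimate(self):
        # raw FDR: 1/1=1.0, 1/2, 1/3, 1/4=0.25 -- the monotone (q-value)
        # estimate lets the well-supported larger threshold qualify even
        # though the smallest p has a noisy raw estimate above the target
        observed = np.array([0.01, 0.02, 0.03, 0.04])
        permuted = [np.array([0.005, 0.5, 0.6, 0.7])]
        assert permutation_fdr(observed, permuted, 0.30) == pytest.approx(0.04)

    def test_threshold_stable_in_permutation_count(self, strong_cohort):
        thresholds = [
            call_cis_eqtls(strong_cohort, "A", n_permutations=n_perm,
                           seed=3).p_threshold
            for n_perm in (10, 100)]
        # Monte-Carlo noise only: both runs keep the same detection set
        results = [
            call_cis_eqtls(strong_cohort, "A", n_permutations=n_perm,
                           seed=3).eqtl_transcripts
            for n_perm in (10, 100)]
        assert results[0] == results[1]
        assert thresholds[0] > 0 and thresholds[1] > 0


class TestCallCisEqtls:
    def test_noiseless_cohort_recovers_architecture(self, strong_cohort):
        # every true effect is detected, and each detected true transcript's
        # lead is the causal SNP (no LD); a 10% FDR scan may legitimately
        # admit a few null transcripts on top
        arch = strong_cohort.architecture
        for tissue in "ABC":
            expected = set(arch.loc[arch[f"b_{tissue}"] != 0, "transcript_id"])
            result = call_cis_eqtls(strong_cohort, tissue, seed=1)
            detected = result.eqtl_transcripts
            assert expected <= detected
            assert len(detected - expected) <= int(0.1 * len(detected)) + 1
            causal = dict(zip(arch["transcript_id"], arch["causal_snp"]))
            for eqtl in result.eqtls:
                if eqtl.transcript_id in expected:
                    assert eqtl.lead_snp_id == causal[eqtl.transcript_id]

    def test_null_cohort_detects_almost_nothing(self, null_cohort):
        result = call_cis_eqtls(null_cohort, "A", seed=2)
        assert result.q <= 2  # FDR-consistent false positives, near zero

    def test_deterministic_for_fixed_seed(self, small_cohort):
        first = call_cis_eqtls(small_cohort, "B", seed=7)
        second = call_cis_eqtls(small_cohort, "B", seed=7)
        assert first.p_threshold == second.p_threshold
        assert [dataclasses.astuple(e) for e in first.leads] == \
            [dataclasses.astuple(e) for e in second.leads]

    def test_one_lead_per_transcript(self, small_cohort):
        result = call_cis_eqtls(small_cohort, "A", seed=1)
        ids = [e.transcript_id for e in result.leads]
        assert len(ids) == len(set(ids))
        for eqtl in result.leads:
            assert abs(eqtl.distance_bp) <= 1_000_000
            assert 0.0 < eqtl.p_value <= 1.0

    def test_retained_set_shrinks_with_stricter_fdr(self, small_cohort):
        detected = [call_cis_eqtls(small_cohort, "A", fdr_target=target,
                                   seed=1).eqtl_transcripts
                    for target in (0.50, 0.10, 0.02)]
        assert detected[2] <= detected[1] <= detected[0]

    def test_subset_scan_uses_subset_maf(self, small_cohort):
        subset = list(small_cohort.sample_ids[:40])
        result = call_cis_eqtls(small_cohort, "A", subset, seed=1)
        assert result.n_samples == 40
        assert all(e.n_used == 40 for e in result.leads)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=30),
       st.lists(st.floats(0.001, 1.0), min_size=1, max_size=30))
def test_fdr_threshold_is_an_observed_p_or_zero(observed, permuted):
    threshold = permutation_fdr(np.array(observed), [np.array(permuted)], 0.1)
    assert threshold == 0.0 or threshold in observed
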