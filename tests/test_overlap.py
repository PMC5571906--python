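"""Cross-method matching, rank correlations, and adsorbent retrieval."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from vocompare.consensus import MethodProfile, build_method_profile, cluster_rt_ranges
from vocompare.datasets import cross_instrument_reference
from vocompare.overlap import (
    _longest_order_preserving_chain,
    adsorbent_retrieval,
    area_rank_correlation,
    elution_order_outliers,
    exhaustive_order_preserving_chain,
    match_across_methods,
    rt_rank_correlation,
    spearman_rank,
)
from vocompare.peak_io import Peak


def mkprofile(method, rt_spectra, sample_count=4):
    """Profile with one cluster per (rt, spectrum), each present in all samples."""
    peaks = []
    for rt, spectrum in rt_spectra:
        for s in range(sample_count):
            peaks.append(
                Peak(f"{method}_s{s}", "a0", method, False, rt, 100.0, tuple(spectrum))
            )
    clusters = cluster_rt_ranges(peaks, rt_tol=0.05)
    return MethodProfile(method_id=method, compounds=clusters, n_samples_total=sample_count)


SPECTRA = [
    ((40.0 + 3 * k, 999.0), (41.0 + 3 * k, 500.0), (200.0 + k, 100.0)) for k in range(10)
]


class TestMatching:
    def test_shared_panel_full_recovery(self, noiseless_dataset):
        """Zero jitter, certain detection: matching is perfect on shared compounds."""
        ds = noiseless_dataset
        compound_of = ds.compound_of_peak()
        prof_a, _ = build_method_profile(ds.peaks_for_method("mobile"))
        prof_b, _ = build_method_profile(ds.peaks_for_method("td_mix"))
        match = match_across_methods(prof_a, prof_b)

        def truth_of(cluster):
            ids = {compound_of[p] for p in cluster.member_peaks}
            assert len(ids) == 1
            return ids.pop()

        shared = {truth_of(c) for c in prof_a.compounds} & {
            truth_of(c) for c in prof_b.compounds
        }
        matched_truth = {(truth_of(p.cluster_a), truth_of(p.cluster_b)) for p in match.pairs}
        assert all(a == b for a, b in matched_truth)  # precision 1
        assert {a for a, _ in matched_truth} == shared  # recall 1

    def test_no_shared_ions_all_unique(self):
        prof_a = mkprofile("a", [(1.0, SPECTRA[0]), (2.0, SPECTRA[1])])
        prof_b = mkprofile("b", [(1.5, SPECTRA[5]), (2.5, SPECTRA[6])])
        match = match_across_methods(prof_a, prof_b)
        assert match.n_common == 0
        assert len(match.unique_a) == 2 and len(match.unique_b) == 2

    def test_subset_in_order_matches_exactly(self):
        # A has compounds 0..4; B shares ions only with 1 and 3, same order
        prof_a = mkprofile("a", [(float(i + 1), SPECTRA[i]) for i in range(5)])
        prof_b = mkprofile("b", [(2.0, SPECTRA[1]), (4.0, SPECTRA[3])])
        match = match_across_methods(prof_a, prof_b)
        got = {(p.cluster_a.rt_center, p.cluster_b.rt_center) for p in match.pairs}
        assert got == {(2.0, 2.0), (4.0, 4.0)}
        assert len(match.unique_a) == 3 and len(match.unique_b) == 0

    def test_order_preservation_invariant_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_a, n_b = rng.integers(2, 8, size=2)
            prof_a = mkprofile(
                "a",
                [(float(1 + i), SPECTRA[rng.integers(0, 6)]) for i in range(n_a)],
            )
            prof_b = mkprofile(
                "b",
                [(float(1 + i), SPECTRA[rng.integers(0, 6)]) for i in range(n_b)],
            )
            match = match_across_methods(prof_a, prof_b)
            rts_a = [p.cluster_a.rt_center for p in match.pairs]
            rts_b = [p.cluster_b.rt_center for p in match.pairs]
            order = np.argsort(rts_a)
            assert all(np.diff(np.array(rts_b)[order]) > 0) or len(match.pairs) < 2
            seen_a = [p.cluster_a.cluster_id for p in match.pairs]
            seen_b = [p.cluster_b.cluster_id for p in match.pairs]
            assert len(set(seen_a)) == len(seen_a) and len(set(seen_b)) == len(seen_b)

    def test_dp_equals_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            cands = [
                (int(rng.integers(0, 8)), int(rng.integers(0, 8)), float(rng.uniform(0, 5)))
                for _ in range(n)
            ]
            cands = list({(i, j): (i, j, s) for i, j, s in cands}.values())
            chain = _longest_order_preserving_chain(cands)
            score = {(i, j): s for i, j, s in cands}
            got = (len(chain), sum(score[p] for p in chain))
            want = exhaustive_order_preserving_chain(cands)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])

    def test_config_errors(self):
        prof = mkprofile("a", [(1.0, SPECTRA[0])])
        with pytest.raises(ValueError):
            match_across_methods(prof, prof, n_diagnostic=9, top_k=8)
        empty = MethodProfile(method_id="b", compounds=[], n_samples_total=0)
        with pytest.raises(ValueError):
            match_across_methods(prof, empty)


class TestSpearman:
    def test_monotone_and_antitone(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert rt_rank_correlation(list(zip(xs, [2.0, 3.5, 5.0, 9.0]))).rho == 1.0
        assert rt_rank_correlation(list(zip(xs, [9.0, 5.0, 3.5, 2.0]))).rho == -1.0

    def test_exact_permutation_p_small_n(self):
        # n = 4, rho = 1: only the identity and the reversal reach |rho| = 1,
        # so the exact two-sided p is 2/4! = 1/12
        res = spearman_rank([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == 1.0
        assert res.p_value == pytest.approx(2 / 24)

    def test_exact_p_matches_enumeration_n5(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman_rank(x, y)
        rhos = [
            spearmanr(x, perm).statistic for perm in itertools.permutations(y)
        ]
        want = np.mean([abs(r) >= abs(res.rho) - 1e-12 for r in rhos])
        assert res.p_value == pytest.approx(want)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        res = spearman_rank(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_constant_side(self):
        res = spearman_rank([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.status == "degenerate"
        assert math.isnan(res.rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rank([1.0, 2.0], [1.0, 2.0])


class TestElutionOutliers:
    def test_reference_table_has_one_discordant_compound(self):
        ref = cross_instrument_reference()
        pairs = list(zip(ref.rt_mobile_min, ref.rt_td_min))
        outliers = elution_order_outliers(pairs)
        assert len(outliers) == 1
        # the discordant pair is (Toluene, 2-methylheptane); the later-eluting
        # member is removed
        assert ref.name[outliers[0]] == "Heptane, 2-methyl-"

    def test_concordant_sequence_has_no_outliers(self):
        pairs = [(1.0, 2.0), (2.0, 3.0), (3.0, 5.0)]
        assert elution_order_outliers(pairs) == []


class TestRetrieval:
    def test_full_retrieval(self):
        names = [f"cmp{i}" for i in range(22)]
        res = adsorbent_retrieval(names, names)
        assert res.fraction == 1.0

    def test_partial_retrieval_fraction(self):
        names = [f"cmp{i}" for i in range(22)]
        res = adsorbent_retrieval(names, names[:3])
        assert res.n_retrieved == 3
        assert res.fraction == pytest.approx(3 / 22)

    def test_zero_retrieval_and_case_insensitivity(self):
        assert adsorbent_retrieval(["a", "b"], ["C"]).fraction == 0.0
        assert adsorbent_retrieval(["Toluene"], ["toluene"]).fraction == 1.0

    def test_empty_confirmed_set_rejected(self):
        with pytest.raises(ValueError):
            adsorbent_retrieval([], ["x"])


class TestAreaCorrelation:
    def test_identical_vectors(self, noiseless_dataset):
        ds = noiseless_dataset
        prof_a, _ = build_method_profile(ds.peaks_for_method("mobile"))
        prof_b, _ = build_method_profile(ds.peaks_for_method("td_mix"))
        match = match_across_methods(prof_a, prof_b)
        same = {p.cluster_a.cluster_id: float(i) for i, p in enumerate(match.pairs)}
        other = {p.cluster_b.cluster_id: float(i) for i, p in enumerate(match.pairs)}
        res = area_rank_correlation(match, same, other)
        assert res.rho == 1.0

    def test_independent_response_factors_give_null_rho(self):
        """Independent per-method areas: mean rho across seeds is ~0."""
        rng = np.random.default_rng(2)
        rhos = []
        for _ in range(100):
            n = 15
            rhos.append(spearman_rank(rng.uniform(size=n), rng.uniform(size=n)).rho)
        assert abs(float(np.mean(rhos))) < 0.1
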