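"""RT-range clustering, occurrence filter and blank correction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocompare.consensus import (
    blank_filter,
    build_method_profile,
    cluster_rt_ranges,
    occurrence_filter,
)
from vocompare.peak_io import Peak
from vocompare.synthetic_data import default_method_specs, generate_dataset, noiseless


def mkpeak(rt, sample="s0", area=100.0, method="m", blank=False):
    return Peak(
        sample_id=sample,
        animal_id="" if blank else "a0",
        method_id=method,
        is_blank=blank,
        rt_min=rt,
        area=area,
        spectrum=((43.0, 999.0), (57.0, 100.0)),
    )


def single_linkage_oracle(rts, tol):
    """Transitive closure of |rt_i - rt_j| <= tol, as sorted clusters."""
    order = sorted(range(len(rts)), key=lambda i: rts[i])
    groups = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if rts[cur] - rts[prev] > tol:
            groups.append([])
        groups[-1].append(cur)
    return [sorted(g) for g in groups]


class TestClustering:
    def test_gap_rule_splits(self):
        peaks = [mkpeak(rt, sample=f"s{i}") for i, rt in enumerate([5.00, 5.03, 5.90])]
        clusters = cluster_rt_ranges(peaks, rt_tol=0.1)
        assert [sorted(c.rt_values) for c in clusters] == [[5.00, 5.03], [5.90]]

    def test_empty_input(self):
        assert cluster_rt_ranges([], rt_tol=0.1) == []

    def test_mixed_methods_rejected(self):
        peaks = [mkpeak(1.0, method="m1"), mkpeak(2.0, method="m2")]
        with pytest.raises(ValueError, match="methods"):
            cluster_rt_ranges(peaks, rt_tol=0.1)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            cluster_rt_ranges([mkpeak(1.0)], rt_tol=0.0)

    def test_matches_single_linkage_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(100):
            n = int(rng.integers(1, 201))
            rts = np.round(rng.uniform(0, 20, size=n), 4)
            peaks = [mkpeak(float(rt), sample=f"s{i}") for i, rt in enumerate(rts)]
            got = cluster_rt_ranges(peaks, rt_tol=0.05)
            got_sets = sorted(
                [sorted(p.rt_min for p in c.member_peaks) for c in got]
            )
            oracle = single_linkage_oracle(list(rts), 0.05)
            want_sets = sorted([sorted(float(rts[i]) for i in g) for g in oracle])
            assert got_sets == want_sets

    @given(
        rts=st.lists(
            st.floats(min_value=0.1, max_value=30.0, allow_nan=False), min_size=1, max_size=60
        ),
        tol=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_and_gap_properties(self, rts, tol):
        peaks = [mkpeak(rt, sample=f"s{i}") for i, rt in enumerate(rts)]
        clusters = cluster_rt_ranges(peaks, rt_tol=tol)
        # partition: every input peak appears exactly once
        members = [p for c in clusters for p in c.member_peaks]
        assert sorted(p.rt_min for p in members) == sorted(rts)
        # within-cluster consecutive gaps <= tol, cluster invariants hold
        for c in clusters:
            srt = sorted(c.rt_values)
            assert all(b - a <= tol + 1e-12 for a, b in zip(srt, srt[1:]))
            assert c.rt_lo <= c.rt_center <= c.rt_hi
            assert c.n_samples_present == len({p.sample_id for p in c.member_peaks})
        # between adjacent clusters the gap exceeds tol
        ordered = sorted(clusters, key=lambda c: c.rt_lo)
        for a, b in zip(ordered, ordered[1:]):
            assert b.rt_lo - a.rt_hi > tol

    def test_same_sample_duplicates_split_off(self):
        # two co-eluting peaks of one sample: the one nearer the median stays
        peaks = [
            mkpeak(5.00, sample="s1"),
            mkpeak(5.02, sample="s2"),
            mkpeak(5.04, sample="s1"),  # duplicate of s1 within the linkage cluster
            mkpeak(5.30, sample="s3"),
        ]
        clusters = cluster_rt_ranges(peaks, rt_tol=0.1)
        for c in clusters:
            samples = [p.sample_id for p in c.member_peaks]
            assert len(samples) == len(set(samples))
        assert sum(len(c.member_peaks) for c in clusters) == 4


class TestOccurrenceFilter:
    def test_half_rule(self):
        present_6 = cluster_rt_ranges(
            [mkpeak(1.0, sample=f"s{i}") for i in range(6)], rt_tol=0.1
        )
        present_5 = cluster_rt_ranges(
            [mkpeak(1.0, sample=f"s{i}") for i in range(5)], rt_tol=0.1
        )
        assert occurrence_filter(present_6, 12) == present_6  # 6 of 12 retained
        assert occurrence_filter(present_5, 12) == []  # 5 of 12 removed

    def test_full_presence_boundary(self):
        full = cluster_rt_ranges([mkpeak(1.0, sample=f"s{i}") for i in range(12)], 0.1)
        partial = cluster_rt_ranges([mkpeak(1.0, sample=f"s{i}") for i in range(11)], 0.1)
        assert occurrence_filter(full, 12, min_frac=1.0) == full
        assert occurrence_filter(partial, 12, min_frac=1.0) == []

    def test_monotone_in_min_frac(self, dataset):
        peaks = dataset.peaks_for_method("td_mix", blanks=False)
        clusters = cluster_rt_ranges(peaks, rt_tol=0.05)
        n = len({p.sample_id for p in peaks})
        counts = [
            len(occurrence_filter(clusters, n, f)) for f in (0.1, 0.3, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            occurrence_filter([], 0)
        with pytest.raises(ValueError):
            occurrence_filter([], 5, min_frac=1.5)


class TestBlankFilter:
    def test_retained_when_animal_higher(self):
        animal = cluster_rt_ranges([mkpeak(5.0, area=1000.0)], 0.05)
        blank = cluster_rt_ranges([mkpeak(5.01, area=400.0, sample="b0", blank=True)], 0.05)
        kept, removed = blank_filter(animal, blank, rt_tol=0.05)
        assert kept == animal and removed == []

    def test_removed_when_blank_higher_with_provenance(self):
        animal = cluster_rt_ranges([mkpeak(5.0, area=300.0)], 0.05)
        blank = cluster_rt_ranges([mkpeak(5.01, area=400.0, sample="b0", blank=True)], 0.05)
        kept, removed = blank_filter(animal, blank, rt_tol=0.05)
        assert kept == []
        assert len(removed) == 1
        assert removed[0].blocking_blank is blank[0]

    def test_no_blank_counterpart_is_kept(self):
        animal = cluster_rt_ranges([mkpeak(5.0, area=10.0)], 0.05)
        blank = cluster_rt_ranges([mkpeak(9.0, area=1e9, sample="b0", blank=True)], 0.05)
        kept, _ = blank_filter(animal, blank, rt_tol=0.05)
        assert kept == animal

    def test_truth_labelled_contaminant_removal(self, noiseless_dataset):
        """Contaminants are emitted 2x in blanks: the filter removes exactly them."""
        ds = noiseless_dataset
        compound_of = ds.compound_of_peak()
        origin = {c.compound_id: c.origin_class for c in ds.truth.panel}
        for spec in ds.method_specs:
            profile, prov = build_method_profile(ds.peaks_for_method(spec.method_id))
            kept_origins = {
                origin[compound_of[p]] for c in profile.compounds for p in c.member_peaks
            }
            assert "exogenous" not in kept_origins
            for removal in prov["blank_removals"]:
                removed_ids = {compound_of[p] for p in removal.cluster.member_peaks}
                assert all(origin[cid] == "exogenous" for cid in removed_ids)


class TestRecovery:
    def test_noiseless_counts_equal_detectable_sets(self, noiseless_dataset):
        """With certain detection and zero jitter the consensus stage recovers
        exactly one occurrence-passing cluster per detectable compound."""
        ds = noiseless_dataset
        for spec in ds.method_specs:
            peaks = ds.peaks_for_method(spec.method_id, blanks=False)
            clusters = cluster_rt_ranges(peaks, rt_tol=0.05)
            n_samples = len({p.sample_id for p in peaks})
            occ = occurrence_filter(clusters, n_samples)
            assert len(occ) == len(ds.truth.detectable[spec.method_id])

    def test_jittered_recovery_high(self):
        """0.01-min RT jitter against a 0.05-min tolerance: near-perfect recovery."""
        recovered, detectable = 0, 0
        for seed in range(3):
            specs = [
                dataclasses.replace(noiseless(s), rt_jitter_sd=0.01)
                for s in default_method_specs()
            ]
            ds = generate_dataset(method_specs=specs, seed=100 + seed,
                                  spectrum_noise_sd=0.0, n_blank_noise_peaks=0.0)
            for spec in ds.method_specs:
                peaks = ds.peaks_for_method(spec.method_id, blanks=False)
                occ = occurrence_filter(
                    cluster_rt_ranges(peaks, rt_tol=0.05),
                    len({p.sample_id for p in peaks}),
                )
                detectable += len(ds.truth.detectable[spec.method_id])
                recovered += min(len(occ), len(ds.truth.detectable[spec.method_id]))
        assert recovered / detectable >= 0.95
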