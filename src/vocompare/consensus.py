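"""Per-method consensus compounds from replicate peak tables.

A repeatedly occurring peak within a narrow retention-time span across a
method's samples is treated as one consensus compound (an "RT range").  The
operational rule is gap-based single linkage on retention time: sort all peaks
of a method, cut wherever consecutive RTs differ by more than ``rt_tol``.
This is exactly the transitive closure of the relation |rt_i - rt_j| <= rt_tol
in one dimension, which keeps the procedure deterministic and order-free.

Two filters follow:

* the occurrence filter keeps clusters present in at least ``min_frac`` of
  the method's samples (default: at least half);
* the blank filter keeps clusters whose mean area in animal samples exceeds
  that of the nearest blank cluster within ``rt_tol`` (clusters with no blank
  counterpart are kept — absence from blanks is the strongest evidence of
  animal origin).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .peak_io import Peak

__all__ = [
    "FeatureCluster",
    "MethodProfile",
    "BlankRemoval",
    "cluster_rt_ranges",
    "occurrence_filter",
    "blank_filter",
    "build_method_profile",
]


@dataclass
class FeatureCluster:
    """One consensus compound ("RT range") within one method."""

    method_id: str
    member_peaks: list[Peak]
    cluster_id: str = ""

    @property
    def rt_values(self) -> list[float]:
        return [p.rt_min for p in self.member_peaks]

    @property
    def rt_center(self) -> float:
        return statistics.median(self.rt_values)

    @property
    def rt_lo(self) -> float:
        return min(self.rt_values)

    @property
    def rt_hi(self) -> float:
        return max(self.rt_values)

    @property
    def n_samples_present(self) -> int:
        return len({p.sample_id for p in self.member_peaks})

    @property
    def mean_area(self) -> float:
        return sum(p.area for p in self.member_peaks) / len(self.member_peaks)

    @property
    def consensus_spectrum(self) -> tuple[tuple[float, float], ...]:
        """Unit-binned mean spectrum over members, rescaled to a 999 base peak."""
        sums: dict[int, float] = {}
        for p in self.member_peaks:
            for mz, inten in p.spectrum:
                b = round(mz)
                sums[b] = sums.get(b, 0.0) + inten
        if not sums:
            return ()
        n = len(self.member_peaks)
        top = max(sums.values()) / n
        return tuple(
            (float(mz), round(999.0 * (s / n) / top, 1)) for mz, s in sorted(sums.items())
        )


@dataclass
class MethodProfile:
    """Blank-corrected consensus compound set of one method."""

    method_id: str
    compounds: list[FeatureCluster]
    n_samples_total: int

    def __post_init__(self) -> None:
        centers = [c.rt_center for c in self.compounds]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("profile compounds must be sorted by strictly increasing rt_center")


@dataclass(frozen=True)
class BlankRemoval:
    """Provenance record for a cluster removed by the blank filter."""

    cluster: FeatureCluster
    blocking_blank: FeatureCluster


def cluster_rt_ranges(
    peaks: Sequence[Peak], rt_tol: float, method_id: str | None = None
) -> list[FeatureCluster]:
    """Partition one method's peaks into RT-range clusters.

    Single-linkage at threshold ``rt_tol`` (gap rule on sorted RTs), followed
    by same-sample duplicate resolution: a cluster keeps at most one peak per
    sample — the one nearest the cluster's median RT, ties broken toward the
    earlier RT — and surplus peaks are reassigned to the nearest other cluster
    (ties toward the earlier cluster).
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be > 0")
    peaks = list(peaks)
    if not peaks:
        return []
    methods = {p.method_id for p in peaks}
    if len(methods) > 1:
        raise ValueError(f"peaks span multiple methods: {sorted(methods)}")
    if method_id is not None and methods != {method_id}:
        raise ValueError(f"expected method {method_id!r}, got {methods}")

    ordered = sorted(peaks, key=lambda p: (p.rt_min, p.sample_id))
    groups: list[list[Peak]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.rt_min - prev.rt_min > rt_tol:
            groups.append([])
        groups[-1].append(cur)

    groups = _resolve_sample_duplicates(groups)
    mid = methods.pop()
    clusters = [
        FeatureCluster(method_id=mid, member_peaks=g, cluster_id=f"{mid}_rt{i:03d}")
        for i, g in enumerate(groups)
    ]
    return clusters


def _resolve_sample_duplicates(groups: list[list[Peak]]) -> list[list[Peak]]:
    """Enforce at-most-one-peak-per-sample per cluster.

    Surplus peaks move to the nearest other cluster by |rt - median|, ties
    toward the earlier cluster; a receiving cluster that already holds a peak
    of that sample passes it on to the next-nearest.  If no cluster can take a
    surplus peak it becomes a singleton cluster of its own.
    """
    if all(len({p.sample_id for p in g}) == len(g) for g in groups):
        return groups

    medians = [statistics.median(p.rt_min for p in g) for g in groups]
    kept: list[list[Peak]] = []
    surplus: list[Peak] = []
    for g, med in zip(groups, medians):
        by_sample: dict[str, list[Peak]] = {}
        for p in g:
            by_sample.setdefault(p.sample_id, []).append(p)
        keep: list[Peak] = []
        for sample_peaks in by_sample.values():
            # nearest to the cluster median; ties toward the earlier RT
            sample_peaks.sort(key=lambda p: (abs(p.rt_min - med), p.rt_min))
            keep.append(sample_peaks[0])
            surplus.extend(sample_peaks[1:])
        keep.sort(key=lambda p: p.rt_min)
        kept.append(keep)

    extra_singletons: list[list[Peak]] = []
    for p in sorted(surplus, key=lambda q: (q.rt_min, q.sample_id)):
        order = sorted(
            range(len(kept)), key=lambda i: (abs(p.rt_min - medians[i]), medians[i])
        )
        for i in order:
            if all(q.sample_id != p.sample_id for q in kept[i]):
                kept[i].append(p)
                kept[i].sort(key=lambda q: q.rt_min)
                break
        else:
            extra_singletons.append([p])

    out = kept + extra_singletons
    out.sort(key=lambda g: statistics.median(p.rt_min for p in g))
    return [g for g in out if g]


def occurrence_filter(
    clusters: Sequence[FeatureCluster], n_samples_total: int, min_frac: float = 0.5
) -> list[FeatureCluster]:
    """Keep clusters present in at least ``ceil(min_frac * n_samples_total)`` samples."""
    if n_samples_total < 1:
        raise ValueError("n_samples_total must be >= 1")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    threshold = math.ceil(min_frac * n_samples_total - 1e-9)
    return [c for c in clusters if c.n_samples_present >= threshold]


def blank_filter(
    animal_clusters: Sequence[FeatureCluster],
    blank_clusters: Sequence[FeatureCluster],
    rt_tol: float,
) -> tuple[list[FeatureCluster], list[BlankRemoval]]:
    """Apply blank correction; returns (kept clusters, removal records).

    A cluster is kept iff its mean area exceeds that of the nearest blank
    cluster within ``rt_tol`` of its RT center, or no blank cluster matches.
    """
    methods = {c.method_id for c in animal_clusters} | {c.method_id for c in blank_clusters}
    if len(methods) > 1:
        raise ValueError(f"clusters span multiple methods: {sorted(methods)}")
    kept: list[FeatureCluster] = []
    removed: list[BlankRemoval] = []
    for c in animal_clusters:
        center = c.rt_center
        nearest = None
        best = None
        for b in blank_clusters:
            d = abs(b.rt_center - center)
            if d <= rt_tol and (best is None or d < best):
                nearest, best = b, d
        if nearest is None or c.mean_area > nearest.mean_area:
            kept.append(c)
        else:
            removed.append(BlankRemoval(cluster=c, blocking_blank=nearest))
    return kept, removed


def build_method_profile(
    peaks: Sequence[Peak],
    rt_tol: float = 0.05,
    min_frac: float = 0.5,
) -> tuple[MethodProfile, dict]:
    """Full consensus stage for one method: cluster, occurrence-filter, blank-correct.

    ``peaks`` must contain both animal and blank peaks of a single method.
    Returns the profile plus a provenance dict with the per-stage counts and
    the blank-removal records.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("no peaks supplied")
    animal = [p for p in peaks if not p.is_blank]
    blank = [p for p in peaks if p.is_blank]
    if not animal:
        raise ValueError("no animal-sample peaks supplied")
    method_id = animal[0].method_id
    n_samples = len({p.sample_id for p in animal})

    clusters = cluster_rt_ranges(animal, rt_tol)
    occ = occurrence_filter(clusters, n_samples, min_frac)
    blank_clusters = cluster_rt_ranges(blank, rt_tol) if blank else []
    kept, removed = blank_filter(occ, blank_clusters, rt_tol)
    kept = sorted(kept, key=lambda c: c.rt_center)

    profile = MethodProfile(method_id=method_id, compounds=kept, n_samples_total=n_samples)
    provenance = {
        "method_id": method_id,
        "n_samples": n_samples,
        "n_clusters_raw": len(clusters),
        "n_after_occurrence": len(occ),
        "n_after_blank": len(kept),
        "blank_removals": removed,
    }
    return profile, provenance
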