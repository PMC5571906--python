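"""Matching compounds across two methods/instruments.

Two GC-MS instruments with different columns produce different retention
times, but elution order on comparable (non-polar) phases is preserved up to
local inversions, and fragment spectra travel with the compound.  Cross-
instrument matching therefore uses two signals:

* **diagnostic ions** — a candidate pair must share at least ``n_diagnostic``
  of each side's top-``k`` most intense consensus-spectrum m/z values
  (within ``mz_tol``);
* **elution order** — among candidates, the final pairing is the maximum-
  cardinality order-preserving matching: the longest chain of candidate pairs
  strictly increasing in retention time on both sides, found by dynamic
  programming, with cardinality ties broken toward higher summed
  diagnostic-ion intensity agreement.

Matches are validated by Spearman rank correlations of the paired retention
times (should be ~1 if assignments are correct) and of the paired relative
mean areas (instrument response factors differ, so this is typically weak).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .consensus import FeatureCluster, MethodProfile

__all__ = [
    "CrossMatch",
    "MatchedPair",
    "RankCorrelationResult",
    "RetrievalResult",
    "match_across_methods",
    "rt_rank_correlation",
    "area_rank_correlation",
    "spearman_rank",
    "adsorbent_retrieval",
    "elution_order_outliers",
]


@dataclass(frozen=True)
class MatchedPair:
    """One compound paired across two methods."""

    cluster_a: FeatureCluster
    cluster_b: FeatureCluster
    diagnostic_ions: tuple[float, ...]  # shared m/z values, most intense first
    ion_agreement: float  # summed min shared-ion intensity (tie-break score)


@dataclass
class CrossMatch:
    """Result of matching two method profiles."""

    method_a: str
    method_b: str
    pairs: list[MatchedPair]
    unique_a: list[FeatureCluster]
    unique_b: list[FeatureCluster]

    @property
    def n_common(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RankCorrelationResult:
    rho: float
    p_value: float
    n: int
    status: str = "ok"  # ok | degenerate


@dataclass(frozen=True)
class RetrievalResult:
    n_searched: int
    n_retrieved: int
    retrieved_names: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return self.n_retrieved / self.n_searched


def _top_ions(cluster: FeatureCluster, k: int) -> list[tuple[float, float]]:
    spec = sorted(cluster.consensus_spectrum, key=lambda s: (-s[1], s[0]))
    return spec[:k]


def _shared_ions(
    ions_a: Sequence[tuple[float, float]],
    ions_b: Sequence[tuple[float, float]],
    mz_tol: float,
) -> list[tuple[float, float]]:
    """Greedy nearest-m/z pairing of two top-ion lists.

    Returns ``(mz_a, min(intensity_a, intensity_b))`` per shared ion, sorted by
    the shared (min) intensity descending.
    """
    candidates = []
    for i, (mza, ia) in enumerate(ions_a):
        for j, (mzb, ib) in enumerate(ions_b):
            d = abs(mza - mzb)
            if d <= mz_tol:
                candidates.append((d, mza, i, j, min(ia, ib)))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = []
    for _, mza, i, j, agree in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((mza, agree))
    shared.sort(key=lambda s: (-s[1], s[0]))
    return shared


def match_across_methods(
    profile_a: MethodProfile,
    profile_b: MethodProfile,
    mz_tol: float = 0.3,
    n_diagnostic: int = 2,
    top_k: int = 8,
) -> CrossMatch:
    """Pair compounds of two profiles by diagnostic ions + elution order.

    The returned pairing is the longest chain of ion-compatible cluster pairs
    that is strictly increasing in RT on both sides (each cluster used at most
    once); among equally long chains the one with the largest total
    diagnostic-ion intensity agreement is chosen, deterministically.
    """
    if not profile_a.compounds or not profile_b.compounds:
        raise ValueError("both profiles must be non-empty")
    if n_diagnostic < 1:
        raise ValueError("n_diagnostic must be >= 1")
    if n_diagnostic > top_k:
        raise ValueError(f"n_diagnostic ({n_diagnostic}) exceeds top_k ({top_k})")

    a = profile_a.compounds
    b = profile_b.compounds
    ions_a = [_top_ions(c, top_k) for c in a]
    ions_b = [_top_ions(c, top_k) for c in b]

    candidates: list[tuple[int, int, list[tuple[float, float]]]] = []
    for i in range(len(a)):
        for j in range(len(b)):
            shared = _shared_ions(ions_a[i], ions_b[j], mz_tol)
            if len(shared) >= n_diagnostic:
                candidates.append((i, j, shared))

    chain = _longest_order_preserving_chain(
        [(i, j, sum(s for _, s in shared)) for i, j, shared in candidates]
    )
    chosen = {(i, j): shared for i, j, shared in candidates}
    pairs = [
        MatchedPair(
            cluster_a=a[i],
            cluster_b=b[j],
            diagnostic_ions=tuple(mz for mz, _ in chosen[(i, j)][:n_diagnostic]),
            ion_agreement=sum(s for _, s in chosen[(i, j)]),
        )
        for i, j in chain
    ]
    matched_a = {i for i, _ in chain}
    matched_b = {j for _, j in chain}
    return CrossMatch(
        method_a=profile_a.method_id,
        method_b=profile_b.method_id,
        pairs=pairs,
        unique_a=[c for k, c in enumerate(a) if k not in matched_a],
        unique_b=[c for k, c in enumerate(b) if k not in matched_b],
    )


def _longest_order_preserving_chain(
    candidates: Sequence[tuple[int, int, float]],
) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both indices; DP in O(n^2).

    ``candidates`` are (index_in_A, index_in_B, tie_break_score); both profiles
    are RT-sorted, so index order is elution order.  Maximises (length, summed
    score) lexicographically; remaining ties resolve toward lexicographically
    smallest index sequence via the processing order.
    """
    if not candidates:
        return []
    cand = sorted(candidates, key=lambda c: (c[0], c[1]))
    n = len(cand)
    best_len = [1] * n
    best_score = [c[2] for c in cand]
    parent = [-1] * n
    for x in range(n):
        ix, jx, sx = cand[x]
        for y in range(x):
            iy, jy, _ = cand[y]
            if iy < ix and jy < jx:
                cand_len = best_len[y] + 1
                cand_score = best_score[y] + sx
                if cand_len > best_len[x] or (
                    cand_len == best_len[x] and cand_score > best_score[x]
                ):
                    best_len[x] = cand_len
                    best_score[x] = cand_score
                    parent[x] = y
    end = max(range(n), key=lambda x: (best_len[x], best_score[x], -x))
    chain = []
    while end != -1:
        chain.append((cand[end][0], cand[end][1]))
        end = parent[end]
    return chain[::-1]


def exhaustive_order_preserving_chain(
    candidates: Sequence[tuple[int, int, float]],
) -> tuple[int, float]:
    """Brute-force oracle: (max chain length, best score at that length).

    Enumerates every subset of candidate pairs; only usable for small inputs.
    """
    best = (0, 0.0)
    cand = list(candidates)
    for r in range(len(cand), 0, -1):
        if r < best[0]:
            break
        for subset in itertools.combinations(cand, r):
            ordered = sorted(subset)
            if all(
                p[0] < q[0] and p[1] < q[1] for p, q in zip(ordered, ordered[1:])
            ):
                score = sum(s for _, _, s in ordered)
                if (r, score) > best:
                    best = (r, score)
    return best


def spearman_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> RankCorrelationResult:
    """Spearman rho with average ranks for ties.

    Two-sided p-value from the exact permutation distribution of rho for
    n <= ``exact_max_n``, from the t approximation otherwise.  Zero rank
    variance on either side gives a degenerate result (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return RankCorrelationResult(rho=math.nan, p_value=math.nan, n=n, status="degenerate")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return RankCorrelationResult(rho=rho, p_value=p, n=n)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """P(|rho_perm| >= |rho_obs|) over all n! permutations of one rank vector."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    cx = rx - rx.mean()
    cp = perms - perms.mean(axis=1, keepdims=True)
    num = cp @ cx
    den = math.sqrt(float(cx @ cx)) * np.sqrt((cp * cp).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def rt_rank_correlation(match: CrossMatch | Sequence[tuple[float, float]]) -> RankCorrelationResult:
    """Spearman correlation of paired retention times across the two methods."""
    if isinstance(match, CrossMatch):
        pairs = [(p.cluster_a.rt_center, p.cluster_b.rt_center) for p in match.pairs]
    else:
        pairs = list(match)
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs")
    xs, ys = zip(*pairs)
    return spearman_rank(xs, ys)


def area_rank_correlation(
    match: CrossMatch,
    rel_mean_area_a: Mapping[str, float],
    rel_mean_area_b: Mapping[str, float],
) -> RankCorrelationResult:
    """Spearman correlation of per-pair relative mean areas across the methods.

    ``rel_mean_area_*`` map cluster_id to the mean relative area of that
    cluster over its side's chromatograms (see :func:`vocompare.stats.relative_areas`).
    """
    xs, ys = [], []
    for p in match.pairs:
        ka, kb = p.cluster_a.cluster_id, p.cluster_b.cluster_id
        if ka in rel_mean_area_a and kb in rel_mean_area_b:
            xs.append(rel_mean_area_a[ka])
            ys.append(rel_mean_area_b[kb])
    if len(xs) < 3:
        raise ValueError("need at least 3 matched pairs with relative areas on both sides")
    return spearman_rank(xs, ys)


def elution_order_outliers(pairs: Sequence[tuple[float, float]]) -> list[int]:
    """Indices of pairs breaking cross-instrument elution-order concordance.

    The concordant core is the longest chain increasing in both RT sequences;
    everything outside it is an outlier.  Among equally long chains the one
    whose excluded members elute later is preferred (ties break toward
    removing the later-eluting member of a discordant pair).
    """
    order = sorted(range(len(pairs)), key=lambda k: (pairs[k][0], pairs[k][1]))
    cand = [(r, pairs[k][1], k) for r, k in enumerate(order)]
    # reuse the DP with a score that prefers keeping earlier-eluting pairs
    scored = [(r, y, -r * 1e-9) for r, y, _ in cand]
    # strictly increasing in rank on side A and RT on side B
    chain = _longest_increasing_chain_values(scored)
    kept = {cand[i][2] for i in chain}
    return sorted(k for k in range(len(pairs)) if k not in kept)


def _longest_increasing_chain_values(
    items: Sequence[tuple[int, float, float]],
) -> list[int]:
    """Longest chain over items (rank, value, score): rank and value strictly increase."""
    n = len(items)
    if n == 0:
        return []
    best_len = [1] * n
    best_score = [it[2] for it in items]
    parent = [-1] * n
    for x in range(n):
        for y in range(x):
            if items[y][0] < items[x][0] and items[y][1] < items[x][1]:
                ln = best_len[y] + 1
                sc = best_score[y] + items[x][2]
                if ln > best_len[x] or (ln == best_len[x] and sc > best_score[x]):
                    best_len[x] = ln
                    best_score[x] = sc
                    parent[x] = y
    end = max(range(n), key=lambda x: (best_len[x], best_score[x], -x))
    out = []
    while end != -1:
        out.append(end)
        end = parent[end]
    return out[::-1]


def adsorbent_retrieval(
    confirmed_names: Sequence[str], target_names: Sequence[str]
) -> RetrievalResult:
    """How many confirmed compounds of one adsorbent reappear in another's profile.

    Retrieval is case-insensitive name presence among the target profile's
    annotations.
    """
    if not confirmed_names:
        raise ValueError("confirmed_names must be non-empty")
    target = {t.strip().casefold() for t in target_names}
    retrieved = tuple(n for n in confirmed_names if n.strip().casefold() in target)
    return RetrievalResult(
        n_searched=len(confirmed_names),
        n_retrieved=len(retrieved),
        retrieved_names=retrieved,
    )
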