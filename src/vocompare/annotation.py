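"""Tentative compound identification and classification.

Identities are assigned by library search with a NIST-style match factor on
the 0-999 scale: a weighted cosine between stick spectra with weights
``intensity**0.5 * mz**1.0`` (the classic library-search weighting, which
up-weights the heavier, more structure-diagnostic fragments), sticks paired
greedily by nearest m/z within a tolerance.  A cluster is named only when one
library entry is the top hit with a score above ``min_score`` in a majority of
the cluster's member samples — a single lucky match in one replicate is not
an identification.

Classification then attaches a volatility label (boiling point below 250 °C
at 760 mmHg counts as volatile) and an origin class (exogenous contaminant,
potentially endogenous, potentially metabolized by host or skin bacteria, or
unclassified) from a curated metadata table.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .consensus import FeatureCluster
from .peak_io import LibraryEntry, lookup_metadata

__all__ = [
    "AnnotatedCompound",
    "spectral_match_score",
    "annotate_cluster",
    "annotate_profile",
    "classify_volatility",
    "classify_origin",
    "VOLATILITY_THRESHOLD_C",
]

#: Boiling-point threshold (°C, 760 mmHg) separating volatile from
#: semi-/non-volatile compounds.  Volatile means strictly below the threshold.
VOLATILITY_THRESHOLD_C = 250.0

DEFAULT_MZ_TOL = 0.3  # unit-resolution quadrupole data


@dataclass(frozen=True)
class AnnotatedCompound:
    """A consensus compound with identity, volatility and origin labels."""

    cluster: FeatureCluster
    name: str | None
    match_score: int | None
    boiling_point_c: float | None
    volatility: str  # volatile | semi_or_nonvolatile | unknown
    origin_class: str

    @property
    def is_named(self) -> bool:
        return self.name is not None


def _weights(spectrum: Sequence[tuple[float, float]], intensity_power: float, mz_power: float):
    return [(mz, (inten**intensity_power) * (mz**mz_power)) for mz, inten in spectrum]


def spectral_match_score(
    query_spectrum: Sequence[tuple[float, float]],
    reference_spectrum: Sequence[tuple[float, float]],
    mz_tol: float = DEFAULT_MZ_TOL,
    intensity_power: float = 0.5,
    mz_power: float = 1.0,
) -> int:
    """Match factor between two stick spectra, integer in [0, 999].

    ``round(999 * cos)`` where cos is the weighted cosine over greedily paired
    sticks: candidate pairs within ``mz_tol`` are taken closest-|Δm/z| first,
    each stick used at most once; unpaired sticks contribute nothing to the
    numerator but their weights stay in the norms, so only identical spectra
    reach 999 and spectra sharing no m/z score 0.
    """
    if not query_spectrum or not reference_spectrum:
        raise ValueError("spectra must be non-empty")
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    wq = _weights(query_spectrum, intensity_power, mz_power)
    wr = _weights(reference_spectrum, intensity_power, mz_power)

    candidates = []
    for i, (mzq, _) in enumerate(wq):
        for j, (mzr, _) in enumerate(wr):
            d = abs(mzq - mzr)
            if d <= mz_tol:
                candidates.append((d, mzq, mzr, i, j))
    candidates.sort()

    used_q: set[int] = set()
    used_r: set[int] = set()
    num = 0.0
    for _, _, _, i, j in candidates:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        num += wq[i][1] * wr[j][1]

    nq = math.sqrt(sum(w * w for _, w in wq))
    nr = math.sqrt(sum(w * w for _, w in wr))
    score = int(round(999.0 * num / (nq * nr)))
    return max(0, min(999, score))


def annotate_cluster(
    cluster: FeatureCluster,
    library: Sequence[LibraryEntry],
    metadata: Mapping[str, tuple[float | None, str]] | None = None,
    min_score: int = 700,
    majority_frac: float = 0.5,
    mz_tol: float = DEFAULT_MZ_TOL,
    volatility_threshold_c: float = VOLATILITY_THRESHOLD_C,
) -> AnnotatedCompound:
    """Name a cluster by majority vote over member-sample library searches.

    Each member peak's spectrum is searched against the library; the cluster
    is named after a library entry only if that entry is the top hit with
    score > ``min_score`` in more than ``majority_frac`` of the member
    samples.  Count ties break toward the higher mean winning score.  The
    reported match score is the rounded mean of the winning scores.
    """
    if not library:
        raise ValueError("library must be non-empty")
    votes: dict[str, list[int]] = defaultdict(list)
    for peak in cluster.member_peaks:
        best_name, best_score = None, -1
        for entry in library:
            s = spectral_match_score(peak.spectrum, entry.spectrum, mz_tol)
            if s > best_score:
                best_name, best_score = entry.name, s
        if best_name is not None and best_score > min_score:
            votes[best_name].append(best_score)

    name: str | None = None
    match_score: int | None = None
    n_members = len({p.sample_id for p in cluster.member_peaks})
    if votes:
        winner = max(votes.items(), key=lambda kv: (len(kv[1]), sum(kv[1]) / len(kv[1])))
        if len(winner[1]) > majority_frac * n_members:
            name = winner[0]
            match_score = int(round(sum(winner[1]) / len(winner[1])))

    bp: float | None = None
    origin = "unclassified"
    if name is not None:
        entry = next(e for e in library if e.name == name)
        bp = entry.boiling_point_c
        if metadata is not None:
            meta = lookup_metadata(metadata, name)
            if meta is not None:
                if meta[0] is not None:
                    bp = meta[0]
                origin = meta[1]

    volatility = (
        "unknown" if bp is None else classify_volatility(bp, volatility_threshold_c)
    )
    return AnnotatedCompound(
        cluster=cluster,
        name=name,
        match_score=match_score,
        boiling_point_c=bp,
        volatility=volatility,
        origin_class=origin,
    )


def annotate_profile(
    profile,
    library: Sequence[LibraryEntry],
    metadata: Mapping[str, tuple[float | None, str]] | None = None,
    **kwargs,
) -> list[AnnotatedCompound]:
    """Annotate every compound of a :class:`~vocompare.consensus.MethodProfile`."""
    return [annotate_cluster(c, library, metadata, **kwargs) for c in profile.compounds]


def classify_volatility(
    boiling_point_c: float, threshold_c: float = VOLATILITY_THRESHOLD_C
) -> str:
    """``volatile`` iff the boiling point is strictly below the threshold.

    The boundary value itself is semi-/non-volatile: volatility is defined by
    the strict inequality bp < threshold.
    """
    if not math.isfinite(boiling_point_c):
        raise ValueError(f"non-finite boiling point {boiling_point_c!r}")
    return "volatile" if boiling_point_c < threshold_c else "semi_or_nonvolatile"


def classify_origin(
    name: str, metadata: Mapping[str, tuple[float | None, str]]
) -> str:
    """Origin class from the metadata table; ``unclassified`` when absent."""
    meta = lookup_metadata(metadata, name)
    return meta[1] if meta is not None else "unclassified"
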