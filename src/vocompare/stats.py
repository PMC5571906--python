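"""Relative peak areas, the common-vs-unique mixed model, and profile summaries.

The central statistical question of a two-instrument comparison: are the
compounds that both instruments detect simply the most abundant ones?  The
test regresses log relative peak area (a peak's area divided by the sum of
all peak areas in its chromatogram) on the sample-set label (``common`` =
detected by both instruments, ``unique`` = detected only by the more
sensitive one), with random intercepts and random set-label slopes for both
the chromatogram (sample) and the animal, intercepts and slopes uncorrelated.
Both the full and the null model (fixed effect dropped) are fitted by maximum
likelihood, and the fixed effect is tested by a likelihood-ratio test against
chi-square with one degree of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .annotation import AnnotatedCompound
from .peak_io import Peak

__all__ = [
    "RelativeAreaRecord",
    "MixedModelResult",
    "ProfileSummary",
    "relative_areas",
    "relative_mean_areas_by_cluster",
    "fit_common_vs_unique_model",
    "profile_summary",
]


@dataclass(frozen=True)
class RelativeAreaRecord:
    """One peak's share of its chromatogram's total area, with labels."""

    sample_id: str
    animal_id: str
    cluster_id: str | None
    relative_area: float
    set_label: str | None = None  # common | unique | None (unlabelled)


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed-effect LRT result for the common-vs-unique comparison.

    ``effect`` is the estimated common-minus-unique difference in mean log
    relative area.
    """

    effect: float
    chi2: float
    df: int
    p_value: float
    n_obs: int
    converged: bool


@dataclass(frozen=True)
class ProfileSummary:
    """Counts of a method's annotated compounds by volatility and origin."""

    method_id: str
    n_total: int
    n_volatile: int
    pct_volatile: float  # nan for an empty profile
    origin_counts: tuple[tuple[str, int], ...]

    @property
    def pct_volatile_rounded(self) -> int | None:
        if math.isnan(self.pct_volatile):
            return None
        return int(round(self.pct_volatile))


def relative_areas(
    peaks: Sequence[Peak], cluster_of_peak: Mapping[Peak, str] | None = None
) -> list[RelativeAreaRecord]:
    """Relative areas of one chromatogram's peaks (they sum to exactly 1).

    All peaks must belong to a single sample.  ``cluster_of_peak`` optionally
    maps each peak to its consensus cluster id for downstream labelling.
    """
    if not peaks:
        raise ValueError("chromatogram has no peaks")
    samples = {p.sample_id for p in peaks}
    if len(samples) > 1:
        raise ValueError(f"peaks span multiple samples: {sorted(samples)}")
    total = sum(p.area for p in peaks)
    return [
        RelativeAreaRecord(
            sample_id=p.sample_id,
            animal_id=p.animal_id,
            cluster_id=None if cluster_of_peak is None else cluster_of_peak.get(p),
            relative_area=p.area / total,
        )
        for p in peaks
    ]


def relative_mean_areas_by_cluster(
    records: Sequence[RelativeAreaRecord],
) -> dict[str, float]:
    """Mean relative area per cluster over all chromatograms it appears in."""
    sums: dict[str, list[float]] = {}
    for r in records:
        if r.cluster_id is not None:
            sums.setdefault(r.cluster_id, []).append(r.relative_area)
    return {k: sum(v) / len(v) for k, v in sums.items()}


def fit_common_vs_unique_model(
    records: Sequence[RelativeAreaRecord],
) -> MixedModelResult:
    """Fit the log relative-area mixed model and LRT the set-label fixed effect.

    Full model: ``log(relative_area) ~ is_common`` with uncorrelated random
    intercepts and is_common slopes for sample and for animal (variance
    components).  Null model drops the fixed effect but keeps the random
    structure.  Both fitted by ML (REML likelihoods are not comparable across
    fixed-effect structures); chi2 = 2 (llf_full - llf_null), df = 1.

    Non-convergence of either fit is reported via ``converged=False``; the
    numbers are still returned, never replaced by a simpler model.
    """
    import statsmodels.formula.api as smf

    labels = {r.set_label for r in records}
    if not {"common", "unique"} <= labels:
        raise ValueError(f"records must contain both set labels, got {sorted(map(str, labels))}")
    df = pd.DataFrame(
        {
            "log_rel": [math.log(r.relative_area) for r in records],
            "is_common": [1.0 if r.set_label == "common" else 0.0 for r in records],
            "sample_id": [r.sample_id for r in records],
            "animal_id": [r.animal_id for r in records],
            "one": 1.0,
        }
    )
    if df["animal_id"].nunique() < 2 or df["sample_id"].nunique() < 2:
        raise ValueError("need at least 2 animals and 2 samples")

    vc = {
        "sample": "0 + C(sample_id)",
        "sample_slope": "0 + C(sample_id):is_common",
        "animal": "0 + C(animal_id)",
        "animal_slope": "0 + C(animal_id):is_common",
    }

    def _fit(formula: str):
        model = smf.mixedlm(formula, df, groups="one", vc_formula=vc, re_formula="0")
        last_exc: Exception | None = None
        # Powell is derivative-free and robust at variance boundaries, where
        # gradient-based optimizers routinely flag false failures; but it can
        # occasionally step into a singular covariance, so fall back.
        for method in ("powell", "lbfgs", "bfgs"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=False, method=method, disp=False)
                    res.llf  # force lazy evaluation inside the warning filter
                    return res
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
        raise RuntimeError(f"mixed-model fit failed with every optimizer: {last_exc}")

    full = _fit("log_rel ~ is_common")
    null = _fit("log_rel ~ 1")
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    return MixedModelResult(
        effect=float(full.fe_params["is_common"]),
        chi2=float(chi2),
        df=1,
        p_value=float(chi2_dist.sf(chi2, 1)),
        n_obs=len(df),
        converged=bool(full.converged and null.converged),
    )


def profile_summary(
    annotated: Sequence[AnnotatedCompound], method_id: str
) -> ProfileSummary:
    """Totals and volatile/origin breakdown of an annotated method profile.

    Percentages are reported rounded to whole percent but kept at full
    precision internally; an empty profile yields an undefined (NaN)
    percentage rather than a fake zero.
    """
    n_total = len(annotated)
    n_volatile = sum(1 for a in annotated if a.volatility == "volatile")
    counts: dict[str, int] = {}
    for a in annotated:
        counts[a.origin_class] = counts.get(a.origin_class, 0) + 1
    pct = math.nan if n_total == 0 else 100.0 * n_volatile / n_total
    return ProfileSummary(
        method_id=method_id,
        n_total=n_total,
        n_volatile=n_volatile,
        pct_volatile=pct,
        origin_counts=tuple(sorted(counts.items())),
    )
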