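"""End-to-end pipeline: consensus → annotation → overlap → stats.

A single declarative configuration drives the whole analysis.  Each run
writes its outputs into one run directory together with a provenance manifest
(config hash, seed, package version, per-stage compound counts), so every
filter's effect on the compound inventory is auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import annotate_profile
from .consensus import build_method_profile
from .overlap import (
    area_rank_correlation,
    match_across_methods,
    rt_rank_correlation,
)
from .peak_io import (
    read_compound_metadata,
    read_msp_library,
    read_peak_table,
)
from .stats import (
    fit_common_vs_unique_model,
    profile_summary,
    relative_areas,
    relative_mean_areas_by_cluster,
    RelativeAreaRecord,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("vocompare")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the offender."""


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, with the documented defaults.

    ``overlap_pair`` names the (coarser, finer) instrument pair for the
    overlap and mixed-model stages; records from the second (finer) method
    are labelled common/unique by the match against the first.
    """

    peaks: str | None = None
    library: str | None = None
    metadata: str | None = None
    rt_tol: float = 0.05
    min_frac: float = 0.5
    min_score: int = 700
    mz_tol: float = 0.3
    n_diagnostic: int = 2
    top_k_ions: int = 8
    volatility_threshold_c: float = 250.0
    overlap_pair: tuple[str, str] = ("mobile", "td_mix")
    seed: int = 1

    def validate(self) -> None:
        if self.rt_tol <= 0 or self.mz_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.min_frac <= 1:
            raise ValueError(f"min_frac must be in (0, 1], got {self.min_frac}")
        if not 0 <= self.min_score <= 999:
            raise ValueError(f"min_score must be in [0, 999], got {self.min_score}")
        if self.volatility_threshold_c <= 0:
            raise ValueError("volatility_threshold_c must be > 0")
        if self.n_diagnostic < 1 or self.n_diagnostic > self.top_k_ions:
            raise ValueError("need 1 <= n_diagnostic <= top_k_ions")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        if "overlap_pair" in raw:
            raw["overlap_pair"] = tuple(raw["overlap_pair"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run consensus → annotation → overlap → stats; write a run directory.

    Returns a result dict with the profiles, overlap, model result and
    summaries; the same information is written as tidy CSV/JSON files under
    ``outdir``.  Identical config and inputs give identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _attach_run_log(outdir)

    if config.peaks is None:
        raise PipelineError("input: no peak table configured")
    try:
        peaks = read_peak_table(config.peaks)
        library = read_msp_library(config.library) if config.library else []
        metadata = read_compound_metadata(config.metadata) if config.metadata else {}
    except Exception as exc:
        raise PipelineError(f"input: {exc}") from exc

    methods = sorted({p.method_id for p in peaks})
    logger.info("loaded %d peaks across methods %s", len(peaks), methods)

    profiles = {}
    provenances = {}
    for m in methods:
        try:
            profile, prov = build_method_profile(
                [p for p in peaks if p.method_id == m],
                rt_tol=config.rt_tol,
                min_frac=config.min_frac,
            )
        except Exception as exc:
            raise PipelineError(f"consensus[{m}]: {exc}") from exc
        profiles[m] = profile
        provenances[m] = prov
        logger.info(
            "%s: %d raw clusters -> %d after occurrence -> %d after blank filter",
            m, prov["n_clusters_raw"], prov["n_after_occurrence"], prov["n_after_blank"],
        )

    annotated = {}
    summaries = {}
    for m, profile in profiles.items():
        try:
            ann = annotate_profile(
                profile,
                library,
                metadata,
                min_score=config.min_score,
                mz_tol=config.mz_tol,
                volatility_threshold_c=config.volatility_threshold_c,
            ) if library else []
        except Exception as exc:
            raise PipelineError(f"annotation[{m}]: {exc}") from exc
        annotated[m] = ann
        summaries[m] = profile_summary(ann, m)

    result: dict = {
        "profiles": profiles,
        "annotated": annotated,
        "summaries": summaries,
        "provenance": provenances,
    }

    a, b = config.overlap_pair
    if a in profiles and b in profiles and profiles[a].compounds and profiles[b].compounds:
        try:
            match = match_across_methods(
                profiles[a], profiles[b],
                mz_tol=config.mz_tol,
                n_diagnostic=config.n_diagnostic,
                top_k=config.top_k_ions,
            )
        except Exception as exc:
            raise PipelineError(f"overlap[{a} vs {b}]: {exc}") from exc
        result["match"] = match

        records = _labelled_records(peaks, profiles[b], match, config.rt_tol)
        result["records"] = records
        rel_a = _side_relative_means(peaks, profiles[a], config.rt_tol)
        rel_b = relative_mean_areas_by_cluster(records)
        try:
            result["rho_rt"] = rt_rank_correlation(match) if match.n_common >= 3 else None
            result["rho_area"] = (
                area_rank_correlation(match, rel_a, rel_b) if match.n_common >= 3 else None
            )
        except Exception as exc:
            raise PipelineError(f"overlap-correlation[{a} vs {b}]: {exc}") from exc
        try:
            labels = {r.set_label for r in records}
            result["mixed_model"] = (
                fit_common_vs_unique_model(records) if {"common", "unique"} <= labels else None
            )
        except Exception as exc:
            raise PipelineError(f"stats[common-vs-unique]: {exc}") from exc

    _write_outputs(result, config, outdir)
    return result


def _cluster_lookup(profile, rt_tol):
    """Map a peak to its profile cluster by membership."""
    lookup = {}
    for c in profile.compounds:
        for p in c.member_peaks:
            lookup[p] = c.cluster_id
    return lookup


def _labelled_records(peaks, profile_b, match, rt_tol) -> list[RelativeAreaRecord]:
    """Relative-area records of the finer method, labelled common/unique."""
    common_ids = {p.cluster_b.cluster_id for p in match.pairs}
    lookup = _cluster_lookup(profile_b, rt_tol)
    records: list[RelativeAreaRecord] = []
    method_peaks = [p for p in peaks if p.method_id == profile_b.method_id and not p.is_blank]
    by_sample: dict[str, list] = {}
    for p in method_peaks:
        by_sample.setdefault(p.sample_id, []).append(p)
    for sample_peaks in by_sample.values():
        for r in relative_areas(sample_peaks, lookup):
            if r.cluster_id is None:
                continue  # peak not in any retained cluster
            records.append(
                RelativeAreaRecord(
                    sample_id=r.sample_id,
                    animal_id=r.animal_id,
                    cluster_id=r.cluster_id,
                    relative_area=r.relative_area,
                    set_label="common" if r.cluster_id in common_ids else "unique",
                )
            )
    return records


def _side_relative_means(peaks, profile, rt_tol) -> dict[str, float]:
    lookup = _cluster_lookup(profile, rt_tol)
    records = []
    method_peaks = [p for p in peaks if p.method_id == profile.method_id and not p.is_blank]
    by_sample: dict[str, list] = {}
    for p in method_peaks:
        by_sample.setdefault(p.sample_id, []).append(p)
    for sample_peaks in by_sample.values():
        records.extend(relative_areas(sample_peaks, lookup))
    return relative_mean_areas_by_cluster(records)


def _attach_run_log(outdir: Path) -> None:
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)


def _write_outputs(result: dict, config: PipelineConfig, outdir: Path) -> None:
    import pandas as pd

    for m, profile in result["profiles"].items():
        ann = {id(a.cluster): a for a in result["annotated"].get(m, [])}
        rows = []
        for c in profile.compounds:
            a = ann.get(id(c))
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "rt_center": c.rt_center,
                    "rt_lo": c.rt_lo,
                    "rt_hi": c.rt_hi,
                    "n_samples_present": c.n_samples_present,
                    "mean_area": c.mean_area,
                    "name": a.name if a else None,
                    "match_score": a.match_score if a else None,
                    "boiling_point_c": a.boiling_point_c if a else None,
                    "volatility": a.volatility if a else None,
                    "origin_class": a.origin_class if a else None,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / f"profile_{m}.csv", index=False)

    if "match" in result:
        match = result["match"]
        pd.DataFrame(
            [
                {
                    "cluster_a": p.cluster_a.cluster_id,
                    "rt_a": p.cluster_a.rt_center,
                    "cluster_b": p.cluster_b.cluster_id,
                    "rt_b": p.cluster_b.rt_center,
                    "diagnostic_ions": " ".join(str(i) for i in p.diagnostic_ions),
                }
                for p in match.pairs
            ]
        ).to_csv(outdir / "overlap_pairs.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "methods": {
            m: {
                "n_total": s.n_total,
                "n_volatile": s.n_volatile,
                "pct_volatile": None if s.n_total == 0 else s.pct_volatile,
                "origin_counts": dict(s.origin_counts),
            }
            for m, s in result["summaries"].items()
        },
        "counts": {
            m: {k: v for k, v in prov.items() if isinstance(v, (int, str))}
            for m, prov in result["provenance"].items()
        },
    }
    if "match" in result:
        summary["overlap"] = {
            "method_a": result["match"].method_a,
            "method_b": result["match"].method_b,
            "n_common": result["match"].n_common,
            "n_unique_a": len(result["match"].unique_a),
            "n_unique_b": len(result["match"].unique_b),
            "rho_rt": None if result.get("rho_rt") is None else result["rho_rt"].rho,
            "rho_area": None if result.get("rho_area") is None else result["rho_area"].rho,
        }
    if result.get("mixed_model") is not None:
        mm = result["mixed_model"]
        summary["mixed_model"] = {
            "effect": mm.effect,
            "chi2": mm.chi2,
            "df": mm.df,
            "p_value": mm.p_value,
            "n_obs": mm.n_obs,
            "converged": mm.converged,
        }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
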