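"""Synthetic multi-method GC-MS datasets with known ground truth.

The study design emulated here is a body-odor method comparison on common
marmosets: six animals, two replicate samples per animal per sampling method,
plus per-method blank samples.  Five sampling methods/adsorbents are modelled
— cotton swabs, a mobile GC-MS with a thermal-desorption trap, and three
thermal-desorption tube variants (mixed-bed, Tenax TA, XAD-4).  Each method
has its own sensitivity, boiling-point coverage window, retention-time mapping
and noise level, so the generator reproduces the qualitative structure the
analysis stages assume:

* a latent compound panel spanning both sides of the 250 °C volatility
  threshold (boiling points uniform on 80-400 °C);
* log-normal per-sample peak areas around a compound-specific mean, with
  animal- and sample-level random effects;
* detection probability increasing in mean log abundance, so an insensitive
  instrument preferentially catches the most abundant compounds;
* exogenous (contaminant) compounds emitted into blanks at equal-or-higher
  mean area than into animal samples, giving the blank filter genuine true
  positives and negatives;
* strictly increasing, instrument-specific retention-time maps with Gaussian
  jitter, so cross-instrument elution order is preserved up to noise.

Everything derives from a single integer master seed via per-(method, sample)
child seeds, so identical configuration gives byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .peak_io import (
    LibraryEntry,
    Peak,
    write_compound_metadata,
    write_msp_library,
    write_peak_table,
)

__all__ = [
    "ConfigurationError",
    "LatentCompound",
    "RTMap",
    "MethodSpec",
    "SimulationTruth",
    "SyntheticDataset",
    "PanelParams",
    "default_method_specs",
    "noiseless",
    "generate_panel",
    "generate_dataset",
    "instrument_observed_rt",
    "simulate_relative_area_records",
]

ORIGIN_CLASSES = (
    "exogenous",
    "potentially_endogenous",
    "potentially_metabolized",
    "unclassified",
)

# Detection probability is logistic((mean_log_abundance - midpoint)/scale
# + logit(sensitivity)): a logistic curve in log abundance shifted by the
# method's sensitivity on the logit scale.  Sensitivity is therefore exactly
# the detection probability for a compound of median (midpoint) abundance;
# sensitivity 1 means certain detection (the noiseless limit used in recovery
# tests); and detection stays monotone increasing in abundance, which is what
# makes a low-sensitivity instrument see mostly the most abundant compounds.
DETECTION_MIDPOINT = 13.0
DETECTION_SCALE = 1.5


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LatentCompound:
    """A ground-truth compound in the simulated panel."""

    compound_id: str
    name: str
    true_rt_index: float
    boiling_point_c: float
    origin_class: str
    mean_log_abundance: float
    spectrum: tuple[tuple[float, float], ...]
    cas: str | None = None

    def __post_init__(self) -> None:
        if self.origin_class not in ORIGIN_CLASSES:
            raise ConfigurationError(f"unknown origin class {self.origin_class!r}")
        n = len(self.spectrum)
        if not 3 <= n <= 40:
            raise ConfigurationError(f"{self.compound_id}: spectrum must have 3-40 sticks, got {n}")
        mzs = [mz for mz, _ in self.spectrum]
        if len(set(mzs)) != len(mzs):
            raise ConfigurationError(f"{self.compound_id}: duplicate m/z in spectrum")
        if any(not 30 <= mz <= 300 for mz in mzs):
            raise ConfigurationError(f"{self.compound_id}: m/z outside [30, 300]")


@dataclass(frozen=True)
class RTMap:
    """Affine-plus-curvature map from elution coordinate to retention time (min).

    ``rt = intercept + slope * t + curvature * t**2``; must be strictly
    increasing over the panel's elution range.
    """

    intercept: float
    slope: float
    curvature: float = 0.0

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * t + self.curvature * t * t

    def validate_increasing(self, t_lo: float, t_hi: float) -> None:
        # derivative slope + 2*curvature*t is linear in t: check the endpoints
        for t in (t_lo, t_hi):
            if self.slope + 2.0 * self.curvature * t <= 0:
                raise ConfigurationError(
                    f"rt_map not strictly increasing over [{t_lo}, {t_hi}]"
                )


@dataclass(frozen=True)
class MethodSpec:
    """Sampling-method/instrument configuration for the simulator."""

    method_id: str
    sensitivity: float
    volatility_window: tuple[float, float]
    rt_map: RTMap
    rt_jitter_sd: float = 0.01
    area_noise_sd: float = 0.5
    n_animals: int = 6
    n_replicates_per_animal: int = 2
    n_blanks: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ConfigurationError(f"{self.method_id}: sensitivity must be in (0, 1]")
        lo, hi = self.volatility_window
        if not lo < hi:
            raise ConfigurationError(f"{self.method_id}: empty volatility window")
        if self.rt_jitter_sd < 0 or self.area_noise_sd < 0:
            raise ConfigurationError(f"{self.method_id}: negative noise sd")

    @property
    def n_samples(self) -> int:
        return self.n_animals * self.n_replicates_per_animal

    def detection_probability(self, mean_log_abundance: float) -> float:
        if self.sensitivity >= 1.0:
            return 1.0
        z = (mean_log_abundance - DETECTION_MIDPOINT) / DETECTION_SCALE
        offset = math.log(self.sensitivity / (1.0 - self.sensitivity))
        return float(expit(z + offset))

    def captures(self, compound: LatentCompound) -> bool:
        lo, hi = self.volatility_window
        return lo <= compound.boiling_point_c < hi


@dataclass
class SimulationTruth:
    """Latent state behind a generated dataset, used to score recovery."""

    panel: list[LatentCompound]
    detectable: dict[str, frozenset[str]]  # method_id -> compound_id set
    assignments: dict[tuple[str, int], str]  # (sample_id, peak index) -> compound/contaminant id

    def compound(self, compound_id: str) -> LatentCompound:
        return next(c for c in self.panel if c.compound_id == compound_id)


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate_dataset`."""

    peaks: list[Peak]
    library: list[LibraryEntry]
    metadata_rows: list[tuple[str, str, str | None, float | None, str]]
    truth: SimulationTruth
    method_specs: list[MethodSpec]
    seed: int

    def peaks_for_method(self, method_id: str, blanks: bool | None = None) -> list[Peak]:
        out = [p for p in self.peaks if p.method_id == method_id]
        if blanks is not None:
            out = [p for p in out if p.is_blank == blanks]
        return out

    def compound_of_peak(self) -> dict[Peak, str]:
        """Map every emitted peak to its true compound/contaminant id."""
        counter: dict[str, int] = {}
        out: dict[Peak, str] = {}
        for p in self.peaks:
            idx = counter.get(p.sample_id, 0)
            counter[p.sample_id] = idx + 1
            out[p] = self.truth.assignments[(p.sample_id, idx)]
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write peak table, MSP library and metadata CSV; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / "peaks.csv",
            "library": outdir / "library.msp",
            "metadata": outdir / "metadata.csv",
        }
        write_peak_table(self.peaks, paths["peaks"])
        write_msp_library(self.library, paths["library"])
        write_compound_metadata(self.metadata_rows, paths["metadata"])
        return paths


@dataclass(frozen=True)
class PanelParams:
    """Latent-panel configuration.

    Defaults: 60 compounds with boiling points uniform on 80-400 °C (so the
    panel straddles the 250 °C volatility threshold), origin-class proportions
    12 % exogenous / 34 % potentially endogenous / 50 % potentially metabolized
    / 4 % unclassified, mean log areas normal around ``log(4e5)``, and a
    minimum elution-coordinate gap so distinct compounds do not co-elute.
    """

    n_compounds: int = 60
    bp_range: tuple[float, float] = (80.0, 400.0)
    origin_probs: tuple[float, float, float, float] = (0.12, 0.34, 0.50, 0.04)
    abundance_mean: float = 13.0
    abundance_sd: float = 1.8
    min_rt_gap: float = 0.25
    mean_rt_gap: float = 0.40
    n_decoys: int = 15
    blank_log_boost: float = math.log(2.0)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("panel must contain at least one compound")
        if abs(sum(self.origin_probs) - 1.0) > 1e-9:
            raise ConfigurationError("origin_probs must sum to 1")


def default_method_specs() -> list[MethodSpec]:
    """The five sampling methods of the emulated design.

    Coverage windows and sensitivities encode the qualitative findings the
    pipeline is meant to reproduce: the mixed-bed TD tube covers the full
    boiling-point range at high sensitivity; the mobile GC-MS sees only
    volatiles (< 250 °C) at low sensitivity; cotton swabs favour semi- and
    non-volatiles; the single-adsorbent TD tubes sit in between.  RT maps are
    loosely scaled to each instrument's run length (mobile ~1-10 min, lab TD
    ~3-16 min).
    """
    return [
        MethodSpec(
            "cotton",
            sensitivity=0.6,
            volatility_window=(170.0, 400.01),
            rt_map=RTMap(1.5, 0.90, 0.0),
        ),
        MethodSpec(
            "mobile",
            sensitivity=0.5,
            volatility_window=(80.0, 250.0),
            rt_map=RTMap(0.55, 0.42, 0.004),
        ),
        MethodSpec(
            "td_mix",
            sensitivity=0.90,
            volatility_window=(80.0, 400.01),
            rt_map=RTMap(2.3, 0.68, 0.001),
        ),
        MethodSpec(
            "td_tenax",
            sensitivity=0.80,
            volatility_window=(90.0, 380.0),
            rt_map=RTMap(3.0, 0.75, 0.002),
        ),
        MethodSpec(
            "td_xad4",
            sensitivity=0.70,
            volatility_window=(100.0, 380.0),
            rt_map=RTMap(2.6, 0.80, 0.001),
            n_animals=5,  # this adsorbent yielded 10 samples in the emulated design
        ),
    ]


def noiseless(spec: MethodSpec) -> MethodSpec:
    """A copy of ``spec`` with certain detection and zero RT/area noise."""
    return replace(spec, sensitivity=1.0, rt_jitter_sd=0.0, area_noise_sd=0.0)


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    # counter-based split: one child stream per (method, sample) and per stage
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_panel(params: PanelParams, seed: int) -> list[LatentCompound]:
    """Draw the latent compound panel.

    Elution order equals boiling-point order (non-polar columns elute roughly
    by volatility), with a jittered minimum gap between consecutive elution
    coordinates so distinct compounds are chromatographically resolvable.
    """
    rng = _child_rng(seed, 0)
    n = params.n_compounds
    bps = np.sort(rng.uniform(*params.bp_range, size=n))
    gaps = params.min_rt_gap + rng.exponential(
        params.mean_rt_gap - params.min_rt_gap, size=n
    )
    rts = 1.0 + np.cumsum(gaps) - gaps[0]
    origins = rng.choice(ORIGIN_CLASSES, size=n, p=params.origin_probs)
    abundances = rng.normal(params.abundance_mean, params.abundance_sd, size=n)
    panel = []
    for i in range(n):
        panel.append(
            LatentCompound(
                compound_id=f"c{i:03d}",
                name=f"compound-{i:03d}",
                cas=f"{9000 + i}-{10 + i % 90}-{i % 10}",
                true_rt_index=float(rts[i]),
                boiling_point_c=float(bps[i]),
                origin_class=str(origins[i]),
                mean_log_abundance=float(abundances[i]),
                spectrum=_random_spectrum(rng),
            )
        )
    return panel


def _random_spectrum(
    rng: np.random.Generator, n_min: int = 5, n_max: int = 25
) -> tuple[tuple[float, float], ...]:
    n = int(rng.integers(n_min, n_max + 1))
    mzs = rng.choice(np.arange(30, 301), size=n, replace=False)
    intensities = rng.uniform(20.0, 999.0, size=n)
    intensities[int(rng.integers(n))] = 999.0  # one base peak at full scale
    order = np.argsort(mzs)
    return tuple((float(mzs[i]), float(round(intensities[i], 1))) for i in order)


def instrument_observed_rt(
    true_rt_index: float, spec: MethodSpec, rng: np.random.Generator | None = None
) -> float:
    """Map an elution coordinate through a method's RT map, adding jitter."""
    rt = float(spec.rt_map(true_rt_index))
    if spec.rt_jitter_sd > 0:
        if rng is None:
            raise ValueError("rng required when rt_jitter_sd > 0")
        rt += float(rng.normal(0.0, spec.rt_jitter_sd))
    return rt


def _noisy_spectrum(
    spectrum: Sequence[tuple[float, float]], rng: np.random.Generator, sd: float = 0.08
) -> tuple[tuple[float, float], ...]:
    if sd <= 0:
        return tuple(spectrum)
    out = []
    for mz, inten in spectrum:
        out.append((mz, float(max(1.0, inten * math.exp(rng.normal(0.0, sd))))))
    return tuple(out)


def generate_dataset(
    method_specs: Sequence[MethodSpec] | None = None,
    panel_params: PanelParams | None = None,
    seed: int = 1,
    panel: Sequence[LatentCompound] | None = None,
    spectrum_noise_sd: float = 0.08,
    n_blank_noise_peaks: float = 2.0,
) -> SyntheticDataset:
    """Generate peak tables for all methods and blanks, a library, metadata, and truth.

    Animal samples contain, for each compound within the method's volatility
    window, a Bernoulli-detected peak with log-normal area around the
    compound's mean log abundance plus animal- and sample-level effects.
    Blank samples contain every exogenous panel compound (at
    ``blank_log_boost`` higher mean log area) plus Poisson-distributed pure
    noise peaks; they never contain non-exogenous panel compounds.
    """
    specs = list(default_method_specs() if method_specs is None else method_specs)
    if not specs:
        raise ConfigurationError("at least one MethodSpec is required")
    params = panel_params or PanelParams()
    if panel is None:
        panel = generate_panel(params, seed)
    panel = list(panel)
    if not panel:
        raise ConfigurationError("panel must contain at least one compound")

    t_lo = min(c.true_rt_index for c in panel)
    t_hi = max(c.true_rt_index for c in panel)
    for spec in specs:
        spec.rt_map.validate_increasing(t_lo, t_hi)

    detectable = {
        spec.method_id: frozenset(c.compound_id for c in panel if spec.captures(c))
        for spec in specs
    }
    truth = SimulationTruth(panel=panel, detectable=detectable, assignments={})
    peaks: list[Peak] = []

    for m_idx, spec in enumerate(specs):
        captured = [c for c in panel if spec.captures(c)]
        # per-(animal, compound) effects shared by that animal's replicates
        eff_rng = _child_rng(seed, 1, m_idx)
        animal_effects = {
            (a, c.compound_id): float(eff_rng.normal(0.0, 0.3))
            for a in range(spec.n_animals)
            for c in captured
        }
        sample_index = 0
        for a in range(spec.n_animals):
            for rep in range(spec.n_replicates_per_animal):
                sample_id = f"{spec.method_id}_a{a + 1}_r{rep + 1}"
                rng = _child_rng(seed, 2, m_idx, sample_index)
                sample_effect = float(rng.normal(0.0, 0.2))
                sample_peaks: list[tuple[float, Peak, str]] = []
                for c in captured:
                    if rng.random() >= spec.detection_probability(c.mean_log_abundance):
                        continue
                    rt = instrument_observed_rt(c.true_rt_index, spec, rng)
                    log_area = (
                        c.mean_log_abundance
                        + animal_effects[(a, c.compound_id)]
                        + sample_effect
                        + (rng.normal(0.0, spec.area_noise_sd) if spec.area_noise_sd else 0.0)
                    )
                    peak = Peak(
                        sample_id=sample_id,
                        animal_id=f"a{a + 1}",
                        method_id=spec.method_id,
                        is_blank=False,
                        rt_min=round(max(rt, 1e-3), 4),
                        area=round(math.exp(log_area), 2),
                        spectrum=_noisy_spectrum(c.spectrum, rng, spectrum_noise_sd),
                    )
                    sample_peaks.append((peak.rt_min, peak, c.compound_id))
                sample_peaks.sort(key=lambda t: t[0])
                for idx, (_, peak, cid) in enumerate(sample_peaks):
                    truth.assignments[(sample_id, idx)] = cid
                    peaks.append(peak)
                sample_index += 1

        exogenous = [c for c in captured if c.origin_class == "exogenous"]
        for b in range(spec.n_blanks):
            sample_id = f"{spec.method_id}_blank{b + 1}"
            rng = _child_rng(seed, 3, m_idx, b)
            blank_peaks: list[tuple[float, Peak, str]] = []
            for c in exogenous:
                rt = instrument_observed_rt(c.true_rt_index, spec, rng)
                log_area = (
                    c.mean_log_abundance
                    + params.blank_log_boost
                    + (rng.normal(0.0, spec.area_noise_sd) if spec.area_noise_sd else 0.0)
                )
                peak = Peak(
                    sample_id=sample_id,
                    animal_id="",
                    method_id=spec.method_id,
                    is_blank=True,
                    rt_min=round(max(rt, 1e-3), 4),
                    area=round(math.exp(log_area), 2),
                    spectrum=_noisy_spectrum(c.spectrum, rng, spectrum_noise_sd),
                )
                blank_peaks.append((peak.rt_min, peak, c.compound_id))
            n_noise = int(rng.poisson(n_blank_noise_peaks)) if n_blank_noise_peaks > 0 else 0
            rt_lo, rt_hi = float(spec.rt_map(t_lo)), float(spec.rt_map(t_hi))
            for k in range(n_noise):
                rt = float(rng.uniform(rt_lo, rt_hi))
                peak = Peak(
                    sample_id=sample_id,
                    animal_id="",
                    method_id=spec.method_id,
                    is_blank=True,
                    rt_min=round(max(rt, 1e-3), 4),
                    area=round(float(rng.lognormal(10.0, 0.5)), 2),
                    spectrum=_random_spectrum(rng, 3, 8),
                )
                blank_peaks.append((peak.rt_min, peak, f"noise_{spec.method_id}_b{b}_{k}"))
            blank_peaks.sort(key=lambda t: t[0])
            for idx, (_, peak, cid) in enumerate(blank_peaks):
                truth.assignments[(sample_id, idx)] = cid
                peaks.append(peak)

    library = _build_library(panel, params, seed)
    metadata_rows = [
        (c.compound_id, c.name, c.cas, round(c.boiling_point_c, 1), c.origin_class)
        for c in panel
    ]
    return SyntheticDataset(
        peaks=peaks,
        library=library,
        metadata_rows=metadata_rows,
        truth=truth,
        method_specs=specs,
        seed=seed,
    )


def _build_library(
    panel: Sequence[LatentCompound], params: PanelParams, seed: int
) -> list[LibraryEntry]:
    """Reference library: every panel compound plus decoy entries not in the panel."""
    rng = _child_rng(seed, 4)
    entries = [
        LibraryEntry(
            name=c.name,
            cas=c.cas,
            boiling_point_c=round(c.boiling_point_c, 1),
            spectrum=c.spectrum,
        )
        for c in panel
    ]
    for d in range(params.n_decoys):
        entries.append(
            LibraryEntry(
                name=f"decoy-{d:03d}",
                cas=None,
                boiling_point_c=round(float(rng.uniform(*params.bp_range)), 1),
                spectrum=_random_spectrum(rng),
            )
        )
    return entries


def simulate_relative_area_records(
    seed: int,
    n_animals: int = 6,
    n_samples: int = 12,
    n_common: int = 8,
    n_unique: int = 8,
    common_shift: float = 0.0,
    intercept: float = -8.0,
    animal_sd: float = 0.4,
    sample_sd: float = 0.3,
    animal_slope_sd: float = 0.15,
    sample_slope_sd: float = 0.15,
    residual_sd: float = 0.6,
):
    """Simulate labelled relative-area records under the mixed model's data process.

    Log relative areas follow ``intercept + common_shift * is_common`` plus
    uncorrelated random intercepts and common/unique slopes for animal and
    sample, plus residual noise.  Samples are assigned to animals round-robin
    (two replicates per animal at the defaults).  Used for power and type-I
    calibration of :func:`vocompare.stats.fit_common_vs_unique_model`.
    """
    from .stats import RelativeAreaRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    animal_of_sample = [s % n_animals for s in range(n_samples)]
    a_int = rng.normal(0.0, animal_sd, size=n_animals)
    a_slp = rng.normal(0.0, animal_slope_sd, size=n_animals)
    records = []
    for s in range(n_samples):
        a = animal_of_sample[s]
        s_int = float(rng.normal(0.0, sample_sd))
        s_slp = float(rng.normal(0.0, sample_slope_sd))
        for c in range(n_common + n_unique):
            is_common = c < n_common
            y = (
                intercept
                + (common_shift if is_common else 0.0)
                + a_int[a]
                + s_int
                + ((a_slp[a] + s_slp) if is_common else 0.0)
                + float(rng.normal(0.0, residual_sd))
            )
            records.append(
                RelativeAreaRecord(
                    sample_id=f"s{s:02d}",
                    animal_id=f"a{a}",
                    cluster_id=f"k{c:02d}",
                    relative_area=math.exp(y),
                    set_label="common" if is_common else "unique",
                )
            )
    return records
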