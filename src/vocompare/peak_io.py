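"""Readers and writers for the on-disk artifacts of a GC-MS method comparison.

Three plain-text formats are handled here:

* **Peak tables** — one CSV per dataset, one row per detected chromatographic
  peak, with the stick spectrum inlined as space-separated ``mz:intensity``
  pairs.  Columns: ``sample_id,animal_id,method_id,is_blank,rt_min,area,spectrum``.
* **MSP spectral libraries** — the NIST text dialect: ``Name:`` / optional
  ``CAS:`` / optional ``BP:`` headers, a ``Num Peaks:`` count, then one
  ``mz intensity`` stick per line, records separated by blank lines.
* **Compound metadata** — CSV mapping compound names to boiling points and
  origin classes, with tolerant parsing of ``95±3``-style uncertainty and
  shorthand origin labels (``exo``, ``pot endo``, ``pot metab``).

All readers reject malformed input with row/record-addressed errors; rows are
never silently dropped.  Writers round-trip bit-identically with the readers
for finite inputs (floats are serialised with ``repr``, which is shortest
round-trip in Python 3).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Peak",
    "LibraryEntry",
    "PeakTableFormatError",
    "MSPFormatError",
    "MetadataError",
    "ORIGIN_CLASSES",
    "normalize_origin",
    "encode_spectrum",
    "decode_spectrum",
    "read_peak_table",
    "write_peak_table",
    "read_msp_library",
    "write_msp_library",
    "read_compound_metadata",
    "write_compound_metadata",
]

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "animal_id",
    "method_id",
    "is_blank",
    "rt_min",
    "area",
    "spectrum",
)

ORIGIN_CLASSES = (
    "exogenous",
    "potentially_endogenous",
    "potentially_metabolized",
    "unclassified",
)

#: Shorthand origin labels as they appear in curated compound tables.
_ORIGIN_ALIASES = {
    "exogenous": "exogenous",
    "exo": "exogenous",
    "potentially_endogenous": "potentially_endogenous",
    "potentially endogenous": "potentially_endogenous",
    "pot endo": "potentially_endogenous",
    "pot_endo": "potentially_endogenous",
    "endogenous": "potentially_endogenous",
    "potentially_metabolized": "potentially_metabolized",
    "potentially metabolized": "potentially_metabolized",
    "pot metab": "potentially_metabolized",
    "pot_metab": "potentially_metabolized",
    "pot met": "potentially_metabolized",
    "pot_met": "potentially_metabolized",
    "unclassified": "unclassified",
}


class PeakTableFormatError(ValueError):
    """Peak-table file violates the documented CSV dialect."""


class MSPFormatError(ValueError):
    """MSP library file violates the NIST text dialect."""


class MetadataError(ValueError):
    """Compound-metadata table is inconsistent."""


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak in one sample.

    ``spectrum`` is a tuple of ``(mz, intensity)`` sticks from a unit-resolution
    quadrupole scan (m/z 30-300 in the instruments emulated here).  Blank
    samples have an empty ``animal_id``.
    """

    sample_id: str
    animal_id: str
    method_id: str
    is_blank: bool
    rt_min: float
    area: float
    spectrum: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.rt_min > 0:
            raise ValueError(f"rt_min must be > 0, got {self.rt_min}")
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")
        if self.is_blank and self.animal_id:
            raise ValueError("blank peaks must have an empty animal_id")


@dataclass(frozen=True)
class LibraryEntry:
    """One reference spectrum in the spectral library."""

    name: str
    spectrum: tuple[tuple[float, float], ...]
    cas: str | None = None
    boiling_point_c: float | None = None

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError(f"library entry {self.name!r} has an empty spectrum")
        if any(i <= 0 for _, i in self.spectrum):
            raise ValueError(f"library entry {self.name!r} has non-positive intensities")


def normalize_origin(label: str) -> str:
    """Map an origin label (including shorthand aliases) to its canonical class.

    Unknown strings map to ``unclassified`` rather than erroring, since curated
    tables routinely carry free-text origin notes.
    """
    return _ORIGIN_ALIASES.get(label.strip().lower(), "unclassified")


def encode_spectrum(spectrum: Sequence[tuple[float, float]]) -> str:
    return " ".join(f"{_fmt(mz)}:{_fmt(i)}" for mz, i in spectrum)


def decode_spectrum(text: str) -> tuple[tuple[float, float], ...]:
    if not text.strip():
        return ()
    sticks = []
    for token in text.split():
        mz_s, _, int_s = token.partition(":")
        if not int_s:
            raise ValueError(f"malformed spectrum stick {token!r} (expected mz:intensity)")
        sticks.append((float(mz_s), float(int_s)))
    return tuple(sticks)


def _fmt(x: float) -> str:
    # repr() floats survive a write/read round trip exactly; integers stay compact
    if float(x).is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def read_peak_table(path: str | Path) -> list[Peak]:
    """Read a peak-table CSV into a list of :class:`Peak`.

    Raises :class:`PeakTableFormatError` naming the missing column for header
    problems and a row-addressed error for invalid values.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PeakTableFormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise PeakTableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                peak = Peak(
                    sample_id=row["sample_id"],
                    animal_id=row["animal_id"],
                    method_id=row["method_id"],
                    is_blank=_parse_bool(row["is_blank"]),
                    rt_min=float(row["rt_min"]),
                    area=float(row["area"]),
                    spectrum=decode_spectrum(row["spectrum"]),
                )
            except (ValueError, KeyError) as exc:
                raise PeakTableFormatError(f"{path}, row {lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_peak_table(peaks: Iterable[Peak], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_TABLE_COLUMNS)
        for p in peaks:
            writer.writerow(
                [
                    p.sample_id,
                    p.animal_id,
                    p.method_id,
                    "true" if p.is_blank else "false",
                    _fmt(p.rt_min),
                    _fmt(p.area),
                    encode_spectrum(p.spectrum),
                ]
            )


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"invalid boolean {text!r}")


def read_msp_library(path: str | Path) -> list[LibraryEntry]:
    """Parse an MSP library (NIST text dialect).

    The number of stick lines must equal the declared ``Num Peaks`` for every
    record; a mismatch raises :class:`MSPFormatError` naming the record.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    name: str | None = None
    cas: str | None = None
    bp: float | None = None
    num_peaks: int | None = None
    sticks: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, cas, bp, num_peaks, sticks
        if name is None:
            if sticks or num_peaks is not None:
                raise MSPFormatError(f"{path}: record without a Name: header")
            return
        if num_peaks is None:
            raise MSPFormatError(f"{path}: record {name!r} lacks a Num Peaks: header")
        if len(sticks) != num_peaks:
            raise MSPFormatError(
                f"{path}: record {name!r} declares {num_peaks} peaks but has {len(sticks)}"
            )
        entries.append(LibraryEntry(name=name, cas=cas, boiling_point_c=bp, spectrum=tuple(sticks)))
        name, cas, bp, num_peaks, sticks = None, None, None, None, []

    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            lower = line.lower()
            if lower.startswith("name:"):
                flush()
                name = line[5:].strip()
            elif lower.startswith("cas:"):
                cas = line[4:].strip() or None
            elif lower.startswith("bp:"):
                bp = float(line[3:].strip())
            elif lower.startswith("num peaks:"):
                num_peaks = int(line.split(":", 1)[1])
            elif ":" in line and not line[0].isdigit():
                continue  # tolerate extra metadata headers
            else:
                # stick lines: "91 999" (one pair) or "91 999; 92 600"
                try:
                    tokens = [float(t) for t in line.replace(";", " ").split()]
                except ValueError:
                    raise MSPFormatError(f"{path}: malformed stick line {line!r}") from None
                if len(tokens) % 2:
                    raise MSPFormatError(f"{path}: odd token count on stick line {line!r}")
                sticks.extend(
                    (tokens[i], tokens[i + 1]) for i in range(0, len(tokens), 2)
                )
    flush()
    return entries


def write_msp_library(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            if e.cas:
                fh.write(f"CAS: {e.cas}\n")
            if e.boiling_point_c is not None:
                fh.write(f"BP: {_fmt(e.boiling_point_c)}\n")
            fh.write(f"Num Peaks: {len(e.spectrum)}\n")
            for mz, inten in e.spectrum:
                fh.write(f"{_fmt(mz)} {_fmt(inten)}\n")
            fh.write("\n")


def parse_boiling_point(text: str) -> float:
    """Parse a boiling point, tolerating ``95±3``-style uncertainty.

    Classification uses the central value only; the uncertainty is dropped.
    """
    central = text.strip().split("±")[0].split("+/-")[0].strip()
    value = float(central)
    if not math.isfinite(value):
        raise ValueError(f"non-finite boiling point {text!r}")
    return value


def read_compound_metadata(path: str | Path) -> dict[str, tuple[float | None, str]]:
    """Read a compound-metadata CSV into ``{name.casefold(): (bp, origin_class)}``.

    Lookup is case-insensitive on the compound name.  Duplicate names with
    conflicting values raise :class:`MetadataError`; consistent duplicates are
    tolerated.
    """
    path = Path(path)
    out: dict[str, tuple[float | None, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MetadataError(f"{path}: empty file, expected a header row")
        for col in ("name", "boiling_point_c", "origin_class"):
            if col not in reader.fieldnames:
                raise MetadataError(f"{path}: missing column {col}")
        for lineno, row in enumerate(reader, start=2):
            key = row["name"].strip().casefold()
            bp_text = (row["boiling_point_c"] or "").strip()
            try:
                bp = parse_boiling_point(bp_text) if bp_text else None
            except ValueError as exc:
                raise MetadataError(f"{path}, row {lineno}: {exc}") from exc
            origin = normalize_origin(row["origin_class"] or "")
            value = (bp, origin)
            if key in out and out[key] != value:
                raise MetadataError(
                    f"{path}, row {lineno}: duplicate name {row['name']!r} with conflicting values"
                )
            out[key] = value
    return out


def write_compound_metadata(
    rows: Iterable[tuple[str, str, str | None, float | None, str]], path: str | Path
) -> None:
    """Write metadata rows ``(compound_id, name, cas, boiling_point_c, origin_class)``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "name", "cas", "boiling_point_c", "origin_class"])
        for cid, name, cas, bp, origin in rows:
            writer.writerow([cid, name, cas or "", "" if bp is None else _fmt(bp), origin])


def lookup_metadata(
    metadata: Mapping[str, tuple[float | None, str]], name: str
) -> tuple[float | None, str] | None:
    """Case-insensitive metadata lookup; ``None`` if the name is absent."""
    return metadata.get(name.strip().casefold())
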