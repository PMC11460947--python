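"""Seeded generator of synthetic specimen populations.

Emulates the measurement structure of a winged-ovule taxon diagnosis so
that the validation pipeline can be exercised end to end without any
fossil data.  In-range records satisfy *all* diagnosis ranges jointly:
wing free length is drawn conditionally on ovule length through the
free-fraction band, because sampling the two printed ranges
independently can break their ratio constraint.  Outlier records
violate exactly one trait, displaced outside its range by 10–50 % of
the range width, and carry the violated trait's name in their
provenance metadata — the ground truth the validator is checked
against.

Randomness comes from NumPy's PCG64 generator with an explicit integer
seed; the seed and full configuration are written to a JSON provenance
sidecar next to every generated CSV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .morphometrics import (
    CSV_COLUMNS,
    InvalidMeasurementError,
    SpecimenRecord,
    TaxonDiagnosis,
    builtin_diagnosis,
)

__all__ = [
    "GeneratorConfig",
    "ParseError",
    "generate",
    "write_specimens",
    "read_specimens",
    "write_provenance",
    "OUTLIER_TRAIT_POOL",
]

#: Traits eligible for outlier displacement: independent of the jointly
#: constrained (ovule_length, wing_free_length, free_fraction) triple, and
#: with room for a half-range-width displacement on both sides without
#: leaving the physical domain (positive lengths, angles inside (0, 180)).
OUTLIER_TRAIT_POOL = (
    "ovule_max_width_mm",
    "wing_max_width_mm",
    "nucellus_length_mm",
    "nucellus_max_width_mm",
    "branch_width_mm",
)

#: CSV measurement columns (all but the two identifier columns).
_MEASUREMENT_COLUMNS = [c for c in CSV_COLUMNS if c not in ("specimen_id", "taxon_hypothesis")]


class ParseError(ValueError):
    """Malformed specimen CSV; the message names the offending row and column."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic specimen population.

    distribution
        "uniform" over each trait range, or "truncated_normal" with the
        mean at the range midpoint and sd = range width / 4, truncated
        to the range.
    outlier_fraction
        Fraction of records (rounded to a count) displaced outside
        exactly one trait range by 10–50 % of the range width.
    missing_fraction
        Per-trait probability of omission, emulating incomplete
        fossils; never applied to the displaced trait of an outlier.
    """

    taxon: str = "alasemenia_tria"
    count: int = 100
    seed: int = 0
    distribution: str = "uniform"
    outlier_fraction: float = 0.0
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InvalidMeasurementError(f"count must be >= 1, got {self.count}")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise InvalidMeasurementError("outlier_fraction must lie in [0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise InvalidMeasurementError("missing_fraction must lie in [0, 1)")
        if self.distribution not in ("uniform", "truncated_normal"):
            raise InvalidMeasurementError(f"unknown distribution {self.distribution!r}")


def _draw(rng: np.random.Generator, lo: float, hi: float, distribution: str) -> float:
    if distribution == "uniform":
        return float(rng.uniform(lo, hi))
    mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    while True:  # truncate by rejection; acceptance ~ 95%
        x = float(rng.normal(mean, sd))
        if lo <= x <= hi:
            return x


def _sample_in_range(rng: np.random.Generator, d: TaxonDiagnosis, distribution: str) -> dict[str, float]:
    """One record satisfying every diagnosis range jointly."""
    nt = d.numeric_traits
    m: dict[str, float] = {}
    length = _draw(rng, nt["ovule_length_mm"].min, nt["ovule_length_mm"].max, distribution)
    m["ovule_length_mm"] = length
    # free length via the fraction band, intersected with its own range
    frac_tr, free_tr = nt["free_fraction"], nt["wing_free_length_mm"]
    lo = max(frac_tr.min, free_tr.min / length)
    hi = min(frac_tr.max, free_tr.max / length)
    m["wing_free_length_mm"] = _draw(rng, lo, hi, distribution) * length
    for name in (
        "ovule_max_width_mm",
        "wing_max_width_mm",
        "nucellus_length_mm",
        "nucellus_max_width_mm",
        "branch_width_mm",
        "dichotomy_angle_deg",
    ):
        m[name] = _draw(rng, nt[name].min, nt[name].max, distribution)
    m["wing_count"] = float(d.categorical_traits["wing_count"])
    return m


def generate(config: GeneratorConfig) -> list[SpecimenRecord]:
    """Generate a deterministic specimen population from a seeded config.

    Exactly ``round(count * outlier_fraction)`` records are outliers;
    each carries ``metadata["outlier_trait"]`` naming its single
    violated trait, and conforming records have ``is_outlier: False``.
    """
    d = builtin_diagnosis(config.taxon)
    rng = np.random.default_rng(config.seed)
    n_outliers = round(config.count * config.outlier_fraction)
    outlier_idx = set(rng.choice(config.count, size=n_outliers, replace=False).tolist()) if n_outliers else set()
    records: list[SpecimenRecord] = []
    for i in range(config.count):
        m = _sample_in_range(rng, d, config.distribution)
        meta: dict = {"is_outlier": False, "outlier_trait": None}
        if i in outlier_idx:
            trait = str(rng.choice(OUTLIER_TRAIT_POOL))
            tr = d.numeric_traits[trait]
            width = tr.max - tr.min
            delta = float(rng.uniform(0.1, 0.5)) * width
            above = bool(rng.random() < 0.5)
            m[trait] = tr.max + delta if above else tr.min - delta
            meta = {"is_outlier": True, "outlier_trait": trait}
        if config.missing_fraction > 0.0:
            for name in list(m):
                if name == meta["outlier_trait"]:
                    continue
                if rng.random() < config.missing_fraction:
                    del m[name]
        records.append(
            SpecimenRecord(
                specimen_id=f"SYN-{config.taxon[:4].upper()}-{i:05d}",
                taxon_hypothesis=config.taxon,
                measurements=m,
                metadata=meta,
            )
        )
    return records


def write_specimens(records: list[SpecimenRecord], path: str | Path) -> None:
    """Write records as CSV (header required, empty cell = missing).

    Floats are serialised with ``repr`` so the round-trip through
    :func:`read_specimens` is exact; wing_count is written as an
    integer.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = [rec.specimen_id, rec.taxon_hypothesis]
            for col in _MEASUREMENT_COLUMNS:
                value = rec.measurements.get(col)
                if value is None:
                    row.append("")
                elif col == "wing_count":
                    row.append(str(int(value)))
                else:
                    row.append(repr(float(value)))
            writer.writerow(row)


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen CSV back into records.

    Raises :class:`ParseError` naming the row and column of any
    non-numeric measurement cell or header mismatch.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {CSV_COLUMNS}") from None
        if header != CSV_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header}, expected {CSV_COLUMNS}")
        records = []
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(CSV_COLUMNS):
                raise ParseError(f"{path}: row {rownum} has {len(row)} cells, expected {len(CSV_COLUMNS)}")
            m: dict[str, float] = {}
            for col, cell in zip(_MEASUREMENT_COLUMNS, row[2:]):
                if cell == "":
                    continue
                try:
                    m[col] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {rownum}, column {col!r}: non-numeric cell {cell!r}"
                    ) from None
            records.append(
                SpecimenRecord(specimen_id=row[0], taxon_hypothesis=row[1], measurements=m)
            )
    return records


def write_provenance(config: GeneratorConfig, csv_path: str | Path) -> Path:
    """Write the generator config + seed as a JSON sidecar next to the CSV."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".provenance.json")
    payload = {
        "generator": "seedwind.synthetic",
        "rng": "numpy.random.Generator(PCG64)",
        "config": dataclasses.asdict(config),
    }
    sidecar.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return sidecar
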