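"""Trait schemas and specimen validation for Famennian winged ovules.

The three Late Devonian genera with winged ovules — *Alasemenia tria*
(three wings), *Guazia dongzhiensis* (four wings, distally incurved)
and *Warsteinia* (four short straight wings) — are encoded here as
machine-checkable diagnoses: numeric trait ranges (lengths in mm,
fractions, angles in degrees) plus categorical characters (wing count,
cupule, attachment, wing folding, distal wing curvature).  A measured
specimen can then be validated trait-by-trait against a diagnosis.

Fossils are incomplete, so missing measurements never count against a
specimen; they only lower its completeness score.  Ranges are inclusive
at both ends unless flagged otherwise (an "up to" bound has an open
minimum at zero).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

from .windward import DiasporeRotor, relative_efficiency, windward_stability

__all__ = [
    "TraitRange",
    "TaxonDiagnosis",
    "SpecimenRecord",
    "ValidationReport",
    "UnknownTaxonError",
    "InvalidMeasurementError",
    "builtin_diagnosis",
    "available_taxa",
    "derive_traits",
    "validate",
    "comparative_table",
    "diagnosis_to_json",
    "diagnosis_from_json",
    "load_diagnosis_schema",
    "CSV_COLUMNS",
    "UNKNOWN",
]

UNKNOWN = "unknown"

#: Specimen CSV dialect: header order; empty cell = missing measurement.
CSV_COLUMNS = [
    "specimen_id",
    "taxon_hypothesis",
    "ovule_length_mm",
    "ovule_max_width_mm",
    "wing_max_width_mm",
    "wing_free_length_mm",
    "nucellus_length_mm",
    "nucellus_max_width_mm",
    "branch_width_mm",
    "dichotomy_angle_deg",
    "wing_count",
]

_VALID_UNITS = {"mm", "fraction", "degrees", "count"}


class UnknownTaxonError(KeyError):
    """Requested taxon has no built-in diagnosis."""


class InvalidMeasurementError(ValueError):
    """A measurement violates its physical domain."""


@dataclass(frozen=True)
class TraitRange:
    """Inclusive numeric range for one trait.

    ``inclusive_min=False`` encodes an "up to X" bound (open at the
    minimum); ``approximate=True`` flags ranges the literature reports
    with "ca." — still enforced as hard bounds, but marked so reports
    can soften their wording.
    """

    name: str
    min: float
    max: float
    units: str
    inclusive_min: bool = True
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise InvalidMeasurementError(f"{self.name}: min {self.min} > max {self.max}")
        if self.units not in _VALID_UNITS:
            raise InvalidMeasurementError(f"{self.name}: unrecognised units {self.units!r}")

    def contains(self, value: float) -> bool:
        lower_ok = value >= self.min if self.inclusive_min else value > self.min
        return lower_ok and value <= self.max


@dataclass(frozen=True)
class TaxonDiagnosis:
    """Numeric trait ranges plus categorical characters for one taxon."""

    taxon: str
    numeric_traits: Mapping[str, TraitRange]
    categorical_traits: Mapping[str, Any]

    def __post_init__(self) -> None:
        wc = self.categorical_traits.get("wing_count")
        if not (isinstance(wc, int) and wc >= 1):
            raise InvalidMeasurementError(f"{self.taxon}: wing_count must be an integer >= 1")
        for name, tr in self.numeric_traits.items():
            if tr.name != name:
                raise InvalidMeasurementError(f"trait key {name!r} != range name {tr.name!r}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured specimen; measurements may be missing (incomplete fossils)."""

    specimen_id: str
    taxon_hypothesis: str
    measurements: Mapping[str, float]
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.measurements.items():
            if name.endswith("_deg"):
                if not (0.0 < value < 180.0):
                    raise InvalidMeasurementError(
                        f"{self.specimen_id}: angle {name}={value} outside (0, 180) degrees"
                    )
            elif not value > 0:
                raise InvalidMeasurementError(
                    f"{self.specimen_id}: measurement {name}={value} must be > 0"
                )


@dataclass(frozen=True)
class ValidationReport:
    """Per-trait verdicts ('pass' | 'fail' | 'missing') for one specimen."""

    specimen_id: str
    taxon: str
    verdicts: Mapping[str, str]
    warnings: tuple[str, ...] = ()

    @property
    def overall_conforms(self) -> bool:
        return not any(v == "fail" for v in self.verdicts.values())

    @property
    def completeness(self) -> float:
        """Fraction of diagnosis traits actually measured on this specimen."""
        n = len(self.verdicts)
        return sum(v != "missing" for v in self.verdicts.values()) / n if n else 0.0


def _alasemenia() -> TaxonDiagnosis:
    ranges = [
        TraitRange("ovule_length_mm", 25.0, 33.0, "mm"),
        TraitRange("ovule_max_width_mm", 3.5, 5.6, "mm"),
        TraitRange("wing_max_width_mm", 1.2, 2.3, "mm"),
        TraitRange("wing_free_length_mm", 8.3, 14.8, "mm"),
        TraitRange("free_fraction", 0.32, 0.45, "fraction"),
        TraitRange("nucellus_length_mm", 10.0, 11.7, "mm", approximate=True),
        TraitRange("nucellus_max_width_mm", 1.2, 1.7, "mm"),
        TraitRange("branch_length_mm", 0.0, 76.0, "mm", inclusive_min=False),
        TraitRange("branch_width_mm", 0.4, 0.9, "mm"),
        TraitRange("dichotomy_angle_deg", 40.0, 135.0, "degrees"),
    ]
    return TaxonDiagnosis(
        taxon="alasemenia_tria",
        numeric_traits={r.name: r for r in ranges},
        categorical_traits={
            "wing_count": 3,
            "cupule": "absent",
            "attachment": "terminal",
            "wing_folding": "inward-abaxial",
            "distal_wing_curvature": "outward",
        },
    )


def _guazia() -> TaxonDiagnosis:
    return TaxonDiagnosis(
        taxon="guazia_dongzhiensis",
        numeric_traits={},
        categorical_traits={
            "wing_count": 4,
            "cupule": "absent",
            "attachment": "terminal",
            "wing_folding": "inward-abaxial",
            "distal_wing_curvature": "inward",
        },
    )


def _warsteinia() -> TaxonDiagnosis:
    return TaxonDiagnosis(
        taxon="warsteinia",
        numeric_traits={},
        categorical_traits={
            "wing_count": 4,
            "cupule": UNKNOWN,
            "attachment": UNKNOWN,
            "wing_folding": "flat",
            "distal_wing_curvature": "straight",
        },
    )


_BUILTIN = {
    "alasemenia_tria": _alasemenia,
    "guazia_dongzhiensis": _guazia,
    "warsteinia": _warsteinia,
}


def available_taxa() -> list[str]:
    return sorted(_BUILTIN)


def builtin_diagnosis(taxon: str) -> TaxonDiagnosis:
    """Built-in diagnosis for one of the three winged-ovule genera."""
    try:
        return _BUILTIN[taxon]()
    except KeyError:
        raise UnknownTaxonError(
            f"unknown taxon {taxon!r}; available: {', '.join(available_taxa())}"
        ) from None


def derive_traits(s: SpecimenRecord) -> SpecimenRecord:
    """Add derived traits: free_fraction = wing_free_length / ovule_length.

    Returns the record unchanged when either source measurement is
    missing or the fraction is already present.
    """
    m = dict(s.measurements)
    if "free_fraction" not in m and "wing_free_length_mm" in m and "ovule_length_mm" in m:
        length = m["ovule_length_mm"]
        if length == 0:
            raise InvalidMeasurementError(f"{s.specimen_id}: ovule_length_mm is zero")
        m["free_fraction"] = m["wing_free_length_mm"] / length
        return dataclasses.replace(s, measurements=m)
    return s


def validate(s: SpecimenRecord, d: TaxonDiagnosis) -> ValidationReport:
    """Check one specimen against a diagnosis, trait by trait.

    Numeric traits are compared inclusively against their ranges;
    wing_count is an exact categorical match.  Absent measurements give
    a 'missing' verdict and can never fail.  Measurements for traits
    the diagnosis does not define are recorded as warnings.
    """
    s = derive_traits(s)
    verdicts: dict[str, str] = {}
    for name, tr in d.numeric_traits.items():
        value = s.measurements.get(name)
        if value is None:
            verdicts[name] = "missing"
        else:
            verdicts[name] = "pass" if tr.contains(value) else "fail"
    wc = s.measurements.get("wing_count")
    if wc is None:
        verdicts["wing_count"] = "missing"
    else:
        verdicts["wing_count"] = "pass" if int(wc) == d.categorical_traits["wing_count"] else "fail"
    known = set(d.numeric_traits) | {"wing_count"}
    warnings = tuple(
        f"measurement {name!r} not in diagnosis of {d.taxon}"
        for name in s.measurements
        if name not in known
    )
    return ValidationReport(
        specimen_id=s.specimen_id, taxon=d.taxon, verdicts=verdicts, warnings=warnings
    )


def comparative_table() -> pd.DataFrame:
    """Character matrix of the three genera plus model-derived dispersal metrics.

    Columns: the five categorical characters, the relative efficiency
    Er (percent) implied by each taxon's wing count, and the windward
    stability ratio.
    """
    rows = []
    for taxon in ["alasemenia_tria", "guazia_dongzhiensis", "warsteinia"]:
        d = builtin_diagnosis(taxon)
        cat = d.categorical_traits
        rotor = DiasporeRotor(n=cat["wing_count"])
        rows.append(
            {
                "taxon": taxon,
                "wing_count": cat["wing_count"],
                "wing_folding": cat["wing_folding"],
                "distal_wing_curvature": cat["distal_wing_curvature"],
                "cupule": cat["cupule"],
                "attachment": cat["attachment"],
                "er_percent": relative_efficiency(rotor).er_percent,
                "stability": windward_stability(rotor),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def diagnosis_to_json(d: TaxonDiagnosis) -> str:
    """Serialise a diagnosis to JSON (round-trips exactly)."""
    payload = {
        "taxon": d.taxon,
        "numeric_traits": [dataclasses.asdict(tr) for tr in d.numeric_traits.values()],
        "categorical_traits": dict(d.categorical_traits),
    }
    return json.dumps(payload, indent=2)


def diagnosis_from_json(text: str) -> TaxonDiagnosis:
    """Parse a diagnosis from JSON, with structural checks."""
    data = json.loads(text)
    for key in ("taxon", "numeric_traits", "categorical_traits"):
        if key not in data:
            raise InvalidMeasurementError(f"diagnosis JSON missing key {key!r}")
    traits = {}
    for item in data["numeric_traits"]:
        tr = TraitRange(**item)
        traits[tr.name] = tr
    return TaxonDiagnosis(
        taxon=data["taxon"],
        numeric_traits=traits,
        categorical_traits=data["categorical_traits"],
    )


def load_diagnosis_schema() -> dict:
    """The JSON schema describing the diagnosis serialisation format."""
    ref = importlib.resources.files("seedwind").joinpath("data/diagnosis.schema.json")
    return json.loads(ref.read_text(encoding="utf-8"))
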