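"""De Man morphometric indices and population summary statistics.

Nematode taxonomists condense raw body measurements (all in micrometres)
into a standard set of dimensionless descriptors introduced by de Man:

* ``L``  — body length, reported in millimetres;
* ``a``  — body length / greatest body diameter;
* ``b``  — body length / distance from the anterior end to the
  pharyngo-intestinal valve (pharynx length);
* ``c``  — body length / tail length;
* ``c'`` — tail length / body diameter at the anus;
* ``V``  — distance from the anterior end to the vulva as % of body length;
* ``G1``/``G2`` — anterior/posterior female gonad length as % of body length.

Two further descriptors are diagnostic for mononchids: the buccal capsule
length/width ratio, and the position of the dorsal tooth apex expressed as
a percentage of buccal capsule length from its anterior end.

Population tables report each character as ``mean ± sd (min–max)``; sample
standard deviation uses the n−1 denominator, and populations of one or two
specimens degenerate to the bare values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP, ROUND_HALF_EVEN
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenMeasurements",
    "DeManIndices",
    "SummaryStats",
    "MeasurementError",
    "compute_indices",
    "tooth_apex_position",
    "summarize_population",
    "indices_table",
    "round_half",
]

EN_DASH = "–"
MISSING_MARK = "–"  # how tables render an absent value


class MeasurementError(ValueError):
    """Raised for non-positive or mutually inconsistent raw measurements."""


def round_half(x: float, decimals: int = 0, mode: str = "away") -> float:
    """Round with an explicit tie rule.

    ``mode='away'`` rounds halves away from zero (the convention used when
    formatting indices); ``mode='even'`` is banker's rounding.  Python's
    built-in :func:`round` is half-even only, hence the explicit helper.
    """
    if mode not in ("away", "even"):
        raise ValueError(f"unknown rounding mode: {mode!r}")
    rule = ROUND_HALF_UP if mode == "away" else ROUND_HALF_EVEN
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=rule))


@dataclass
class SpecimenMeasurements:
    """Raw per-specimen measurements, in micrometres unless noted.

    Optional fields default to ``None`` (missing).  ``extra`` carries any
    additional numeric characters (spicule length, lip region height, ...)
    as an open name→value map, in micrometres unless documented otherwise
    by the producer.
    """

    specimen_id: str
    body_length: float
    taxon_label: str | None = None
    tail_length: float | None = None
    pharynx_length: float | None = None
    max_body_diameter: float | None = None
    body_diameter_at_anus: float | None = None
    vulva_distance: float | None = None
    anterior_gonad_length: float | None = None
    posterior_gonad_length: float | None = None
    buccal_capsule_length: float | None = None
    buccal_capsule_width: float | None = None
    tooth_apex_distance: float | None = None
    lip_region_width: float | None = None
    rectum_length: float | None = None
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            "body_length": self.body_length,
            "tail_length": self.tail_length,
            "pharynx_length": self.pharynx_length,
            "max_body_diameter": self.max_body_diameter,
            "body_diameter_at_anus": self.body_diameter_at_anus,
            "vulva_distance": self.vulva_distance,
            "anterior_gonad_length": self.anterior_gonad_length,
            "posterior_gonad_length": self.posterior_gonad_length,
            "buccal_capsule_length": self.buccal_capsule_length,
            "buccal_capsule_width": self.buccal_capsule_width,
            "tooth_apex_distance": self.tooth_apex_distance,
            "lip_region_width": self.lip_region_width,
            "rectum_length": self.rectum_length,
        }
        for name, value in numeric.items():
            if value is None:
                continue
            if not math.isfinite(value) or value <= 0:
                raise MeasurementError(
                    f"{self.specimen_id}: {name} must be positive and finite, got {value!r}"
                )
        if self.tail_length is not None and self.tail_length >= self.body_length:
            raise MeasurementError(
                f"{self.specimen_id}: tail_length ({self.tail_length}) must be "
                f"shorter than body_length ({self.body_length})"
            )
        if self.vulva_distance is not None and self.vulva_distance >= self.body_length:
            raise MeasurementError(
                f"{self.specimen_id}: vulva_distance ({self.vulva_distance}) must be "
                f"anterior to the body end ({self.body_length})"
            )
        if (
            self.tooth_apex_distance is not None
            and self.buccal_capsule_length is not None
            and self.tooth_apex_distance > self.buccal_capsule_length
        ):
            raise MeasurementError(
                f"{self.specimen_id}: tooth apex ({self.tooth_apex_distance}) lies "
                f"beyond the buccal capsule ({self.buccal_capsule_length})"
            )


@dataclass
class DeManIndices:
    """Derived De Man indices; an index whose inputs were absent is None.

    ``L`` is in millimetres; ``V``, ``G1``, ``G2`` and ``tooth_position``
    are percentages; the rest are dimensionless ratios.  Values are kept
    unrounded; rounding is applied only at formatting time.
    """

    specimen_id: str
    L: float
    a: float | None = None
    b: float | None = None
    c: float | None = None
    c_prime: float | None = None
    V: float | None = None
    G1: float | None = None
    G2: float | None = None
    bc_ratio: float | None = None
    tooth_position: float | None = None

    INDEX_NAMES = ("L", "a", "b", "c", "c_prime", "V", "G1", "G2", "bc_ratio", "tooth_position")

    @property
    def missing(self) -> frozenset[str]:
        """Names of indices that could not be computed."""
        return frozenset(n for n in self.INDEX_NAMES if getattr(self, n) is None)

    def as_dict(self) -> dict[str, float | None]:
        return {n: getattr(self, n) for n in self.INDEX_NAMES}

    def formatted(self, rounding: str = "away") -> dict[str, str]:
        """Render per table convention: 1 decimal for L and ratios/percents,
        integer for tooth position; missing values as the en-dash mark."""
        out: dict[str, str] = {}
        for name in self.INDEX_NAMES:
            value = getattr(self, name)
            if value is None:
                out[name] = MISSING_MARK
            elif name == "tooth_position":
                out[name] = str(int(round_half(value, 0, rounding)))
            elif name == "L":
                out[name] = f"{round_half(value, 2, rounding):.2f}"
            else:
                out[name] = f"{round_half(value, 1, rounding):.1f}"
        return out


def _ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None:
        return None
    return num / den


def compute_indices(m: SpecimenMeasurements) -> DeManIndices:
    """Compute the De Man indices for one specimen.

    Each index is computed exactly from its defining ratio; indices whose
    raw inputs are absent are left as missing (None), never imputed.
    """
    m.validate()
    tooth = None
    if m.tooth_apex_distance is not None and m.buccal_capsule_length is not None:
        tooth = tooth_apex_position(m.buccal_capsule_length, m.tooth_apex_distance)
    return DeManIndices(
        specimen_id=m.specimen_id,
        L=m.body_length / 1000.0,
        a=_ratio(m.body_length, m.max_body_diameter),
        b=_ratio(m.body_length, m.pharynx_length),
        c=_ratio(m.body_length, m.tail_length),
        c_prime=_ratio(m.tail_length, m.body_diameter_at_anus),
        V=None if m.vulva_distance is None else 100.0 * m.vulva_distance / m.body_length,
        G1=None
        if m.anterior_gonad_length is None
        else 100.0 * m.anterior_gonad_length / m.body_length,
        G2=None
        if m.posterior_gonad_length is None
        else 100.0 * m.posterior_gonad_length / m.body_length,
        bc_ratio=_ratio(m.buccal_capsule_length, m.buccal_capsule_width),
        tooth_position=tooth,
    )


def tooth_apex_position(bc_length: float, apex_distance: float) -> float:
    """Dorsal tooth apex position: distance from the apex to the anterior
    end of the buccal capsule as % of buccal capsule length.

    Returns the unrounded percentage; tables render it as an integer.
    """
    if bc_length <= 0 or apex_distance <= 0:
        raise MeasurementError("buccal capsule length and apex distance must be positive")
    if apex_distance > bc_length:
        raise MeasurementError(
            f"tooth apex distance ({apex_distance}) exceeds buccal capsule length ({bc_length})"
        )
    return 100.0 * apex_distance / bc_length


@dataclass(frozen=True)
class SummaryStats:
    """Population summary: n, mean, sample SD, range, and the table string."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    formatted: str


def _fmt_number(x: float, decimals: int) -> str:
    if decimals == 0:
        return str(int(round_half(x, 0)))
    return f"{round_half(x, decimals):.{decimals}f}"


def summarize_population(
    values: Sequence[float], decimals: int | None = None
) -> SummaryStats:
    """Summarise one character over a population.

    Formatting follows the table dialect: ``mean ± sd (min–max)`` for
    n ≥ 3, the bare comma-separated values for n = 2, and the single value
    for n = 1.  ``decimals`` controls rendering; by default integral inputs
    render as integers and fractional inputs with 2 decimals.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("summarize_population requires at least one value")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("all values must be finite")
    arr = np.asarray(vals, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    lo, hi = float(arr.min()), float(arr.max())
    if decimals is None:
        decimals = 0 if all(float(v).is_integer() for v in vals) else 2
    if n == 1:
        formatted = _fmt_number(vals[0], decimals)
    elif n == 2:
        formatted = ", ".join(_fmt_number(v, decimals) for v in vals)
    else:
        formatted = (
            f"{_fmt_number(mean, decimals)} ± {_fmt_number(sd, decimals)} "
            f"({_fmt_number(lo, decimals)}{EN_DASH}{_fmt_number(hi, decimals)})"
        )
    return SummaryStats(n=n, mean=mean, sd=sd, min=lo, max=hi, formatted=formatted)


#: characters shown in a morphometric table, in row order
TABLE_CHARACTERS: tuple[tuple[str, str], ...] = (
    ("L", "L (mm)"),
    ("a", "a"),
    ("b", "b"),
    ("c", "c"),
    ("c_prime", "c'"),
    ("V", "V (%)"),
    ("G1", "G1 (%)"),
    ("G2", "G2 (%)"),
    ("buccal_capsule_length", "Buccal capsule length"),
    ("buccal_capsule_width", "Buccal capsule width"),
    ("tooth_apex_distance", "Tooth apex from anterior end of buccal capsule"),
    ("tooth_position", "Position of tooth apex (%)"),
    ("pharynx_length", "Pharynx length"),
    ("lip_region_width", "Lip region width"),
    ("max_body_diameter", "Maximum body diameter"),
    ("body_diameter_at_anus", "Body diameter at anus"),
    ("anterior_gonad_length", "Anterior genital branch length"),
    ("posterior_gonad_length", "Posterior genital branch length"),
    ("vulva_distance", "Vulva from anterior end"),
    ("rectum_length", "Rectum length"),
    ("tail_length", "Tail length"),
)

_INDEX_DECIMALS = {"L": 2, "a": 1, "b": 1, "c": 1, "c_prime": 1, "V": 1, "G1": 1, "G2": 1}


def indices_table(
    specimens: Iterable[SpecimenMeasurements],
    group_by: str = "taxon_label",
) -> pd.DataFrame:
    """Render a population morphometric table, one column per group.

    Each cell holds the :func:`summarize_population` string for that
    character in that group (derived indices included); missing data render
    as an en dash.  ``group_by`` is the attribute used to form columns
    (``taxon_label`` by default; ungrouped specimens fall into ``''``).
    """
    specimens = list(specimens)
    if not specimens:
        raise ValueError("indices_table requires at least one specimen")
    groups: dict[str, list[SpecimenMeasurements]] = {}
    for sp in specimens:
        label = getattr(sp, group_by, None) or ""
        groups.setdefault(str(label), []).append(sp)

    rows: dict[str, dict[str, str]] = {}
    counts: dict[str, int] = {}
    for label, members in groups.items():
        counts[label] = len(members)
        derived = [compute_indices(m) for m in members]
        for attr, rowname in TABLE_CHARACTERS:
            if attr in DeManIndices.INDEX_NAMES:
                vals = [getattr(d, attr) for d in derived]
                decimals = _INDEX_DECIMALS.get(attr, 0)
            else:
                vals = [getattr(m, attr) for m in members]
                decimals = None
            present = [v for v in vals if v is not None]
            cell = (
                summarize_population(present, decimals=decimals).formatted
                if present
                else MISSING_MARK
            )
            rows.setdefault(rowname, {})[label] = cell

    frame = pd.DataFrame(rows).T
    frame = frame[[label for label in groups]]
    frame.columns = [
        f"{label} (n = {counts[label]})" if label else f"(n = {counts[label]})"
        for label in groups
    ]
    frame.index.name = "Character"
    return frame
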