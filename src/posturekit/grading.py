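"""Ordinal severity grading of postural index values.

Each index value is mapped onto a three-level ordinal scale
(light / medium / heavy) by a rubric of half-open intervals. The default
rubric encodes the standard screening breakpoints:

===========================  =============  ==============  ===========
index                        light          medium          heavy
===========================  =============  ==============  ===========
uneven_shoulders (deg)       [0, 2)         [2, 4)          >= 4
lateral_pelvic_tilt (deg)    [0, 2)         [2, 4)          >= 4
scoliosis (deg)              [0, 2)         [2, 4)          >= 4
scapula_inclination (deg)    [0, 5)         [5, 10)         >= 10
pelvic_tilt (deg)            [0, 15)        [15, 25)        >= 25
forward_head (cm)            [0, 2.5)       [2.5, 5)        >= 5
knee_alignment (deg)         [-1, 3)        [3, 5) O-leg    >= 5 O-leg
                                            (-3, -1) X-leg  <= -3 X-leg
===========================  =============  ==============  ===========

The knee scale is signed: positive angles are varus (O-leg), negative
valgus (X-leg). The printed bands tie at exactly -3 deg (both the medium
and the heavy X band include it as written); the tie is resolved to the
severer grade, and rubric validation accepts exactly this double-inclusive
boundary pattern.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import RubricError

GRADES = ("light", "medium", "heavy")
_SEVERITY = {g: i for i, g in enumerate(GRADES)}

INDEX_NAMES = (
    "uneven_shoulders",
    "lateral_pelvic_tilt",
    "knee_alignment",
    "forward_head",
    "pelvic_tilt",
    "scoliosis",
    "scapula_inclination",
)

INDEX_UNITS = {name: "deg" for name in INDEX_NAMES} | {"forward_head": "cm"}


@dataclass(frozen=True)
class Band:
    """One grading interval. ``lo``/``hi`` may be +-inf; inclusivity explicit."""

    lo: float
    hi: float
    grade: str
    tag: str | None = None
    lo_incl: bool = True
    hi_incl: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lo or (self.lo_incl and value == self.lo)
        below = value < self.hi or (self.hi_incl and value == self.hi)
        return above and below


@dataclass(frozen=True)
class GradingRubric:
    """Per-index ordered bands plus a version string recorded in reports."""

    bands: dict[str, tuple[Band, ...]]
    version: str = "default"

    def __post_init__(self):
        for index, bands in self.bands.items():
            _validate_bands(index, bands)

    def grade(self, index_name: str, value: float) -> tuple[str, str | None]:
        """Grade ``value`` for ``index_name``; returns (grade, tag).

        Where the printed bands overlap at a breakpoint (the knee -3 deg
        tie), the severer grade wins.
        """
        if index_name not in self.bands:
            raise RubricError(f"unknown index {index_name!r}")
        if not math.isfinite(value):
            raise RubricError(f"non-finite value for {index_name}: {value}")
        hits = [b for b in self.bands[index_name] if b.contains(value)]
        if not hits:
            lo = min(b.lo for b in self.bands[index_name])
            raise RubricError(
                f"value {value} outside admissible range for {index_name} "
                f"(starts at {lo})"
            )
        best = max(hits, key=lambda b: _SEVERITY[b.grade])
        return best.grade, best.tag


def _validate_bands(index: str, bands: tuple[Band, ...]) -> None:
    if not bands:
        raise RubricError(f"{index}: no bands defined")
    for b in bands:
        if b.grade not in GRADES:
            raise RubricError(f"{index}: unknown grade {b.grade!r}")
        if not b.lo < b.hi:
            raise RubricError(f"{index}: empty band [{b.lo}, {b.hi}]")
    ordered = sorted(bands, key=lambda b: (b.lo, b.hi))
    for a, b in zip(ordered, ordered[1:]):
        if a.hi < b.lo:
            raise RubricError(
                f"{index}: gap between bands at ({a.hi}, {b.lo})"
            )
        if a.hi > b.lo:
            raise RubricError(
                f"{index}: overlapping bands near {b.lo}"
            )
        # a.hi == b.lo: boundary must belong to at least one side. Double
        # inclusion (the documented knee tie) is allowed and resolved
        # severer-wins at grading time.
        if not (a.hi_incl or b.lo_incl):
            raise RubricError(f"{index}: breakpoint {a.hi} belongs to no band")


def _triad(lo_mid: float, mid_hi: float) -> tuple[Band, ...]:
    return (
        Band(0.0, lo_mid, "light"),
        Band(lo_mid, mid_hi, "medium"),
        Band(mid_hi, math.inf, "heavy"),
    )


def default_rubric() -> GradingRubric:
    """The built-in screening rubric (see module docstring)."""
    bands = {
        "uneven_shoulders": _triad(2.0, 4.0),
        "lateral_pelvic_tilt": _triad(2.0, 4.0),
        "scoliosis": _triad(2.0, 4.0),
        "scapula_inclination": _triad(5.0, 10.0),
        "pelvic_tilt": _triad(15.0, 25.0),
        "forward_head": _triad(2.5, 5.0),
        "knee_alignment": (
            # -3 is included by both its bands as printed; heavy wins.
            Band(-math.inf, -3.0, "heavy", "X", lo_incl=False, hi_incl=True),
            Band(-3.0, -1.0, "medium", "X", lo_incl=True),
            Band(-1.0, 3.0, "light", None),
            Band(3.0, 5.0, "medium", "O"),
            Band(5.0, math.inf, "heavy", "O"),
        ),
    }
    return GradingRubric(bands=bands, version="table-default-1")


_DEFAULT = None


def grade(
    index_name: str, value: float, rubric: GradingRubric | None = None
) -> tuple[str, str | None]:
    """Grade with an explicit rubric, or the cached default."""
    global _DEFAULT
    if rubric is None:
        if _DEFAULT is None:
            _DEFAULT = default_rubric()
        rubric = _DEFAULT
    return rubric.grade(index_name, value)


def _band_from_dict(d: dict) -> Band:
    def _num(v, default):
        if v is None:
            return default
        if isinstance(v, str):
            s = v.strip().lower()
            if s in ("inf", "+inf", "infinity"):
                return math.inf
            if s == "-inf":
                return -math.inf
            return float(s)
        return float(v)

    return Band(
        lo=_num(d.get("min"), -math.inf),
        hi=_num(d.get("max"), math.inf),
        grade=d["grade"],
        tag=d.get("tag"),
        lo_incl=bool(d.get("min_inclusive", True)),
        hi_incl=bool(d.get("max_inclusive", False)),
    )


def load_rubric(path: str | Path) -> GradingRubric:
    """Load a rubric from a JSON config file.

    Schema::

        {"version": "...",
         "indexes": {"uneven_shoulders": {"bands": [
             {"min": 0, "max": 2, "grade": "light"}, ...]}, ...}}

    Omitted min/max mean -inf/+inf; min is inclusive and max exclusive
    unless ``min_inclusive``/``max_inclusive`` say otherwise. Validation
    rejects gapped or overlapping bands (double-inclusive shared
    breakpoints excepted, resolved severer-wins).
    """
    with open(path) as fh:
        raw = json.load(fh)
    try:
        indexes = raw["indexes"]
    except (TypeError, KeyError) as exc:
        raise RubricError("rubric config must contain an 'indexes' object") from exc
    bands: dict[str, tuple[Band, ...]] = {}
    for index, cfg in indexes.items():
        if index not in INDEX_NAMES:
            raise RubricError(f"unknown index in rubric config: {index!r}")
        try:
            band_list = tuple(_band_from_dict(b) for b in cfg["bands"])
        except (KeyError, TypeError, ValueError) as exc:
            raise RubricError(f"malformed bands for index {index!r}: {exc}") from exc
        bands[index] = band_list
    missing = [n for n in INDEX_NAMES if n not in bands]
    if missing:
        raise RubricError(f"rubric config missing indexes: {', '.join(missing)}")
    return GradingRubric(bands=bands, version=str(raw.get("version", "custom")))


def save_rubric(rubric: GradingRubric, path: str | Path) -> None:
    """Write a rubric back out in the load_rubric JSON schema."""

    def _num(v):
        if v == math.inf:
            return "inf"
        if v == -math.inf:
            return "-inf"
        return v

    payload = {
        "version": rubric.version,
        "indexes": {
            index: {
                "bands": [
                    {
                        "min": _num(b.lo),
                        "max": _num(b.hi),
                        "grade": b.grade,
                        "tag": b.tag,
                        "min_inclusive": b.lo_incl,
                        "max_inclusive": b.hi_incl,
                    }
                    for b in bands
                ]
            }
            for index, bands in rubric.bands.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__ = [
    "Band",
    "GradingRubric",
    "GRADES",
    "INDEX_NAMES",
    "INDEX_UNITS",
    "default_rubric",
    "grade",
    "load_rubric",
    "save_rubric",
]
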