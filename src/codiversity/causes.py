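"""Cause-classification schemes and ICD-10 code mapping.

A :class:`CauseScheme` fixes the list of mutually exclusive cause groups
(the ``k`` categories over which diversity is measured) and, optionally,
the inclusive ICD-10 three-character code ranges that define each group.
The bundled default groups deaths into 18 ICD-10-chapter-based categories:
four communicable, twelve noncommunicable, external causes, and the
ill-defined chapter (R00-R99) whose share flags certification quality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "CauseScheme",
    "SchemeError",
    "UnclassifiableCodeError",
    "default_scheme",
    "generic_scheme",
    "map_icd_to_scheme",
    "read_scheme",
    "write_scheme",
]

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\..*)?$")
_RANGE_RE = re.compile(r"^([A-Z]\d{2})\s*[-–]\s*([A-Z]\d{2})$")


class SchemeError(ValueError):
    """Invalid cause scheme (duplicate labels, overlapping ranges, ...)."""


class UnclassifiableCodeError(KeyError):
    """An ICD-10 code that falls outside every range of the scheme."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unclassifiable code: {self.code!r} is outside every range of the scheme"


def _code_key(code: str) -> tuple[str, int]:
    """Sort key of a three-character ICD-10 code: (letter, number).

    Fourth and later characters (sub-codes after the decimal) are ignored:
    a sub-code inherits the mapping of its three-character parent.
    """
    m = _CODE_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(
            f"invalid ICD-10 code {code!r}: expected letter + two digits (e.g. 'I21')"
        )
    return m.group(1), int(m.group(2))


def _parse_range(text: str) -> tuple[tuple[str, int], tuple[str, int]]:
    m = _RANGE_RE.match(text.strip().upper())
    if m is None:
        raise ValueError(f"invalid ICD-10 range {text!r}: expected e.g. 'A00-B99'")
    lo, hi = _code_key(m.group(1)), _code_key(m.group(2))
    if hi < lo:
        raise ValueError(f"invalid ICD-10 range {text!r}: end precedes start")
    return lo, hi


@dataclass(frozen=True)
class CauseScheme:
    """An ordered set of k >= 2 cause labels, optionally with ICD-10 ranges.

    Parameters
    ----------
    labels
        Ordered, unique cause-group names.
    icd_ranges
        Mapping from label to one or more inclusive ICD-10 ranges such as
        ``"A00-B99"``. May be empty for label-only schemes (e.g. synthetic
        causes), in which case :func:`map_icd_to_scheme` is unavailable.
    ill_defined_label
        The label that carries ICD-10 chapter R00-R99, used by the
        data-quality flag. ``None`` if the scheme has no such group.
    """

    labels: tuple[str, ...]
    icd_ranges: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    ill_defined_label: str | None = None

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise SchemeError("a cause scheme needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise SchemeError("cause labels must be unique")
        ranges = {lab: tuple(r) for lab, r in dict(self.icd_ranges).items()}
        object.__setattr__(self, "icd_ranges", ranges)
        unknown = set(ranges) - set(labels)
        if unknown:
            raise SchemeError(f"icd_ranges refer to unknown labels: {sorted(unknown)}")
        if self.ill_defined_label is not None and self.ill_defined_label not in labels:
            raise SchemeError(
                f"ill_defined_label {self.ill_defined_label!r} not among labels"
            )
        # parse once, check pairwise disjointness
        parsed: list[tuple[tuple[str, int], tuple[str, int], str]] = []
        for lab in labels:
            for rng in ranges.get(lab, ()):
                lo, hi = _parse_range(rng)
                parsed.append((lo, hi, lab))
        parsed.sort()
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(parsed, parsed[1:]):
            if lo2 <= hi1:
                raise SchemeError(
                    f"overlapping ICD ranges between {l1!r} and {l2!r}"
                )
        object.__setattr__(self, "_parsed_ranges", tuple(parsed))

    @property
    def k(self) -> int:
        """Number of cause groups."""
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def map_icd_to_scheme(code: str, scheme: CauseScheme) -> str:
    """Return the scheme label whose ICD-10 range contains *code*.

    The code's optional decimal sub-classification is ignored; e.g. both
    ``"I21"`` and ``"I21.4"`` map wherever ``I21`` does.

    Raises
    ------
    UnclassifiableCodeError
        If no range of the scheme contains the code.
    """
    key = _code_key(code)
    for lo, hi, label in scheme._parsed_ranges:  # type: ignore[attr-defined]
        if lo <= key <= hi:
            return label
    raise UnclassifiableCodeError(code)


def _parse_scheme_lines(lines: Iterable[str], name: str = "<scheme>") -> CauseScheme:
    labels: list[str] = []
    ranges: dict[str, tuple[str, ...]] = {}
    for ln, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise SchemeError(f"{name}:{ln}: expected 'label: range, range'")
        label, rhs = (part.strip() for part in line.split(":", 1))
        if not label:
            raise SchemeError(f"{name}:{ln}: empty label")
        labels.append(label)
        if rhs:
            ranges[label] = tuple(r.strip() for r in rhs.split(",") if r.strip())
    ill = next(
        (
            lab
            for lab, rs in ranges.items()
            if any(r.replace(" ", "").upper().startswith("R00") for r in rs)
        ),
        None,
    )
    return CauseScheme(tuple(labels), ranges, ill_defined_label=ill)


def read_scheme(path) -> CauseScheme:
    """Read a cause scheme from the plain-text key-value format."""
    with open(path, encoding="utf-8") as fh:
        return _parse_scheme_lines(fh, name=str(path))


def write_scheme(scheme: CauseScheme, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab in scheme.labels:
            rs = scheme.icd_ranges.get(lab, ())
            fh.write(f"{lab}: {', '.join(rs)}\n" if rs else f"{lab}:\n")


def default_scheme() -> CauseScheme:
    """The bundled 18-group ICD-10-chapter scheme."""
    text = resources.files("codiversity.data").joinpath("icd10_18groups.txt").read_text(
        encoding="utf-8"
    )
    scheme = _parse_scheme_lines(text.splitlines(), name="icd10_18groups.txt")
    assert scheme.k == 18
    return scheme


def generic_scheme(k: int, prefix: str = "cause") -> CauseScheme:
    """A label-only scheme with k anonymous causes, for simulated data."""
    return CauseScheme(tuple(f"{prefix}_{i + 1}" for i in range(k)))
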