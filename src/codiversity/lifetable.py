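"""Abridged period life tables and the life-table cause-of-death distribution.

Diversity indices computed from observed death counts confound the cause
mix with the age structure of the population. The standardization used
here instead takes the deaths column of a period life table (driven only
by age-specific mortality rates) and partitions it across causes with the
observed age-specific cause fractions — a multiple-decrement split. The
resulting cause-of-death distribution is free of the population's age
pyramid, so populations with different age structures become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causes import CauseScheme
from .data_model import CauseDistribution, ValidationError

__all__ = [
    "AgeSchedule",
    "LifeTable",
    "RADIX",
    "build_life_table",
    "cause_of_death_distribution",
    "default_age_groups",
    "read_rates",
    "write_life_table",
]

RADIX = 100_000.0


def default_age_groups() -> list[tuple[int, int | None]]:
    """WHO-style abridged ages: 0, 1-4, 5-9, ..., 80-84, 85+ (open)."""
    groups: list[tuple[int, int | None]] = [(0, 1), (1, 4)]
    groups += [(a, 5) for a in range(5, 85, 5)]
    groups.append((85, None))
    return groups


@dataclass(frozen=True)
class AgeSchedule:
    """Age-specific inputs: mortality rates and observed deaths by cause.

    ``age_groups`` is an ordered list of (start, width) intervals, the last
    open-ended (width ``None``). ``m`` holds age-specific mortality rates in
    deaths per person-year. ``cause_counts`` is an optional (age x cause)
    matrix of observed deaths used to split life-table deaths across causes.
    """

    age_groups: tuple[tuple[float, float | None], ...]
    m: np.ndarray
    cause_counts: np.ndarray | None = None
    cause_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        groups = tuple((float(s), None if w is None else float(w)) for s, w in self.age_groups)
        object.__setattr__(self, "age_groups", groups)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "m", m)
        if m.shape != (len(groups),):
            raise ValidationError("m must have one rate per age group")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValidationError("mortality rates must be finite and non-negative")
        if groups[0][0] != 0:
            raise ValidationError("age groups must start at age 0")
        for (s, w), (s2, _) in zip(groups, groups[1:]):
            if w is None or s + w != s2:
                raise ValidationError("age groups must be contiguous; only the last open")
        if groups[-1][1] is not None:
            raise ValidationError("last age group must be open-ended (width None)")
        if self.cause_counts is not None:
            cc = np.asarray(self.cause_counts, dtype=float)
            object.__setattr__(self, "cause_counts", cc)
            if cc.ndim != 2 or cc.shape[0] != len(groups):
                raise ValidationError("cause_counts must be (n_ages, n_causes)")
            if np.any(cc < 0):
                raise ValidationError("cause counts must be non-negative")

    @property
    def n_ages(self) -> int:
        return len(self.age_groups)


@dataclass(frozen=True)
class LifeTable:
    """Columns of an abridged life table at radix 100 000.

    q: probability of dying in the interval; l: survivors at its start;
    d: life-table deaths in it; a: mean person-years lived in the interval
    by those dying in it (open interval: expectation 1/m, unused by the
    cause split).
    """

    age_groups: tuple[tuple[float, float | None], ...]
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.l) > 0):
            raise ValidationError("survivorship l must be non-increasing")
        if abs(self.d.sum() - self.l[0]) > 1e-6:
            raise ValidationError("life-table deaths must exhaust the radix")
        if np.any((self.q < 0) | (self.q > 1)) or self.q[-1] != 1.0:
            raise ValidationError("q must lie in [0,1] with q=1 in the open interval")


def _default_a(age_groups) -> np.ndarray:
    """Mean years lived in interval by decedents: 0.3 for the infant
    interval, half the width otherwise (standard demographic defaults)."""
    a = np.empty(len(age_groups))
    for i, (start, width) in enumerate(age_groups):
        if width is None:
            a[i] = np.nan  # set from 1/m later; d=l in the open interval
        elif start == 0 and width == 1:
            a[i] = 0.3
        else:
            a[i] = width / 2.0
    return a


def build_life_table(sched: AgeSchedule, a: np.ndarray | None = None) -> LifeTable:
    """Construct the abridged life table for an age schedule of rates.

    For a closed interval of width n, q = n*m / (1 + (n - a)*m); the open
    interval has q = 1 and absorbs all remaining survivors.
    """
    groups = sched.age_groups
    m = sched.m
    if a is None:
        a = _default_a(groups)
    else:
        a = np.asarray(a, dtype=float)
    q = np.empty(len(groups))
    for i, (start, width) in enumerate(groups):
        if width is None:
            q[i] = 1.0
        else:
            q[i] = width * m[i] / (1.0 + (width - a[i]) * m[i])
    q = np.clip(q, 0.0, 1.0)
    l = np.empty(len(groups))
    l[0] = RADIX
    for i in range(len(groups) - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    a_out = a.copy()
    if m[-1] > 0:
        a_out[-1] = 1.0 / m[-1]
    return LifeTable(groups, q=q, l=l, d=d, a=a_out)


def cause_of_death_distribution(
    lt: LifeTable, sched: AgeSchedule, scheme: CauseScheme
) -> CauseDistribution:
    """Age-standardized cause shares via the multiple-decrement split.

    Life-table deaths d_x at each age are partitioned across causes in
    proportion to the observed age-specific cause counts; the shares are
    the cause totals over the radix. ``n`` of the result is the observed
    death count behind the cause fractions (the quantity that drives
    sampling uncertainty), not the life-table radix.
    """
    if sched.cause_counts is None:
        raise ValidationError("age schedule carries no cause counts")
    cc = sched.cause_counts
    if cc.shape[0] != len(lt.age_groups):
        raise ValidationError("cause_counts rows must align with life-table ages")
    if cc.shape[1] != scheme.k:
        raise ValidationError("cause_counts columns must match the scheme")
    row_tot = cc.sum(axis=1)
    bad = (lt.d > 0) & (row_tot == 0)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"cannot partition: life-table deaths at age index {idx} "
            "but zero observed deaths of any cause"
        )
    frac = np.zeros_like(cc)
    nz = row_tot > 0
    frac[nz] = cc[nz] / row_tot[nz, None]
    p = lt.d @ frac / RADIX
    return CauseDistribution(scheme, p, n=float(cc.sum()))


def read_rates(path, sep: str = ",") -> pd.DataFrame:
    """Read age-specific mortality rates: columns group,year,sex,age_group,mx."""
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    required = {"group", "year", "sex", "age_group", "mx"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def write_life_table(lt: LifeTable, path, sep: str = ",") -> None:
    labels = [
        f"{int(s)}" if w == 1 else (f"{int(s)}+" if w is None else f"{int(s)}-{int(s + w - 1)}")
        for s, w in lt.age_groups
    ]
    pd.DataFrame({"age": labels, "q": lt.q, "l": lt.l, "d": lt.d, "a": lt.a}).to_csv(
        path, sep=sep, index=False
    )
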