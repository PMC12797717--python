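"""Core data containers: cause-share distributions, grouped mortality,
and long-format deaths tables with validation and missing-year imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .causes import CauseScheme

__all__ = [
    "CauseDistribution",
    "GroupedMortality",
    "DeathsTable",
    "ValidationError",
    "build_grouped",
    "impute_missing_years",
    "quality_flag",
    "read_deaths_table",
    "write_deaths_table",
]

_SUM_TOL = 1e-9

DEATHS_COLUMNS = ("group", "year", "sex", "age_group", "cause", "deaths")


class ValidationError(ValueError):
    """Input violates a structural invariant (shares, weights, keys...)."""


@dataclass(frozen=True)
class CauseDistribution:
    """A vector of cause shares p_c over one scheme, summing to 1.

    ``n`` is the number of deaths behind the shares; it is optional and only
    required for statistical inference (where it sets the binomial standard
    deviation of each share). After linear-interpolation imputation ``n``
    may be non-integer.
    """

    scheme: CauseScheme
    shares: np.ndarray
    n: float | None = None
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        shares = np.asarray(self.shares, dtype=float)
        object.__setattr__(self, "shares", shares)
        if not self._validate:
            return
        if shares.ndim != 1 or shares.shape[0] != self.scheme.k:
            raise ValidationError(
                f"expected {self.scheme.k} shares, got shape {shares.shape}"
            )
        if np.any(shares < 0) or np.any(shares > 1) or not np.all(np.isfinite(shares)):
            raise ValidationError("shares must lie in [0, 1]")
        if abs(shares.sum() - 1.0) > _SUM_TOL:
            raise ValidationError(f"shares sum to {shares.sum():.12f}, not 1")
        if self.n is not None and not self.n > 0:
            raise ValidationError("n must be positive when given")

    @property
    def k(self) -> int:
        return self.scheme.k

    def share_of(self, label: str) -> float:
        return float(self.shares[self.scheme.index(label)])


@dataclass(frozen=True)
class GroupedMortality:
    """Per-group death-share weights and cause distributions on one scheme.

    ``weights[g]`` is the share of group g among all deaths in the pooled
    population; ``distributions[g]`` its cause-share vector.
    """

    scheme: CauseScheme
    group_labels: tuple[str, ...]
    weights: np.ndarray
    distributions: tuple[CauseDistribution, ...]
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "distributions", tuple(self.distributions))
        if not self._validate:
            return
        G = len(self.group_labels)
        if G < 1:
            raise ValidationError("need at least one group")
        if len(set(self.group_labels)) != G:
            raise ValidationError("group labels must be unique")
        if weights.shape != (G,) or len(self.distributions) != G:
            raise ValidationError("weights/distributions length mismatch")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > _SUM_TOL:
            raise ValidationError("weights must be non-negative and sum to 1")
        for d in self.distributions:
            if d.scheme.labels != self.scheme.labels:
                raise ValidationError("all distributions must share the scheme")

    @property
    def G(self) -> int:
        return len(self.group_labels)

    def share_matrix(self) -> np.ndarray:
        """(G, k) matrix of cause shares, rows in group order."""
        return np.vstack([d.shares for d in self.distributions])

    def group(self, label: str) -> CauseDistribution:
        return self.distributions[self.group_labels.index(label)]


@dataclass(frozen=True)
class DeathsTable:
    """Long-format deaths counts keyed by (group, year, sex, age_group, cause)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in DEATHS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(DEATHS_COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["deaths"] = df["deaths"].astype(float)
        if (df["deaths"] < 0).any():
            raise ValidationError("death counts must be non-negative")
        keys = ["group", "year", "sex", "age_group", "cause"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys)].iloc[0]
            raise ValidationError(
                "duplicate record key: "
                + ", ".join(str(dup[k]) for k in keys)
            )
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def subset(self, **conditions) -> "DeathsTable":
        """Rows matching every column=value condition (e.g. sex="f", year=2000)."""
        df = self.frame
        for col, val in conditions.items():
            df = df[df[col] == val]
        return DeathsTable(df.reset_index(drop=True))


def read_deaths_table(path, sep: str | None = None) -> DeathsTable:
    """Read a deaths table from delimited text (comma default, tab accepted)."""
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return DeathsTable(pd.read_csv(path, sep=sep, encoding="utf-8"))


def write_deaths_table(table: DeathsTable, path, sep: str = ",") -> None:
    table.frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def build_grouped(
    table: DeathsTable,
    scheme: CauseScheme,
    weight_source: str = "observed_deaths",
    supplied_weights: Sequence[float] | None = None,
) -> GroupedMortality:
    """Aggregate a deaths table into per-group cause shares and weights.

    Counts are summed over year, sex and age group. With
    ``weight_source="observed_deaths"`` each group's weight is its share of
    the grand total of deaths; with ``"supplied"`` the caller provides the
    weight vector (in the sorted group-label order) and only the cause
    shares come from the table.
    """
    df = table.frame
    unknown = set(df["cause"].unique()) - set(scheme.labels)
    if unknown:
        raise ValidationError(f"causes not in scheme: {sorted(unknown)}")
    pivot = (
        df.groupby(["group", "cause"], sort=True)["deaths"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=list(scheme.labels), fill_value=0.0)
    )
    totals = pivot.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValidationError(f"empty group (zero total deaths): {empty.index[0]!r}")
    group_labels = tuple(pivot.index)
    if weight_source == "observed_deaths":
        weights = (totals / totals.sum()).to_numpy()
    elif weight_source == "supplied":
        if supplied_weights is None:
            raise ValidationError("weight_source='supplied' requires supplied_weights")
        weights = np.asarray(supplied_weights, dtype=float)
        if weights.shape != (len(group_labels),):
            raise ValidationError("supplied_weights length mismatch")
    else:
        raise ValidationError(f"unknown weight_source {weight_source!r}")
    dists = tuple(
        CauseDistribution(scheme, row / tot, n=float(tot))
        for row, tot in zip(pivot.to_numpy(), totals.to_numpy())
    )
    return GroupedMortality(scheme, group_labels, weights, dists)


def impute_missing_years(
    table: DeathsTable, group: str, missing_years: Sequence[int]
) -> DeathsTable:
    """Fill interior missing years for one group by linear interpolation.

    Within each (sex, age_group, cause) stratum the count at a missing year
    is interpolated linearly between the nearest observed flanking years;
    a stratum absent in an observed year contributes a zero there. Records
    of observed years are passed through untouched. Years outside the
    observed range are refused — interpolation only, no extrapolation.
    """
    df = table.frame
    gdf = df[df["group"] == group]
    if gdf.empty:
        raise ValidationError(f"no records for group {group!r}")
    observed = np.array(sorted(gdf["year"].unique()))
    new_rows = []
    for year in missing_years:
        if year in observed:
            raise ValidationError(f"year {year} already observed for {group!r}")
        if year < observed[0] or year > observed[-1]:
            raise ValidationError(
                f"cannot extrapolate: year {year} outside observed range "
                f"{observed[0]}-{observed[-1]} for {group!r}"
            )
        lo = observed[observed < year].max()
        hi = observed[observed > year].min()
        frac = (year - lo) / (hi - lo)
        strata = (
            gdf[gdf["year"].isin([lo, hi])]
            .pivot_table(
                index=["sex", "age_group", "cause"],
                columns="year",
                values="deaths",
                fill_value=0.0,
                aggfunc="sum",
            )
            .reindex(columns=[lo, hi], fill_value=0.0)
        )
        for (sex, age_group, cause), row in strata.iterrows():
            count = row[lo] + frac * (row[hi] - row[lo])
            new_rows.append(
                dict(
                    group=group,
                    year=year,
                    sex=sex,
                    age_group=age_group,
                    cause=cause,
                    deaths=count,
                )
            )
    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return DeathsTable(out)


def quality_flag(dist: CauseDistribution, threshold: float = 0.20) -> bool:
    """True iff the ill-defined share strictly exceeds *threshold*.

    A high share of ICD-10 chapter R00-R99 marks low-quality cause-of-death
    certification; the conventional cutoff is 20%, applied strictly (a
    share of exactly 0.20 is not flagged).
    """
    label = dist.scheme.ill_defined_label
    if label is None:
        raise ValidationError("scheme has no ill-defined label")
    return dist.share_of(label) > threshold
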