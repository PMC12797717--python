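"""Simpson cause-of-death diversity and its multi-group decompositions.

The Simpson index of diversity S of a cause-share vector p is the
probability that two randomly chosen deaths are attributable to different
causes,

    S = 1 - sum_c p_c^2,

ranging from 0 (all deaths from one cause) to (k-1)/k (deaths spread
evenly over k causes). When the population is partitioned into G groups
with death-share weights pi_g and cause shares p_{c,g}, S of the pooled
population splits exactly into a within-group and a between-group part:

    S = S_W + S_B,
    S_W = sum_g pi_g^2 S_g,
    S_B = sum_g sum_{h != g} pi_g pi_h S_gh,

where S_g is the Simpson index inside group g and
S_gh = 1 - sum_c p_{c,g} p_{c,h} is the probability that one random death
from g and one from h differ in cause. The between sum runs over ordered
pairs (equivalently, twice the sum over unordered pairs) — the unique
convention under which the decomposition, the group contributions and the
quadratic form pi' M pi all return the same S.

Further decompositions attribute S to causes (C_c = p_c (1 - p_c)), to
groups, and to cause-group cells; each family sums back to S exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CauseDistribution, GroupedMortality, ValidationError

__all__ = [
    "DiversityDecomposition",
    "DiversityMatrix",
    "ContributionTable",
    "InternalConsistencyError",
    "simpson",
    "pair_diversity",
    "pooled_distribution",
    "within_between",
    "diversity_matrix",
    "quadratic_form",
    "cause_contributions",
    "group_contributions",
    "joint_contributions",
    "contribution_table",
    "contribution_correlation",
]

#: relative tolerance at which the exact algebraic identities are enforced
IDENTITY_RTOL = 1e-12


class InternalConsistencyError(ArithmeticError):
    """An exact decomposition identity failed beyond numerical tolerance."""


def _check_identity(lhs: float, rhs: float, what: str) -> None:
    tol = IDENTITY_RTOL * max(1.0, abs(lhs), abs(rhs))
    if abs(lhs - rhs) > tol:
        raise InternalConsistencyError(
            f"{what}: {lhs!r} != {rhs!r} (|diff| = {abs(lhs - rhs):.3e})"
        )


@dataclass(frozen=True)
class DiversityDecomposition:
    """Total diversity S with its within (S_W) and between (S_B) parts."""

    S: float
    S_W: float
    S_B: float

    def __post_init__(self):
        _check_identity(self.S, self.S_W + self.S_B, "S = S_W + S_B")
        if self.S_W < 0 or self.S_B < 0:
            raise InternalConsistencyError("components must be non-negative")

    @property
    def between_share(self) -> float:
        """Fraction of overall diversity attributable to group differences."""
        return self.S_B / self.S if self.S > 0 else 0.0

    @property
    def within_share(self) -> float:
        return self.S_W / self.S if self.S > 0 else 0.0


@dataclass(frozen=True)
class DiversityMatrix:
    """Symmetric G x G matrix: group diversities S_g on the diagonal,
    pairwise diversities S_gh off it."""

    group_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        G = len(self.group_labels)
        if values.shape != (G, G):
            raise ValidationError(f"expected a {G}x{G} matrix, got {values.shape}")
        if not np.allclose(values, values.T, rtol=0, atol=IDENTITY_RTOL):
            raise InternalConsistencyError("diversity matrix must be symmetric")
        if np.any(values < -IDENTITY_RTOL) or np.any(values > 1 + IDENTITY_RTOL):
            raise ValidationError("diversity values must lie in [0, 1]")

    @property
    def G(self) -> int:
        return len(self.group_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_labels, columns=self.group_labels)

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="group")


@dataclass(frozen=True)
class ContributionTable:
    """Cause, group, and joint cause-x-group contributions to S.

    ``by_cause`` refers to the pooled population's cause shares; ``joint``
    is a (k x G) matrix whose column sums reproduce ``by_group`` and whose
    grand total is S.
    """

    cause_labels: tuple[str, ...]
    group_labels: tuple[str, ...]
    S: float
    by_cause: np.ndarray
    by_group: np.ndarray
    joint: np.ndarray

    def __post_init__(self):
        _check_identity(float(self.by_cause.sum()), self.S, "sum_c C_c = S")
        _check_identity(float(self.by_group.sum()), self.S, "sum_g C_g = S")
        col = self.joint.sum(axis=0)
        for g, (a, b) in enumerate(zip(col, self.by_group)):
            _check_identity(float(a), float(b), f"sum_c C_cg = C_g (group {g})")

    def cause_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contribution": self.by_cause, "share_of_S": self.by_cause / self.S},
            index=pd.Index(self.cause_labels, name="cause"),
        )

    def group_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contribution": self.by_group, "share_of_S": self.by_group / self.S},
            index=pd.Index(self.group_labels, name="group"),
        )

    def joint_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.joint,
            index=pd.Index(self.cause_labels, name="cause"),
            columns=self.group_labels,
        )


def simpson(dist: CauseDistribution | np.ndarray) -> float:
    """Simpson index of diversity, 1 - sum_c p_c^2."""
    p = dist.shares if isinstance(dist, CauseDistribution) else np.asarray(dist, float)
    return float(1.0 - p @ p)


def pair_diversity(a: CauseDistribution, b: CauseDistribution) -> float:
    """Probability that one random death from each of two groups differ in cause."""
    if a.scheme.labels != b.scheme.labels:
        raise ValidationError("distributions use different cause schemes")
    return float(1.0 - a.shares @ b.shares)


def pooled_distribution(gm: GroupedMortality) -> CauseDistribution:
    """The pi-weighted mixture of the group distributions."""
    p = gm.weights @ gm.share_matrix()
    n = None
    ns = [d.n for d in gm.distributions]
    if all(v is not None for v in ns):
        n = float(sum(ns))
    return CauseDistribution(gm.scheme, p / p.sum(), n=n)


def diversity_matrix(gm: GroupedMortality) -> DiversityMatrix:
    """The matrix with S_g on the diagonal and S_gh off it."""
    P = gm.share_matrix()
    M = 1.0 - P @ P.T
    M = (M + M.T) / 2.0  # exact symmetry despite float non-associativity
    return DiversityMatrix(gm.group_labels, M)


def quadratic_form(weights: np.ndarray, M: DiversityMatrix) -> float:
    """Overall diversity as the quadratic form pi' M pi."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (M.G,):
        raise ValidationError(f"weights length {w.shape} does not match G={M.G}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must sum to 1")
    return float(w @ M.values @ w)


def within_between(gm: GroupedMortality) -> DiversityDecomposition:
    """Split pooled diversity into within- and between-group components.

    The result is cross-checked against the Simpson index of the pooled
    distribution; a discrepancy beyond 1e-12 raises
    :class:`InternalConsistencyError`.
    """
    M = diversity_matrix(gm).values
    w = gm.weights
    S_W = float(w**2 @ np.diag(M))
    outer = np.outer(w, w) * M
    S_B = float(outer.sum() - (w**2 * np.diag(M)).sum())
    S = S_W + S_B
    _check_identity(S, simpson(pooled_distribution(gm)), "S (decomposed) = S (pooled)")
    return DiversityDecomposition(S=S, S_W=S_W, S_B=S_B)


def cause_contributions(dist: CauseDistribution) -> np.ndarray:
    """Absolute contribution of each cause: C_c = p_c (1 - p_c)."""
    p = dist.shares
    return p * (1.0 - p)


def group_contributions(gm: GroupedMortality) -> np.ndarray:
    """Contribution of each group: C_g = pi_g^2 S_g + pi_g sum_{h!=g} pi_h S_gh."""
    M = diversity_matrix(gm).values
    w = gm.weights
    diag = np.diag(M)
    cross = M @ w - diag * w  # sum_{h != g} pi_h S_gh
    return w**2 * diag + w * cross


def joint_contributions(gm: GroupedMortality) -> np.ndarray:
    """(k x G) contributions of each cause-group cell.

    C_{c,g} = pi_g^2 p_{c,g}(1 - p_{c,g})
            + pi_g (1 - p_{c,g}) sum_{h != g} pi_h p_{c,h}.
    Column sums reproduce the group contributions.
    """
    P = gm.share_matrix()  # (G, k)
    w = gm.weights
    pooled = w @ P  # sum over all h of pi_h p_{c,h}
    others = pooled[None, :] - w[:, None] * P  # exclude h = g
    cells = (w[:, None] ** 2) * P * (1.0 - P) + w[:, None] * (1.0 - P) * others
    return cells.T


def contribution_table(gm: GroupedMortality) -> ContributionTable:
    """All three contribution decompositions, with their sum identities enforced."""
    pooled = pooled_distribution(gm)
    S = simpson(pooled)
    return ContributionTable(
        cause_labels=gm.scheme.labels,
        group_labels=gm.group_labels,
        S=S,
        by_cause=cause_contributions(pooled),
        by_group=group_contributions(gm),
        joint=joint_contributions(gm),
    )


def contribution_correlation(x, y) -> float:
    """Pearson correlation between two aligned vectors (e.g. group diversity
    levels S_g against group contributions C_g)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need two aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: a vector has zero variance")
    return float(stats.pearsonr(x, y).statistic)
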