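"""Monte-Carlo confidence intervals for diversity statistics.

Sampling model: the death count of cause c is Binomial(n, p_c), so the
estimated share has standard deviation sqrt(p_c (1 - p_c) / n). Every
group's share vector is re-drawn independently per replication and the
statistic of interest recomputed; confidence intervals are empirical
percentiles of the replicate distribution (they may be asymmetric around
the plug-in point estimate).

Two resamplers implement the model. The default, ``multinomial``, draws
the k counts jointly; its binomial margins are exactly the model above
and it reproduces the negative cross-cause covariances of share
estimates, which matters for a statistic like the Simpson index that
aggregates across causes. The alternative, ``truncnorm``, applies the
large-n normal approximation per cause — each share drawn from a normal
with the binomial standard deviation, truncated to [0, 1], the vector
then renormalized to sum to one. The truncated-normal route ignores the
cross-cause covariances, and the renormalization shrinks the replicate
spread of the index a few percent, so its intervals run slightly
anticonservative; it is kept for comparability with the per-cause
normal-approximation description of the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .data_model import CauseDistribution, GroupedMortality, ValidationError
from . import diversity as _div

__all__ = [
    "MonteCarloSpec",
    "IntervalEstimate",
    "STATISTICS",
    "sample_shares",
    "sample_shares_matrix",
    "mc_interval",
    "difference_significant",
]

logger = logging.getLogger(__name__)

#: named statistics of a GroupedMortality usable with mc_interval
STATISTICS: dict[str, Callable[[GroupedMortality], float]] = {
    "simpson": lambda gm: _div.simpson(_div.pooled_distribution(gm)),
    "within": lambda gm: _div.within_between(gm).S_W,
    "between": lambda gm: _div.within_between(gm).S_B,
}


@dataclass(frozen=True)
class MonteCarloSpec:
    """Replication count, significance level and seed of one MC run."""

    replications: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.replications < 2:
            raise ValidationError("need at least 2 replications")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie strictly between 0 and 1")


@dataclass(frozen=True)
class IntervalEstimate:
    """Plug-in point estimate with percentile bounds and the raw draws."""

    point: float
    lower: float
    upper: float
    replications: int
    alpha: float
    draws: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _draw_share_matrix(
    p: np.ndarray, n: float, size: int, rng: np.random.Generator, sampler: str
) -> np.ndarray:
    """(size, k) matrix of replicated share vectors for one group."""
    if sampler == "truncnorm":
        sd = np.sqrt(p * (1.0 - p) / n)
        out = np.tile(p, (size, 1))
        free = sd > 0  # degenerate shares (0 or 1) have no sampling noise
        if free.any():
            pf, sf = p[free], sd[free]
            a = (0.0 - pf) / sf
            b = (1.0 - pf) / sf
            out[:, free] = stats.truncnorm.rvs(
                a, b, loc=pf, scale=sf, size=(size, free.sum()), random_state=rng
            )
        out /= out.sum(axis=1, keepdims=True)
        return out
    if sampler == "multinomial":
        counts = rng.multinomial(int(round(n)), p / p.sum(), size=size)
        return counts / counts.sum(axis=1, keepdims=True)
    raise ValidationError(f"unknown sampler {sampler!r}")


def sample_shares(
    dist: CauseDistribution,
    rng: np.random.Generator | int | None = None,
    sampler: str = "multinomial",
) -> np.ndarray:
    """One perturbed share vector under the binomial sampling model."""
    return sample_shares_matrix(dist, 1, rng, sampler)[0]


def sample_shares_matrix(
    dist: CauseDistribution,
    size: int,
    rng: np.random.Generator | int | None = None,
    sampler: str = "multinomial",
) -> np.ndarray:
    """(size, k) replicated share vectors for one distribution."""
    if dist.n is None:
        raise ValidationError("no sample size for inference: distribution lacks n")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _draw_share_matrix(dist.shares, dist.n, size, rng, sampler)


def mc_interval(
    gm: GroupedMortality,
    statistic: str | Callable[[GroupedMortality], float],
    spec: MonteCarloSpec = MonteCarloSpec(),
    sampler: str = "multinomial",
) -> IntervalEstimate:
    """Percentile confidence interval of a statistic of grouped mortality.

    Every group's share vector is re-drawn independently in each
    replication (weights stay fixed) and the statistic recomputed. A
    replication where the statistic raises is discarded with a warning;
    more than 1% discarded is an error.
    """
    fn = STATISTICS[statistic] if isinstance(statistic, str) else statistic
    for d in gm.distributions:
        if d.n is None:
            raise ValidationError("no sample size for inference: a group lacks n")
    rng = np.random.default_rng(spec.seed)
    R = spec.replications
    # one vectorized draw per group, in group order, for reproducibility
    drawn = [
        _draw_share_matrix(d.shares, d.n, R, rng, sampler) for d in gm.distributions
    ]
    values = np.empty(R)
    failed = 0
    for r in range(R):
        dists = tuple(
            CauseDistribution(gm.scheme, drawn[g][r], n=gm.distributions[g].n,
                              _validate=False)
            for g in range(gm.G)
        )
        rep = GroupedMortality(gm.scheme, gm.group_labels, gm.weights, dists,
                               _validate=False)
        try:
            values[r] = fn(rep)
        except Exception as exc:  # noqa: BLE001 - replication-level robustness
            failed += 1
            values[r] = np.nan
            logger.warning("replication %d discarded: %s", r, exc)
    if failed > 0.01 * R:
        raise ValidationError(
            f"{failed}/{R} replications failed; statistic unstable on resamples"
        )
    good = values[~np.isnan(values)]
    lo, hi = np.percentile(good, [100 * spec.alpha / 2, 100 * (1 - spec.alpha / 2)])
    return IntervalEstimate(
        point=fn(gm),
        lower=float(lo),
        upper=float(hi),
        replications=len(good),
        alpha=spec.alpha,
        draws=good,
    )


def difference_significant(
    a: IntervalEstimate, b: IntervalEstimate, alpha: float = 0.05
) -> bool:
    """True iff the percentile interval of paired draw differences excludes 0.

    The two estimates must come from runs with equal replication counts
    (ideally a common seed, so shared sampling noise cancels).
    """
    if a.replications != b.replications or len(a.draws) != len(b.draws):
        raise ValidationError("draw counts differ; cannot pair replications")
    diff = a.draws - b.draws
    lo, hi = np.percentile(diff, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return bool(lo > 0 or hi < 0)
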