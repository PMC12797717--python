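"""Synthetic grouped cause-of-death data with controlled structure.

Group cause-share vectors are drawn from Dirichlet distributions whose
concentration parameters span the realistic range of mortality profiles:
large symmetric concentrations give near-uniform, highly diverse
profiles; small or asymmetric ones give profiles dominated by a few
causes. Death counts are multinomial given the shares, and group weights
come from the realized death totals, mirroring how real registry data
would be ingested. Named presets construct the polar cases used
throughout testing:

``identical``
    every group carries exactly the same share vector (between-group
    pairwise diversity equals within-group diversity);
``disjoint``
    group g loads entirely on cause g (every pairwise diversity is 1);
``polarized``
    half the groups concentrate on a chronic-cause block, half spread
    across communicable, external and chronic causes — the contrast
    between late- and early/mixed-transition mortality profiles;
``uniformish``
    near-uniform profiles close to the diversity maximum;
``mortality_like``
    realistic chronic-dominated national profiles drawn around
    :data:`MORTALITY_PROFILE`, with Simpson indices near 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .causes import CauseScheme, default_scheme, generic_scheme
from .data_model import (
    CauseDistribution,
    DeathsTable,
    GroupedMortality,
    ValidationError,
)
from .lifetable import AgeSchedule, default_age_groups

__all__ = [
    "ScenarioSpec",
    "PRESETS",
    "MORTALITY_PROFILE",
    "generate_grouped",
    "generate_age_cause_panel",
]

#: named concentration presets (documented parameter values)
PRESETS = {
    "identical": "one Dirichlet(5) draw shared by every group",
    "disjoint": "group g loads only on cause g (mod k)",
    "polarized": "half: Dirichlet(8) on a 4-cause chronic block; "
    "half: Dirichlet(2) over chronic + communicable + external",
    "uniformish": "Dirichlet(50) per group: near-uniform, high diversity",
    "mortality_like": "Dirichlet(60 x MORTALITY_PROFILE): realistic "
    "chronic-dominated national profiles, Simpson index ~0.8",
}

#: a typical chronic-dominated national cause-share profile on the default
#: 18-group scheme (cardiovascular-led, substantial neoplasms/respiratory/
#: external shares, small communicable block) — group Simpson index ~0.84,
#: well away from the degenerate uniform maximum (k-1)/k.
MORTALITY_PROFILE = np.array(
    [
        0.060,  # infectious
        0.005,  # maternal
        0.020,  # perinatal
        0.010,  # congenital
        0.170,  # neoplasms
        0.005,  # blood
        0.050,  # endocrine
        0.010,  # mental
        0.030,  # neurological
        0.001,  # eye_ear
        0.300,  # cardiovascular
        0.090,  # respiratory
        0.050,  # digestive
        0.002,  # skin
        0.005,  # musculoskeletal
        0.020,  # genitourinary
        0.080,  # external
        0.050,  # ill_defined
    ]
)
MORTALITY_PROFILE = MORTALITY_PROFILE / MORTALITY_PROFILE.sum()


@dataclass(frozen=True)
class ScenarioSpec:
    """Controls for one synthetic grouped-mortality scenario.

    ``concentration`` is either a positive scalar/vector of Dirichlet
    parameters applied per group, or one of the :data:`PRESETS` names.
    ``n_per_group`` is a single death count or one per group. With
    ``count_noise=False`` the drawn share vectors are kept exactly instead
    of being replaced by realized multinomial count fractions — useful
    when a scenario must serve as noise-free ground truth.
    """

    G: int
    k: int = 18
    weights: str | Sequence[float] = "equal"
    concentration: float | Sequence[float] | str = 1.0
    n_per_group: int | Sequence[int] = 10_000
    seed: int | None = None
    count_noise: bool = True

    def __post_init__(self):
        if self.G < 1:
            raise ValidationError("G must be >= 1")
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if not isinstance(self.concentration, str):
            conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
            if np.any(conc <= 0):
                raise ValidationError("concentration parameters must be > 0")
        elif self.concentration not in PRESETS:
            raise ValidationError(
                f"unknown preset {self.concentration!r}; choose from {sorted(PRESETS)}"
            )
        n = np.atleast_1d(np.asarray(self.n_per_group, dtype=int))
        if np.any(n < 1):
            raise ValidationError("n_per_group must be positive")

    def _ns(self) -> np.ndarray:
        n = np.atleast_1d(np.asarray(self.n_per_group, dtype=int))
        return np.full(self.G, n[0]) if n.size == 1 else n


def _scheme_for(spec: ScenarioSpec) -> CauseScheme:
    return default_scheme() if spec.k == 18 else generic_scheme(spec.k)


def _preset_shares(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    G, k = spec.G, spec.k
    if spec.concentration == "identical":
        p = rng.dirichlet(np.full(k, 5.0))
        return np.tile(p, (G, 1))
    if spec.concentration == "disjoint":
        if G > k:
            raise ValidationError("disjoint preset needs G <= k")
        P = np.zeros((G, k))
        P[np.arange(G), np.arange(G) % k] = 1.0
        return P
    if spec.concentration == "uniformish":
        return rng.dirichlet(np.full(k, 50.0), size=G)
    if spec.concentration == "mortality_like":
        if k != 18:
            raise ValidationError("mortality_like preset requires k = 18")
        return rng.dirichlet(60.0 * MORTALITY_PROFILE, size=G)
    if spec.concentration == "polarized":
        # chronic block: first 4 causes; broad block: all causes
        chronic = np.full(k, 1e-3)
        chronic[: min(4, k)] = 8.0
        broad = np.full(k, 2.0)
        half = G // 2 + G % 2
        P = np.empty((G, k))
        P[:half] = rng.dirichlet(chronic, size=half)
        P[half:] = rng.dirichlet(broad, size=G - half)
        return P
    raise ValidationError(f"unknown preset {spec.concentration!r}")


def generate_grouped(spec: ScenarioSpec) -> GroupedMortality:
    """Draw one grouped-mortality scenario, reproducible from the seed.

    For Dirichlet concentrations the realized counts are multinomial and
    the shares are the observed count fractions; the exact presets
    (``identical``, ``disjoint``) keep their shares noise-free so the
    algebraic relations they exist to exercise hold exactly.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = _scheme_for(spec)
    ns = spec._ns()
    exact = not spec.count_noise or (
        isinstance(spec.concentration, str)
        and spec.concentration in ("identical", "disjoint")
    )
    if isinstance(spec.concentration, str):
        P = _preset_shares(spec, rng)
    else:
        conc = np.atleast_1d(np.asarray(spec.concentration, dtype=float))
        alpha = np.full(spec.k, conc[0]) if conc.size == 1 else conc
        if alpha.shape != (spec.k,):
            raise ValidationError("concentration vector length must equal k")
        P = rng.dirichlet(alpha, size=spec.G)
    if not exact:
        counts = np.vstack([rng.multinomial(n, p) for n, p in zip(ns, P)])
        # multinomial draws can zero out a group only if n is tiny; guard anyway
        P = counts / counts.sum(axis=1, keepdims=True)
    labels = tuple(f"group_{i + 1}" for i in range(spec.G))
    dists = tuple(
        CauseDistribution(scheme, p, n=float(n)) for p, n in zip(P, ns)
    )
    if isinstance(spec.weights, str) and spec.weights == "equal":
        w = np.full(spec.G, 1.0 / spec.G)
    elif isinstance(spec.weights, str) and spec.weights == "observed_deaths":
        w = ns / ns.sum()
    else:
        w = np.asarray(spec.weights, dtype=float)
        w = w / w.sum()
    return GroupedMortality(scheme, labels, w, dists)


def _gompertz_rates(n_ages: int, rng: np.random.Generator) -> np.ndarray:
    """Plausible abridged-age mortality schedule: high infant rate, a dip
    in childhood, then roughly exponential (Gompertz-like) rise."""
    base = 0.002 * np.exp(0.35 * np.arange(n_ages))
    base[0] = 0.02
    base[1] = 0.001
    jitter = rng.lognormal(mean=0.0, sigma=0.1, size=n_ages)
    return np.clip(base * jitter, 1e-5, 1.0)


def generate_age_cause_panel(
    spec: ScenarioSpec,
    year: int = 2000,
    sex: str = "all",
    deaths_scale: int = 5_000,
    constant_fractions: bool = True,
) -> tuple[dict[str, AgeSchedule], DeathsTable]:
    """Age-structured panel exercising the life-table pipeline end to end.

    Each group receives an age schedule of mortality rates and an
    (age x cause) matrix of observed death counts. With
    ``constant_fractions=True`` (default) the age-specific cause fractions
    inside a group are identical at every age and equal to the group's
    target share vector — so the life-table cause-of-death distribution
    reproduces that vector exactly, whatever the age pattern of deaths.
    The observed deaths per age follow an arbitrary age pyramid drawn per
    group, which is exactly the nuisance the standardization removes.
    """
    rng = np.random.default_rng(spec.seed)
    target = generate_grouped(spec)
    age_groups = tuple(default_age_groups())
    n_ages = len(age_groups)
    schedules: dict[str, AgeSchedule] = {}
    rows = []
    for g, label in enumerate(target.group_labels):
        m = _gompertz_rates(n_ages, rng)
        pyramid = rng.dirichlet(np.full(n_ages, 2.0))
        age_totals = np.maximum(1.0, np.round(deaths_scale * pyramid))
        p = target.distributions[g].shares
        if constant_fractions:
            cc = np.outer(age_totals, p)
        else:
            cc = np.vstack(
                [rng.multinomial(int(t), p) for t in age_totals]
            ).astype(float)
        schedules[label] = AgeSchedule(
            age_groups, m, cause_counts=cc, cause_labels=target.scheme.labels
        )
        for i, (start, width) in enumerate(age_groups):
            age_lab = f"{int(start)}+" if width is None else f"{int(start)}-{int(start + width - 1)}"
            for c, cause in enumerate(target.scheme.labels):
                if cc[i, c] > 0:
                    rows.append(
                        dict(group=label, year=year, sex=sex, age_group=age_lab,
                             cause=cause, deaths=cc[i, c])
                    )
    return schedules, DeathsTable(pd.DataFrame(rows))
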