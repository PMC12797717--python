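# Methods

## The index and its decompositions

The Simpson index of diversity of a cause-of-death distribution with
shares `p_c` over `k` mutually exclusive causes is `S = 1 − Σ_c p_c²`,
the probability that two independently drawn deaths have different
causes. Its range is `[0, (k−1)/k]`; with the default 18-cause scheme
the maximum is 17/18 ≈ 0.9444.

For a population partitioned into `G` groups with death-share weights
`π_g` (Σ π_g = 1) and cause shares `p_{c,g}`, the pooled index splits as

    S = S_W + S_B,
    S_W = Σ_g π_g² S_g,
    S_B = Σ_g Σ_{h≠g} π_g π_h S_gh,
    S_gh = 1 − Σ_c p_{c,g} p_{c,h}.

The between sum runs over **ordered** pairs `(g, h), h ≠ g` —
equivalently twice the sum over unordered pairs. This is the unique
convention under which three independent routes to `S` coincide
exactly: the Simpson index of the π-weighted pooled distribution, the
within/between split, and the quadratic form `πᵀMπ` with `M` the
symmetric matrix holding `S_g` on the diagonal and `S_gh` off it. The
pairwise term `S_gh` is the probability that one random death from `g`
and one from `h` differ in cause; the closed form above follows from
that definition and is what makes the quadratic-form identity hold.

Contribution decompositions:

* by cause: `C_c = p_c (1 − p_c)`, with `Σ_c C_c = S`;
* by group: `C̃_g = π_g² S_g + π_g Σ_{h≠g} π_h S_gh`, with `Σ_g C̃_g = S`;
* jointly: `C̃_{c,g} = π_g² p_{c,g}(1−p_{c,g}) + π_g(1−p_{c,g}) Σ_{h≠g} π_h p_{c,h}`,
  whose column sums reproduce `C̃_g` and whose grand total is `S`.

All identities are enforced at a relative tolerance of `1e-12`;
violations raise `InternalConsistencyError` rather than warn, because a
violation can only mean an implementation defect, never data noise.

## Temporal change

Writing `S_t = f(π_t, M_t) = π_tᵀ M_t π_t`, the change between two
periods is decomposed with the symmetric two-factor (Kitagawa) scheme:

    Δ_π = [ (f(π₂,M₂) − f(π₁,M₂)) + (f(π₂,M₁) − f(π₁,M₁)) ] / 2
    Δ_S = [ (f(π₂,M₂) − f(π₂,M₁)) + (f(π₁,M₂) − f(π₁,M₁)) ] / 2

so that `Δ_π + Δ_S = S₂ − S₁` exactly and swapping the periods negates
every component. Both counterfactual orderings are averaged; a
one-sided substitution would not be antisymmetric. The two states must
describe the same groups in the same order: groups entering or leaving
the panel are rejected rather than zero-padded, because zero-padding
silently renormalizes the weights of the remaining groups.

## Life-table standardization

Computed directly from observed death counts, cause shares confound the
cause mix with the population's age structure. The package therefore
derives shares from a period life table: an abridged table is built
from age-specific mortality rates (`q = n·m / (1 + (n − a)·m)` for a
closed interval of width `n`; the open interval has `q = 1`), and its
deaths column `d_x` is partitioned across causes in proportion to the
observed age-specific cause counts (a multiple-decrement split). The
resulting distribution `p_c = Σ_x d_{x,c} / radix` depends only on the
rate schedule and the age-specific cause **fractions**, not on the age
pyramid of the observed deaths — two populations differing only in that
pyramid get identical shares, which is the point of the construction.

Conventions: abridged ages 0, 1–4, 5–9, …, 80–84, 85+ by default
(configurable); mean person-years lived by decedents `a₀ = 0.3` in the
infant interval and half the width elsewhere, standard demographic
defaults. Sexes are processed independently end to end. The `n` stored
with a standardized distribution is the observed death count behind the
cause fractions, not the life-table radix — it is the quantity that
drives sampling uncertainty.

## Cause scheme and data handling

The bundled scheme groups ICD-10 three-character codes into 18 causes
by chapter: infectious (A00–B99), maternal (O00–O99), perinatal
(P00–P96), congenital (Q00–Q99); neoplasms (C00–D48), blood (D50–D89),
endocrine (E00–E90), mental (F00–F99), neurological (G00–G99), eye/ear
(H00–H95), cardiovascular (I00–I99), respiratory (J00–J99), digestive
(K00–K93), skin (L00–L99), musculoskeletal (M00–M99), genitourinary
(N00–N99); external (S00–T98, V01–Y98); ill-defined (R00–R99). Ranges
are compared lexicographically on (letter, two-digit number); sub-codes
after the decimal inherit the three-character mapping; codes outside
every range raise a named error rather than falling into a catch-all.
An ill-defined share strictly above 20% flags low certification
quality (`quality_flag`); the cutoff is strict — exactly 20% is not
flagged.

Interior missing years in a deaths table are filled by linear
interpolation per (sex, age group, cause) stratum between the nearest
observed flanking years; a stratum absent in a flanking year counts as
zero there. Years outside the observed range are refused —
interpolation only, never extrapolation. Interpolated counts are kept
as non-integers; rounding would break the share identities downstream.

Group weights default to observed death shares (`π_g` = group deaths /
total deaths); a supplied weight vector is accepted as an alternative
for standardized-weight analyses.

## Statistical inference

The death count of cause `c` is modelled as `Binomial(n, p_c)`, giving
each share the standard deviation `sqrt(p_c(1−p_c)/n)`. Confidence
intervals are Monte-Carlo: every group's share vector is re-drawn
independently per replication (1000 by default), the statistic is
recomputed, and the empirical 2.5/97.5 percentiles are reported with
the plug-in point estimate. Percentile intervals are used because the
sampling distributions of diversity statistics are visibly asymmetric
at realistic death counts; the interval may exclude the plug-in point
in skewed cases. Identical seeds give bit-identical intervals.

Two resamplers are provided:

* **multinomial** (default): counts drawn jointly as
  `Multinomial(n, p)`. Its margins are exactly the binomial model and
  it reproduces the negative cross-cause covariances of share
  estimates. In nested-simulation checks at n = 10 000 per group the
  95% intervals for `S` cover the truth at 94–96% under realistic
  concentrated profiles.
* **truncnorm**: each share drawn independently from a normal with the
  binomial standard deviation truncated to [0, 1], the vector then
  renormalized to sum to one. This per-cause normal approximation
  ignores the cross-cause covariances, and the renormalization shrinks
  the replicate spread of the index by a few percent; measured coverage
  runs 1–3 points anticonservative. It is kept as an explicit flag for
  comparability with per-cause normal treatments, not as the default.

Shares that are exactly 0 or 1 carry no binomial noise and stay fixed
across replications; consequently the intervals do not account for
causes observed zero times, a boundary limitation shared by any plug-in
resampling scheme. Significance of a difference between two estimates
is judged by whether the percentile interval of paired replicate
differences excludes zero; runs must share a replication count (and
should share a seed so common sampling noise cancels).

Known limitation: when the pooled distribution approaches the uniform
maximum `(k−1)/k`, the gradient of `S` degenerates and the sampling
distribution of the plug-in index becomes strongly skewed; no
resampling interval is well calibrated in that regime. Realistic
national profiles (S ≈ 0.7–0.88) are far from it.

## Synthetic data

The generator draws group cause-share vectors from Dirichlet
distributions and realizes death counts multinomially, so generated
tables carry exactly the sampling noise the inference model assumes.
Presets cover the structural poles used in testing — `identical`
(between-group pairwise diversity equals within diversity), `disjoint`
(all pairwise diversities 1), `polarized` (a concentrated chronic-cause
block against spread mixed-transition profiles), `uniformish` (near the
diversity maximum) — plus `mortality_like`, a realistic
chronic-dominated profile (Dirichlet concentration 60 × a
cardiovascular-led base profile; group Simpson indices ≈ 0.8). Exact
presets (`identical`, `disjoint`) skip count noise so the algebraic
relations they exercise hold exactly; `count_noise=False` extends that
to any scenario that must serve as noise-free ground truth. The
age-structured panel generator holds age-specific cause fractions
constant within each group, so the life-table pipeline must reproduce
each group's target shares exactly whatever age pyramid the observed
deaths follow.

What the generator does *not* emulate: temporal autocorrelation of
cause shares, correlated profiles between neighbouring groups,
registration-coverage artefacts, and cause-classification error.
Passing tests therefore demonstrate the algebra, the standardization
and the calibration of the intervals under the stated sampling model —
not robustness to miscoded or incomplete registry data.

## Problem sizes used in the checks

The identity suite runs 1000 random grouped populations (G ≤ 25,
k = 18). The sampling oracle uses 10⁶ paired draws. The
interval-calibration check uses 3 groups of 10 000 deaths, 500 outer
replications and 1000 inner replications, conditions under which a
percentile interval's coverage can be measured to about one percentage
point.
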