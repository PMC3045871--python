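"""The two intervention models: antihypertensive medication and health promotion.

High-risk strategy (medication)
    Individuals above an initiation threshold ``e`` who consult a physician
    (probability s(x) = 1 - exp(-(x - a) b), the consultation rate) have
    their SBP lowered by g(x) = (x - c) * d, of which a ``contribution``
    fraction (default 50%) is credited toward risk reduction within the
    convergence horizon.  The population incidence after the intervention is

        int_L^e f P dx
        + int_e^H f P(x - g(x) * contribution) s(x) dx
        + int_e^H f P (1 - s(x)) dx.

Population strategy (health promotion)
    A campaign succeeds for a fraction beta of the whole population, shifting
    their SBP down by alpha (again only ``contribution`` of the shift is
    credited):

        beta * int f P(x - alpha * contribution) dx + (1 - beta) * int f P dx.

    beta may be aggregated from a stratified campaign table (population
    shares times per-stratum success rates).  Because a constant shift of an
    exponential risk is a pure rescaling by exp(-alpha*contribution/k), the
    post-promotion rate has the closed form
    C * (1 - beta * (1 - exp(-alpha*contribution/k))) with C the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DEFAULT_GRID,
    ConfigurationError,
    IntegrationGrid,
    RiskModel,
    SBPDistribution,
    cumulative_ir_closed_form,
)
from .core import _quadrature  # shared quadrature dispatch

__all__ = [
    "MedicationPolicy",
    "PromotionPolicy",
    "SuccessRateTable",
    "consultation_rate",
    "consultation_probability_density",
    "sbp_lowering_effect",
    "treated_individual_ir",
    "promoted_individual_ir",
    "post_medication_ir",
    "post_promotion_ir",
    "post_promotion_ir_closed_form",
    "aggregate_success_rate",
]


@dataclass(frozen=True)
class MedicationPolicy:
    """High-risk intervention: physician consultation plus SBP lowering.

    Parameters
    ----------
    alarm : float
        Alarming SBP ``a`` (mm Hg) above which individuals become concerned;
        the consultation rate is zero at and below it.
    access : float
        Accessibility factor ``b`` (per mm Hg) of the consultation rate.
    target : float
        Target SBP ``c`` (mm Hg) of the antihypertensive treatment.
    adherence : float
        Fraction ``d`` in [0, 1] of the gap to target actually closed
        (physician guideline compliance times patient drug adherence).
    initiation : float
        SBP threshold ``e`` (mm Hg) at and above which medication starts.
    contribution : float
        Fraction of the achieved SBP decrease credited to risk reduction
        within the convergence horizon; default 0.5.
    label : str
        Scenario label used in tables and figures.
    """

    alarm: float = 140.0
    access: float = 0.03
    target: float = 140.0
    adherence: float = 0.7
    initiation: float = 150.0
    contribution: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not self.access > 0:
            raise ConfigurationError(f"b (access) must be > 0 (got {self.access})")
        if not 0.0 <= self.adherence <= 1.0:
            raise ConfigurationError(
                f"d (adherence) must be in [0, 1] (got {self.adherence})"
            )
        if not 0.0 < self.contribution <= 1.0:
            raise ConfigurationError(
                f"contribution must be in (0, 1] (got {self.contribution})"
            )
        if self.initiation < self.target:
            raise ConfigurationError(
                f"initiation e={self.initiation} must be >= target c={self.target}"
            )

    def with_initiation(self, e: float) -> "MedicationPolicy":
        return replace(self, initiation=e)


@dataclass(frozen=True)
class SuccessRateTable:
    """Stratified campaign table whose share-weighted mean is beta.

    ``strata`` is an ordered list of (label, population_share, success_rate)
    with shares summing to 1 and rates in [0, 1]; both stored as fractions
    and displayed as percentages.
    """

    strata: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        total = sum(share for _, share, _ in self.strata)
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"population shares must sum to 1 (got {total})"
            )
        for name, _, rate in self.strata:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"success rate for {name!r} must be in [0, 1] (got {rate})"
                )

    @classmethod
    def campaign(cls, affirmative: float, motivating: float,
                 information: float) -> "SuccessRateTable":
        """The three-support-system campaign with 10/20/50/20 shares.

        Strata: affirmative support (10% of the population), motivating
        support (20%), information only (50%), indifferent (20%, success 0).
        """
        return cls((
            ("affirmative", 0.10, affirmative),
            ("motivating", 0.20, motivating),
            ("information", 0.50, information),
            ("indifferent", 0.20, 0.0),
        ))

    @classmethod
    def realistic(cls) -> "SuccessRateTable":
        return cls.campaign(0.375, 0.25, 0.10)

    @classmethod
    def optimistic(cls) -> "SuccessRateTable":
        return cls.campaign(0.75, 0.50, 0.20)

    @classmethod
    def ideal(cls) -> "SuccessRateTable":
        return cls.campaign(1.0, 0.75, 0.50)


def aggregate_success_rate(table: SuccessRateTable) -> float:
    """Share-weighted overall success rate beta of a stratified campaign."""
    return sum(share * rate for _, share, rate in table.strata)


@dataclass(frozen=True)
class PromotionPolicy:
    """Population intervention: SBP shift alpha achieved by a fraction beta."""

    alpha: float = 10.0
    beta: float = 0.275
    contribution: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0 (got {self.alpha})")
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigurationError(f"beta must be in [0, 1] (got {self.beta})")
        if not 0.0 < self.contribution <= 1.0:
            raise ConfigurationError(
                f"contribution must be in (0, 1] (got {self.contribution})"
            )

    @classmethod
    def from_table(cls, alpha: float, table: SuccessRateTable,
                   contribution: float = 0.5, label: str = "") -> "PromotionPolicy":
        return cls(alpha=alpha, beta=aggregate_success_rate(table),
                   contribution=contribution, label=label)


def consultation_rate(x, policy: MedicationPolicy):
    """Probability of consulting a primary physician at SBP ``x``.

    1 - exp(-(x - a) b), clamped to 0 below the alarming SBP ``a`` where the
    raw expression would be negative.
    """
    x = np.asarray(x, dtype=float)
    out = -np.expm1(-(x - policy.alarm) * policy.access)
    return np.clip(out, 0.0, 1.0)


def consultation_probability_density(x, dist: SBPDistribution,
                                     policy: MedicationPolicy):
    """Density of consulters per mm Hg: f(x) times the consultation rate."""
    return dist.density(x) * consultation_rate(x, policy)


def sbp_lowering_effect(x, policy: MedicationPolicy):
    """Effective risk-credited SBP reduction (mm Hg) under treatment.

    (x - c) * d * contribution for x above the target c, 0 below; the
    treated SBP never falls below the target.
    """
    x = np.asarray(x, dtype=float)
    return np.maximum(x - policy.target, 0.0) * policy.adherence * policy.contribution


def treated_individual_ir(x, risk: RiskModel, policy: MedicationPolicy):
    """Incidence rate of a treated individual at pre-treatment SBP ``x``.

    Only defined at and above the initiation threshold ``e``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < policy.initiation):
        raise ValueError(
            f"treated_individual_ir is defined for SBP >= e={policy.initiation}"
        )
    return risk.risk_at(x - sbp_lowering_effect(x, policy))


def promoted_individual_ir(x, risk: RiskModel, policy: PromotionPolicy):
    """Incidence rate of a successfully promoted individual at SBP ``x``."""
    x = np.asarray(x, dtype=float)
    return risk.risk_at(x - policy.alpha * policy.contribution)


def _medication_post_raw(x, dist: SBPDistribution, risk: RiskModel,
                         policy: MedicationPolicy):
    # treated-branch density, valid at and above the initiation threshold
    f = dist.density(x)
    s = consultation_rate(x, policy)
    treated = risk.risk_at(x - sbp_lowering_effect(x, policy))
    return f * (s * treated + (1.0 - s) * risk.risk_at(x))


def medication_integrands(x, dist: SBPDistribution, risk: RiskModel,
                          policy: MedicationPolicy):
    """Pointwise pre and post expected event-rate densities for medication.

    Below e the two coincide; above e the post density mixes treated
    consulters with untreated non-consulters.  The post density jumps at e;
    a sample landing exactly on e carries the half-sum of the two limits,
    so that trapezoid quadrature of the sampled curve on a grid containing
    e equals the split integral.
    """
    x = np.asarray(x, dtype=float)
    f = dist.density(x)
    pre = f * risk.risk_at(x)
    post_raw = _medication_post_raw(x, dist, risk, policy)
    at_e = np.isclose(x, policy.initiation, rtol=0.0, atol=1e-9)
    post = np.where(x > policy.initiation, post_raw,
                    np.where(at_e, 0.5 * (pre + post_raw), pre))
    return pre, post


def post_medication_ir(
    dist: SBPDistribution,
    risk: RiskModel,
    policy: MedicationPolicy,
    grid: IntegrationGrid = DEFAULT_GRID,
    method: str = "trapezoid",
) -> float:
    """Population incidence rate after the medication intervention.

    Three-term integral: untreated below e, plus consulters treated to a
    lower SBP and non-consulters at their original risk above e.  Always
    <= the baseline; equal when nobody consults (b -> 0) or adherence is 0.
    """
    if not grid.lower <= policy.initiation <= grid.upper:
        raise ConfigurationError(
            f"initiation e={policy.initiation} lies outside the grid "
            f"[{grid.lower}, {grid.upper}]"
        )
    x = grid.points()
    e = policy.initiation
    # split the quadrature at the jump; insert e when it is not a grid node
    i = int(np.searchsorted(x, e))
    aligned = i < len(x) and abs(x[i] - e) < 1e-9
    x_below = x[: i + 1] if aligned else np.append(x[:i], e)
    x_above = x[i:] if aligned else np.insert(x[i:], 0, e)
    f_below = dist.density(x_below) * risk.risk_at(x_below)
    f_above = _medication_post_raw(x_above, dist, risk, policy)
    below = _quadrature(f_below, x_below, method) if len(x_below) > 1 else 0.0
    above = _quadrature(f_above, x_above, method) if len(x_above) > 1 else 0.0
    return below + above


def promotion_integrands(x, dist: SBPDistribution, risk: RiskModel,
                         policy: PromotionPolicy):
    """Pointwise pre and post expected event-rate densities for promotion."""
    x = np.asarray(x, dtype=float)
    f = dist.density(x)
    pre = f * risk.risk_at(x)
    shifted = risk.risk_at(x - policy.alpha * policy.contribution)
    post = policy.beta * f * shifted + (1.0 - policy.beta) * pre
    return pre, post


def post_promotion_ir(
    dist: SBPDistribution,
    risk: RiskModel,
    policy: PromotionPolicy,
    grid: IntegrationGrid = DEFAULT_GRID,
    method: str = "trapezoid",
) -> float:
    """Population incidence rate after the health-promotion intervention.

    Two-term mixture: a successful fraction beta with SBP shifted down by
    alpha * contribution, the rest unchanged.  Equals the baseline when
    alpha = 0 or beta = 0.
    """
    x = grid.points()
    _, post = promotion_integrands(x, dist, risk, policy)
    return _quadrature(post, x, method)


def post_promotion_ir_closed_form(
    dist: SBPDistribution, risk: RiskModel, policy: PromotionPolicy
) -> float:
    """Analytic post-promotion rate: C (1 - beta (1 - exp(-alpha*contrib/k))).

    A constant SBP shift rescales the exponential risk, so the promotion
    mixture has an exact closed form; the quadrature must agree with it to
    high relative accuracy on the default grid.
    """
    c0 = cumulative_ir_closed_form(dist, risk)
    shrink = 1.0 - np.exp(-policy.alpha * policy.contribution / risk.k)
    return c0 * (1.0 - policy.beta * shrink)
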