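"""Scenario grids, incidence reduction, number of health checks, and curves.

The two strategies are compared on two indexes: the reduction in the
cumulative incidence rate, delta_IR = baseline - post, and the number of
annual health checks needed to prevent one cardiovascular event per year,
N_HC = 1 / delta_IR.  The scenario grids sweep the policy parameters the
way the published sensitivity tables do: medication scenarios over
initiation thresholds e (rows) and (a, b, c, d) policy columns for each
risk slope k, promotion scenarios over SBP shifts alpha (columns) and
campaign success levels beta (rows) for each k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_GRID,
    IntegrationGrid,
    RiskModel,
    SBPDistribution,
    cumulative_ir,
)
from .interventions import (
    MedicationPolicy,
    PromotionPolicy,
    medication_integrands,
    post_medication_ir,
    post_promotion_ir,
    promotion_integrands,
)

__all__ = [
    "InterventionOutcome",
    "ScenarioGridResult",
    "StrategyComparison",
    "delta_ir",
    "n_hc",
    "n_hc_rounded",
    "evaluate_medication",
    "evaluate_promotion",
    "run_medication_grid",
    "run_promotion_grid",
    "compare_strategies",
    "pointwise_risk_curves",
    "DEFAULT_MEDICATION_COLUMNS",
    "DEFAULT_E_ROWS",
    "DEFAULT_ALPHAS",
    "DEFAULT_BETAS",
]

Policy = Union[MedicationPolicy, PromotionPolicy]

#: Policy columns of the medication sensitivity grid: (a, b) and (c, d) vary
#: jointly from the most to the least favourable situation.
DEFAULT_MEDICATION_COLUMNS: tuple[MedicationPolicy, ...] = (
    MedicationPolicy(alarm=130, access=0.05, target=130, adherence=0.8,
                     initiation=140, label="a=130 b=0.05 c=130 d=0.8"),
    MedicationPolicy(alarm=140, access=0.03, target=140, adherence=0.7,
                     initiation=150, label="a=140 b=0.03 c=140 d=0.7"),
    MedicationPolicy(alarm=150, access=0.02, target=150, adherence=0.6,
                     initiation=160, label="a=150 b=0.02 c=150 d=0.6"),
    MedicationPolicy(alarm=160, access=0.01, target=160, adherence=0.5,
                     initiation=180, label="a=160 b=0.01 c=160 d=0.5"),
)

DEFAULT_E_ROWS: tuple[float, ...] = (140.0, 150.0, 160.0, 180.0)
DEFAULT_ALPHAS: tuple[float, ...] = (20.0, 10.0, 5.0)
#: Campaign success levels: share-weighted sums of the stratified table.
DEFAULT_BETAS: dict[str, float] = {
    "ideal": 0.50,
    "optimistic": 0.275,
    "realistic": 0.1375,
}


def delta_ir(baseline: float, post: float) -> float:
    """Reduction in cumulative incidence rate (events/year).

    Raises if the intervention raised risk: a valid policy can never have a
    negative reduction under this model.
    """
    if baseline < 0 or post < 0:
        raise ValueError("incidence rates must be non-negative")
    d = baseline - post
    if d < 0:
        raise ValueError(
            f"policy raises risk (baseline {baseline:g} < post {post:g})"
        )
    return d


def n_hc(delta: float) -> float:
    """Annual health checks needed to prevent one event per year: 1/delta.

    Infinite when the reduction is zero (no event is ever prevented).
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0 (got {delta})")
    return math.inf if delta == 0 else 1.0 / delta


def n_hc_rounded(delta: float) -> float:
    """N_HC rounded half-up to an integer for display; inf stays inf."""
    value = n_hc(delta)
    return value if math.isinf(value) else float(math.floor(value + 0.5))


@dataclass(frozen=True)
class InterventionOutcome:
    """Baseline and post-intervention rates for one scenario, plus curves.

    ``curve_x``, ``curve_pre`` and ``curve_post`` sample the expected
    event-rate density f*P before and after the intervention on the grid;
    the quadrature of their gap reproduces ``delta_ir``.
    """

    scenario_id: str
    baseline_ir: float
    post_ir: float
    curve_x: np.ndarray
    curve_pre: np.ndarray
    curve_post: np.ndarray

    @property
    def delta_ir(self) -> float:
        return delta_ir(self.baseline_ir, self.post_ir)

    @property
    def n_hc(self) -> float:
        return n_hc(self.delta_ir)

    @property
    def n_hc_display(self) -> float:
        return n_hc_rounded(self.delta_ir)


def pointwise_risk_curves(
    dist: SBPDistribution,
    risk: RiskModel,
    policy: Policy,
    grid: IntegrationGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled pre/post expected event-rate densities (x, pre, post).

    ``pre`` is f(x) P(x); ``post`` is the integrand of the corresponding
    post-intervention formula, so the grid quadrature of ``pre - post``
    equals the scenario's delta_ir.
    """
    x = grid.points()
    if isinstance(policy, MedicationPolicy):
        pre, post = medication_integrands(x, dist, risk, policy)
    elif isinstance(policy, PromotionPolicy):
        pre, post = promotion_integrands(x, dist, risk, policy)
    else:
        raise TypeError(f"unsupported policy type {type(policy).__name__}")
    return x, pre, post


def _outcome(dist, risk, policy, grid, method, post_fn, scenario_id):
    baseline = cumulative_ir(dist, risk, grid, method)
    post = post_fn(dist, risk, policy, grid, method)
    x, pre, post_curve = pointwise_risk_curves(dist, risk, policy, grid)
    return InterventionOutcome(
        scenario_id=scenario_id, baseline_ir=baseline, post_ir=post,
        curve_x=x, curve_pre=pre, curve_post=post_curve,
    )


def evaluate_medication(
    dist: SBPDistribution,
    risk: RiskModel,
    policy: MedicationPolicy,
    grid: IntegrationGrid = DEFAULT_GRID,
    method: str = "trapezoid",
) -> InterventionOutcome:
    """Full outcome (rates, delta, N_HC, curves) of a medication scenario."""
    sid = policy.label or (
        f"medication a={policy.alarm:g} b={policy.access:g} "
        f"c={policy.target:g} d={policy.adherence:g} e={policy.initiation:g}"
    )
    return _outcome(dist, risk, policy, grid, method, post_medication_ir, sid)


def evaluate_promotion(
    dist: SBPDistribution,
    risk: RiskModel,
    policy: PromotionPolicy,
    grid: IntegrationGrid = DEFAULT_GRID,
    method: str = "trapezoid",
) -> InterventionOutcome:
    """Full outcome of a health-promotion scenario."""
    sid = policy.label or (
        f"promotion alpha={policy.alpha:g} beta={policy.beta:g}"
    )
    return _outcome(dist, risk, policy, grid, method, post_promotion_ir, sid)


@dataclass(frozen=True)
class ScenarioGridResult:
    """delta_IR values on a (k-block, row, column) grid.

    ``frames`` maps each risk slope k to a DataFrame of reductions in
    events/year; blank (intentionally absent) cells are NaN.
    """

    kind: str  # "medication" or "promotion"
    frames: dict[float, pd.DataFrame]

    def cell(self, k: float, row, col) -> float:
        return float(self.frames[k].loc[row, col])


def run_medication_grid(
    dist: SBPDistribution,
    risk_models: Sequence[RiskModel],
    policy_columns: Sequence[MedicationPolicy] = DEFAULT_MEDICATION_COLUMNS,
    e_rows: Sequence[float] = DEFAULT_E_ROWS,
    grid: IntegrationGrid = DEFAULT_GRID,
) -> ScenarioGridResult:
    """delta_IR for every (k, e, policy-column) medication scenario.

    A cell is populated only when the initiation threshold is at least
    10 mm Hg above the column's alarming SBP (the published grid leaves the
    other combinations blank); absent cells are NaN, not zero.
    """
    frames: dict[float, pd.DataFrame] = {}
    labels = [p.label or f"col{i}" for i, p in enumerate(policy_columns)]
    for risk in risk_models:
        baseline = cumulative_ir(dist, risk, grid)
        data = np.full((len(e_rows), len(policy_columns)), np.nan)
        for j, col in enumerate(policy_columns):
            for i, e in enumerate(e_rows):
                if e < col.alarm + 10:
                    continue
                post = post_medication_ir(dist, risk, col.with_initiation(e), grid)
                data[i, j] = delta_ir(baseline, post)
        frames[risk.k] = pd.DataFrame(
            data, index=[f"e={e:g}" for e in e_rows], columns=labels
        )
    return ScenarioGridResult(kind="medication", frames=frames)


def run_promotion_grid(
    dist: SBPDistribution,
    risk_models: Sequence[RiskModel],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    betas: dict[str, float] = DEFAULT_BETAS,
    grid: IntegrationGrid = DEFAULT_GRID,
    contribution: float = 0.5,
) -> ScenarioGridResult:
    """delta_IR for every (k, beta-level, alpha) promotion scenario.

    Rows are exactly proportional to beta because the promotion mixture is
    linear in the success fraction.
    """
    frames: dict[float, pd.DataFrame] = {}
    for risk in risk_models:
        baseline = cumulative_ir(dist, risk, grid)
        data = np.empty((len(betas), len(alphas)))
        for i, beta in enumerate(betas.values()):
            for j, alpha in enumerate(alphas):
                policy = PromotionPolicy(alpha=alpha, beta=beta,
                                         contribution=contribution)
                data[i, j] = delta_ir(
                    baseline, post_promotion_ir(dist, risk, policy, grid)
                )
        frames[risk.k] = pd.DataFrame(
            data,
            index=[f"beta {name}" for name in betas],
            columns=[f"alpha={a:g}" for a in alphas],
        )
    return ScenarioGridResult(kind="promotion", frames=frames)


@dataclass(frozen=True)
class StrategyComparison:
    """Head-to-head comparison of two intervention outcomes."""

    medication: InterventionOutcome
    promotion: InterventionOutcome
    delta_ratio: float  # medication delta / promotion delta
    n_hc_ratio: float  # promotion N_HC / medication N_HC
    winner: str  # "medication", "promotion" or "tie"


def compare_strategies(
    med: InterventionOutcome, promo: InterventionOutcome
) -> StrategyComparison:
    """Compare the two strategies on delta_IR and N_HC.

    Both outcomes must share the same baseline; the strategy with the larger
    reduction wins.
    """
    if not math.isclose(med.baseline_ir, promo.baseline_ir, rel_tol=1e-9):
        raise ValueError(
            "outcomes have different baselines "
            f"({med.baseline_ir:g} vs {promo.baseline_ir:g})"
        )
    dm, dp = med.delta_ir, promo.delta_ir
    if dm <= 0 or dp <= 0:
        raise ValueError("comparison undefined when either delta_IR is <= 0")
    if math.isclose(dm, dp, rel_tol=1e-12):
        winner = "tie"
    else:
        winner = "medication" if dm > dp else "promotion"
    return StrategyComparison(
        medication=med, promotion=promo,
        delta_ratio=dm / dp, n_hc_ratio=dm / dp,
        winner=winner,
    )
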