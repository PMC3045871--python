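"""Figure rendering: risk curves, consultation curves, pre/post comparisons.

Four figures mirror the model's main visual diagnostics: the exponential
risk curve family over k; the consultation rate and the density of
consulters for the three access situations; and the pre/post expected
event-rate densities for the medication and promotion scenarios (the area
between the curves is the incidence reduction).  Rendering is optional and
non-fatal: if the plotting backend is unavailable the run continues with a
warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .interventions import (
    MedicationPolicy,
    PromotionPolicy,
    consultation_probability_density,
    consultation_rate,
)
from .scenarios import pointwise_risk_curves

__all__ = ["render_figures"]

logger = logging.getLogger(__name__)

_LINESTYLES = ["-", "--", ":", "-."]


def render_figures(config: RunConfig, outdir: str | Path,
                   fmt: str = "png") -> list[Path]:
    """Render the four diagnostic figures into ``outdir``.

    Returns the list of written files; an empty list if matplotlib cannot
    provide a backend.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - backend present in practice
        logger.warning("plotting backend unavailable, skipping figures: %s", exc)
        return []

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dist, grid = config.population, config.grid
    x = np.linspace(90, 200, 441)
    written: list[Path] = []

    # 1. SBP -> incidence-rate curve family over k
    fig, ax = plt.subplots(figsize=(6, 4))
    for risk, ls in zip(config.risks, _LINESTYLES):
        ax.plot(x, risk.risk_at(x), ls, label=f"k = {risk.k:g}")
    ax.set_xlabel("SBP (mm Hg)")
    ax.set_ylabel("incidence rate (events/year)")
    ax.set_title("SBP vs cardiovascular event rate")
    ax.legend()
    path = outdir / f"risk_curves.{fmt}"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    # 2. consultation rate and density of consulters
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for policy, ls in zip(config.medication_columns, _LINESTYLES):
        label = f"a={policy.alarm:g}, b={policy.access:g}"
        ax1.plot(x, consultation_rate(x, policy), ls, label=label)
        ax2.plot(x, consultation_probability_density(x, dist, policy), ls,
                 label=label)
    ax1.set_xlabel("SBP (mm Hg)")
    ax1.set_ylabel("consultation rate")
    ax2.set_xlabel("SBP (mm Hg)")
    ax2.set_ylabel("consulters per mm Hg")
    ax1.legend(fontsize=8)
    fig.suptitle("SBP vs primary-physician consultation")
    path = outdir / f"consultation.{fmt}"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    # 3 & 4. pre/post expected event-rate densities
    risk = config.risks[0]
    for stem, policies in (
        ("medication_curves", config.medication_columns[:3]),
        ("promotion_curves", [
            PromotionPolicy(alpha=10.0, beta=beta,
                            contribution=config.promotion_contribution,
                            label=name)
            for name, beta in config.betas.items()
        ]),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        first = True
        for policy, ls in zip(policies, _LINESTYLES[1:]):
            gx, pre, post = pointwise_risk_curves(dist, risk, policy, grid)
            if first:
                ax.plot(gx, pre, "k-", label="no intervention")
                first = False
            label = policy.label or type(policy).__name__
            ax.plot(gx, post, ls, label=label)
        ax.set_xlim(90, 200)
        ax.set_xlabel("SBP (mm Hg)")
        ax.set_ylabel("expected events per year per mm Hg")
        ax.set_title("Event-rate density before/after intervention")
        ax.legend(fontsize=8)
        path = outdir / f"{stem}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    return written
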