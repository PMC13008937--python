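"""Two-step MR mediation: product-of-coefficients decomposition.

The total effect of the exposure on the outcome (α_total) is decomposed
into an indirect path through the mediator, α_mediated = α₁ · α₂ (the
product of the exposure→mediator and mediator→outcome IVW estimates),
and the direct remainder α_direct = α_total − α_mediated.  The mediated
proportion is α_mediated / α_total × 100%.  The SE of the mediated effect
uses the first-order delta method, √(α₁²·se₂² + α₂²·se₁²); the
second-order term se₁²·se₂² can be added by flag.

Each leg is estimated by univariable IVW with instruments re-selected for
its own exposure role (the mediator→outcome leg is not adjusted for the
exposure — a product-of-coefficients, not multivariable-MR, design).
No CI is propagated onto the proportion: ratio intervals are unstable
when α_total is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._pipeline import fit_ivw_leg
from .config import AnalysisConfig
from .errors import EstimationError
from .gwas_data import SummaryStats
from .mr_estimators import MREstimate

__all__ = ["MediationResult", "two_step_mediation", "mediation_pipeline"]

Z95 = 1.96


@dataclass
class MediationResult:
    """The α_total / α₁ / α₂ / α_mediated / α_direct / proportion bundle.

    Invariants (by construction): ``alpha_mediated == alpha_1 * alpha_2``,
    ``alpha_direct + alpha_mediated == alpha_total`` and
    ``proportion_mediated * alpha_total == 100 * alpha_mediated`` (when the
    total effect is nonzero; otherwise the proportion is ``None``).
    """

    alpha_total: float
    alpha_1: float
    alpha_2: float
    alpha_mediated: float
    se_mediated: float
    ci_mediated: tuple[float, float]
    alpha_direct: float
    proportion_mediated: Optional[float]
    total_estimate: Optional[MREstimate] = field(default=None, repr=False)
    step1_estimate: Optional[MREstimate] = field(default=None, repr=False)
    step2_estimate: Optional[MREstimate] = field(default=None, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One-row report of the decomposition."""
        return pd.DataFrame(
            [
                {
                    "alpha_total": self.alpha_total,
                    "alpha_1": self.alpha_1,
                    "alpha_2": self.alpha_2,
                    "alpha_mediated": self.alpha_mediated,
                    "se_mediated": self.se_mediated,
                    "ci_low": self.ci_mediated[0],
                    "ci_high": self.ci_mediated[1],
                    "alpha_direct": self.alpha_direct,
                    "proportion_pct": self.proportion_mediated,
                }
            ]
        )

    def report(self) -> str:
        lines = [
            f"alpha_total     {self.alpha_total:+.4f}",
            f"alpha_1         {self.alpha_1:+.4f}",
            f"alpha_2         {self.alpha_2:+.4f}",
            f"alpha_mediated  {self.alpha_mediated:+.4f} "
            f"(95% CI {self.ci_mediated[0]:+.4f} to {self.ci_mediated[1]:+.4f})",
            f"alpha_direct    {self.alpha_direct:+.4f}",
        ]
        if self.proportion_mediated is None:
            lines.append("proportion_mediated  undefined (alpha_total = 0)")
        else:
            lines.append(f"proportion_mediated  {self.proportion_mediated:.2f}%")
        for leg, n in self.provenance.items():
            lines.append(f"instruments[{leg}]  {n}")
        return "\n".join(lines)


def two_step_mediation(
    total: MREstimate,
    step1: MREstimate,
    step2: MREstimate,
    second_order: bool = False,
) -> MediationResult:
    """Combine three IVW estimates into the mediation decomposition.

    ``total`` is exposure→outcome, ``step1`` exposure→mediator (α₁),
    ``step2`` mediator→outcome (α₂).  With ``second_order`` the delta-method
    variance adds the ``se₁²·se₂²`` term.  A zero total effect leaves the
    proportion undefined (``None``); all other fields are still returned.
    """
    for name, e in (("total", total), ("step1", step1), ("step2", step2)):
        if not (np.isfinite(e.beta) and np.isfinite(e.se)):
            raise EstimationError(f"mediation: non-finite {name} estimate")
    a_t, a1, a2 = total.beta, step1.beta, step2.beta
    mediated = a1 * a2
    var = a1**2 * step2.se**2 + a2**2 * step1.se**2
    if second_order:
        var += step1.se**2 * step2.se**2
    se = float(np.sqrt(var))
    proportion = None if a_t == 0 else 100.0 * mediated / a_t
    return MediationResult(
        alpha_total=a_t,
        alpha_1=a1,
        alpha_2=a2,
        alpha_mediated=mediated,
        se_mediated=se,
        ci_mediated=(mediated - Z95 * se, mediated + Z95 * se),
        alpha_direct=a_t - mediated,
        proportion_mediated=proportion,
        total_estimate=total,
        step1_estimate=step1,
        step2_estimate=step2,
    )


def mediation_pipeline(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    config: Optional[AnalysisConfig] = None,
    second_order: bool = False,
) -> MediationResult:
    """Run all three IVW legs and the two-step decomposition.

    Instruments are re-selected for each leg's exposure role
    (exposure→outcome, exposure→mediator, mediator→outcome).  The
    per-leg instrument counts are recorded in ``result.provenance``.

    Raises :class:`~mrmediation.errors.PipelineError` naming the first leg
    with zero instruments.
    """
    cfg = config or AnalysisConfig()
    total, h_total = fit_ivw_leg(exposure, outcome, cfg, "total (exposure->outcome)")
    step1, h_1 = fit_ivw_leg(exposure, mediator, cfg, "step1 (exposure->mediator)")
    step2, h_2 = fit_ivw_leg(mediator, outcome, cfg, "step2 (mediator->outcome)")
    result = two_step_mediation(total, step1, step2, second_order=second_order)
    result.provenance = {
        "total": h_total.n_snps,
        "step1": h_1.n_snps,
        "step2": h_2.n_snps,
    }
    return result
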