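"""Sensitivity analyses: leave-one-out, reverse MR, direction consistency.

Leave-one-out refits the IVW estimate with each instrument removed in
turn and flags instruments whose removal changes the sign of the estimate
or moves it outside the full fit's 95% CI.  Reverse MR swaps the roles of
disease and trait to screen for reverse causation: a trait is retained
when the disease→trait IVW p-value exceeds 0.05.  Direction consistency
requires all five estimators to agree on the sign (equivalently, all odds
ratios on the same side of 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import (
    HarmonizationError,
    InsufficientInstrumentsError,
    PipelineError,
)
from .gwas_data import SummaryStats
from .instruments import HarmonizedSet, clump, harmonize, select_instruments
from .mr_estimators import FIVE_METHODS, MREstimate, ivw

__all__ = [
    "LOOResult",
    "ReverseMRResult",
    "leave_one_out",
    "reverse_mr",
    "direction_consistency",
]


@dataclass
class LOOResult:
    """Leave-one-out IVW refits keyed by the omitted instrument."""

    full_estimate: MREstimate
    estimates: dict[str, MREstimate]
    flag_influential: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Forest-plot-ready table: dropped rsid, beta, CI, influence flag."""
        rows = [
            {
                "dropped_rsid": rsid,
                "beta": e.beta,
                "ci_low": e.beta - 1.96 * e.se,
                "ci_high": e.beta + 1.96 * e.se,
                "flag_influential": rsid in self.flag_influential,
            }
            for rsid, e in self.estimates.items()
        ]
        return pd.DataFrame(rows)


def leave_one_out(h: HarmonizedSet, model: str = "multiplicative_random") -> LOOResult:
    """One IVW refit per omitted instrument, with influence flags."""
    if h.n_snps < 2:
        raise InsufficientInstrumentsError(
            f"leave-one-out requires at least 2 instruments, got {h.n_snps}"
        )
    full = ivw(h, model=model)
    lo = full.beta - 1.96 * full.se
    hi = full.beta + 1.96 * full.se
    estimates: dict[str, MREstimate] = {}
    flags: list[str] = []
    rsids = h.table["rsid"].tolist()
    for rsid in rsids:
        sub = h.subset(h.table["rsid"] != rsid)
        e = ivw(sub, model=model)
        estimates[rsid] = e
        sign_change = np.sign(e.beta) != np.sign(full.beta)
        outside = not (lo <= e.beta <= hi)
        if sign_change or outside:
            flags.append(rsid)
    return LOOResult(full, estimates, flags)


@dataclass
class ReverseMRResult:
    """Outcome of a reverse-direction MR fit.

    ``status`` is ``"ok"`` when an estimate exists and ``"untestable"``
    when the disease GWAS yields no usable instruments — a distinct result,
    not an error, so the screening layer can apply its declared policy.
    """

    status: str
    estimate: Optional[MREstimate] = None
    n_instruments: int = 0

    @property
    def pval(self) -> Optional[float]:
        return self.estimate.pval if self.estimate is not None else None


def reverse_mr(
    outcome_stats: SummaryStats,
    exposure_stats: SummaryStats,
    p_threshold: float = 1e-5,
    config: Optional[AnalysisConfig] = None,
) -> ReverseMRResult:
    """MR with roles swapped: the disease GWAS instruments the analysis.

    Estimates the causal effect of ``outcome_stats``'s trait on
    ``exposure_stats``'s trait.  The caller retains exposures whose
    reverse p-value exceeds 0.05 (no evidence of reverse causation).
    """
    cfg = (config or AnalysisConfig()).replace(p_threshold=p_threshold)
    selected = select_instruments(outcome_stats, cfg.p_threshold)
    if not selected:
        return ReverseMRResult("untestable")
    kept = clump(outcome_stats, selected, cfg.r2_threshold, cfg.window_kb)
    try:
        h = harmonize(outcome_stats, exposure_stats, kept, cfg.palindrome_eaf_window)
    except HarmonizationError:
        return ReverseMRResult("untestable")
    if h.n_snps == 0:
        return ReverseMRResult("untestable")
    return ReverseMRResult("ok", ivw(h, model=cfg.ivw_model), h.n_snps)


def direction_consistency(estimates: Sequence[MREstimate]) -> bool:
    """True iff all five methods' betas share one strict sign.

    Requires exactly one estimate from each of the five methods; a zero
    beta counts as inconsistent.  Invariant to the order of the list.
    """
    methods = sorted(e.method for e in estimates)
    if methods != sorted(FIVE_METHODS):
        missing = set(FIVE_METHODS) - set(methods)
        raise ValueError(
            f"direction_consistency needs one estimate per method "
            f"{FIVE_METHODS}; missing or duplicated: {missing or set(methods)}"
        )
    betas = np.array([e.beta for e in estimates])
    return bool(np.all(betas > 0) or np.all(betas < 0))
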