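"""End-to-end screening: forward MR over many exposures, reverse-MR filter,
mediator screen with the five-method direction-consistency rule, and the
H-score reporting utility.

The screen mirrors a proteome-wide two-sample MR design: every exposure is
tested against the outcome by IVW (raw p < 0.01 by default, no
multiple-testing correction — the inflation risk is documented and an FDR
flag is available); forward hits are re-tested in the reverse direction
and retained only when the reverse p-value exceeds 0.05; mediator
candidates must associate with the outcome (raw p < 0.05) and show an
exposure→mediator IVW p < 0.05 with all five estimators agreeing in
direction.  Untestable traits (no instruments) are reported, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from statsmodels.stats.multitest import multipletests

from ._pipeline import fit_ivw_leg
from .config import AnalysisConfig
from .errors import PipelineError
from .gwas_data import SummaryStats
from .mediation import MediationResult, mediation_pipeline
from .mr_estimators import MREstimate, all_methods
from .sensitivity import ReverseMRResult, direction_consistency, reverse_mr

__all__ = [
    "ScreenRow",
    "MediatorCandidate",
    "ScreenReport",
    "HScore",
    "screen_exposures",
    "screen_mediators",
    "full_screen",
    "h_score",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenRow:
    """One exposure's audit record in the forward/reverse screen."""

    exposure_id: str
    forward: Optional[MREstimate]
    reverse: Optional[ReverseMRResult]
    passes_forward: bool
    passes_reverse: bool
    classification: Optional[str]  # "risk" (OR>1) | "protective" (OR<1)
    status: str = "ok"  # ok | untestable
    fdr_q: Optional[float] = None

    @property
    def reverse_pval(self):
        if self.reverse is None:
            return None
        return self.reverse.pval if self.reverse.status == "ok" else "untestable"


@dataclass
class MediatorCandidate:
    """One mediator's audit record in the mediator screen."""

    mediator_id: str
    to_outcome: Optional[MREstimate]
    from_exposure: Optional[list[MREstimate]]
    passes_outcome_p: bool
    exposure_ivw_p: Optional[float] = None
    consistent_direction: Optional[bool] = None
    passes: bool = False
    status: str = "ok"


@dataclass
class ScreenReport:
    """Full screen output: exposure rows, mediator audit, top mediation."""

    exposure_rows: list[ScreenRow]
    mediator_rows: list[MediatorCandidate] = field(default_factory=list)
    top_exposure_id: Optional[str] = None
    top_mediator_id: Optional[str] = None
    mediation: Optional[MediationResult] = None


def _classify(estimate: MREstimate) -> Optional[str]:
    if estimate.or_ > 1:
        return "risk"
    if estimate.or_ < 1:
        return "protective"
    return None


def screen_exposures(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    p_forward: float = 0.01,
    config: Optional[AnalysisConfig] = None,
    fdr: bool = False,
) -> list[ScreenRow]:
    """Forward IVW per exposure; reverse MR for the forward hits.

    Returns one row per input exposure (passed, failed or untestable),
    sorted by forward p ascending with untestable rows last.  With
    ``fdr=True`` a Benjamini-Hochberg q-value is attached and the forward
    pass additionally requires q < ``p_forward``.
    """
    cfg = config or AnalysisConfig()
    logger.info(
        "screening %d exposures against %s: p_forward=%g, p_instr=%g",
        len(exposures), outcome.trait_id, p_forward, cfg.p_threshold,
    )
    rows: list[ScreenRow] = []
    for stats in exposures:
        try:
            forward, _ = fit_ivw_leg(stats, outcome, cfg, f"forward {stats.trait_id}")
        except PipelineError as exc:
            logger.info("exposure %s untestable: %s", stats.trait_id, exc)
            rows.append(
                ScreenRow(stats.trait_id, None, None, False, False, None, "untestable")
            )
            continue
        passes_forward = forward.pval < p_forward
        rev = None
        passes_reverse = False
        if passes_forward:
            rev = reverse_mr(outcome, stats, cfg.p_threshold, cfg)
            # untestable reverse MR is treated conservatively: not passed
            passes_reverse = rev.status == "ok" and rev.pval > 0.05
        rows.append(
            ScreenRow(
                stats.trait_id, forward, rev, passes_forward, passes_reverse,
                _classify(forward),
            )
        )
    if fdr:
        testable = [r for r in rows if r.forward is not None]
        if testable:
            q = multipletests(
                [r.forward.pval for r in testable], method="fdr_bh"
            )[1]
            for r, qv in zip(testable, q):
                r.fdr_q = float(qv)
                r.passes_forward = r.passes_forward and qv < p_forward
    rows.sort(
        key=lambda r: (r.forward is None, r.forward.pval if r.forward else 0.0)
    )
    n_pass = sum(r.passes_forward for r in rows)
    logger.info("forward screen: %d/%d exposures pass", n_pass, len(rows))
    return rows


def screen_mediators(
    mediators: Sequence[SummaryStats],
    exposure: SummaryStats,
    outcome: SummaryStats,
    p_mediator: float = 0.05,
    config: Optional[AnalysisConfig] = None,
) -> list[MediatorCandidate]:
    """Two-stage mediator screen, ranked by mediator→outcome p-value.

    Stage 1: mediator→outcome IVW at ``p_mediator``.  Stage 2 (survivors):
    exposure→mediator with all five estimators, requiring IVW p < 0.05 and
    direction consistency.  Candidates passing both stages come first in
    the ranking; every input mediator appears exactly once.
    """
    cfg = config or AnalysisConfig()
    rows: list[MediatorCandidate] = []
    for stats in mediators:
        try:
            to_out, _ = fit_ivw_leg(stats, outcome, cfg, f"mediator {stats.trait_id}")
        except PipelineError:
            rows.append(
                MediatorCandidate(stats.trait_id, None, None, False, status="untestable")
            )
            continue
        cand = MediatorCandidate(
            stats.trait_id, to_out, None, to_out.pval < p_mediator
        )
        if cand.passes_outcome_p:
            try:
                _, h = fit_ivw_leg(exposure, stats, cfg, f"exposure->{stats.trait_id}")
                five = all_methods(h, n_boot=cfg.n_boot, seed=cfg.seed, phi=cfg.phi)
            except PipelineError:
                cand.status = "untestable"
                rows.append(cand)
                continue
            cand.from_exposure = five
            ivw_est = next(e for e in five if e.method == "ivw")
            cand.exposure_ivw_p = ivw_est.pval
            cand.consistent_direction = direction_consistency(five)
            cand.passes = (
                cand.exposure_ivw_p < 0.05 and cand.consistent_direction
            )
        rows.append(cand)
    rows.sort(
        key=lambda c: (
            not c.passes,
            c.to_outcome.pval if c.to_outcome is not None else 1.0,
        )
    )
    if not any(c.passes for c in rows):
        logger.info("mediator screen: no mediator passed both filters")
    return rows


def full_screen(
    exposures: Sequence[SummaryStats],
    mediators: Sequence[SummaryStats],
    outcome: SummaryStats,
    p_forward: float = 0.01,
    p_mediator: float = 0.05,
    config: Optional[AnalysisConfig] = None,
) -> ScreenReport:
    """Forward screen → reverse filter → mediator screen → mediation.

    The top hit is the smallest-forward-p exposure passing both the
    forward and reverse filters, paired with the top-ranked passing
    mediator; the two-step mediation is then estimated for that pair.
    """
    cfg = config or AnalysisConfig()
    rows = screen_exposures(exposures, outcome, p_forward, cfg)
    report = ScreenReport(rows)
    winners = [r for r in rows if r.passes_forward and r.passes_reverse]
    if not winners:
        return report
    top = winners[0]
    report.top_exposure_id = top.exposure_id
    exposure = next(s for s in exposures if s.trait_id == top.exposure_id)
    med_rows = screen_mediators(mediators, exposure, outcome, p_mediator, cfg)
    report.mediator_rows = med_rows
    passing = [c for c in med_rows if c.passes]
    if not passing:
        return report
    report.top_mediator_id = passing[0].mediator_id
    mediator = next(s for s in mediators if s.trait_id == report.top_mediator_id)
    report.mediation = mediation_pipeline(exposure, mediator, outcome, cfg)
    return report


@dataclass
class HScore:
    """Semi-quantitative immunostaining score on the 0-300 scale."""

    pct_weak: float
    pct_moderate: float
    pct_strong: float
    score: float


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> HScore:
    """Histochemistry score: 1×%weak + 2×%moderate + 3×%strong.

    Each percentage must lie in [0, 100] and their sum must not exceed 100
    (the remainder being unstained cells); the score therefore lies in
    [0, 300].
    """
    pcts = (pct_weak, pct_moderate, pct_strong)
    for name, p in zip(("weak", "moderate", "strong"), pcts):
        if not 0 <= p <= 100:
            raise ValueError(f"pct_{name} must lie in [0, 100], got {p}")
    if sum(pcts) > 100 + 1e-9:
        raise ValueError(f"staining percentages sum to {sum(pcts)} > 100")
    score = 1.0 * pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong
    return HScore(pct_weak, pct_moderate, pct_strong, score)
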