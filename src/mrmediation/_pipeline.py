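"""Internal helper: one select → clump → harmonize → IVW leg."""

from __future__ import annotations

from typing import Optional

from .config import AnalysisConfig
from .errors import HarmonizationError, PipelineError
from .gwas_data import SummaryStats
from .instruments import HarmonizedSet, clump, harmonize, select_instruments
from .mr_estimators import MREstimate, ivw


def fit_ivw_leg(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: Optional[AnalysisConfig] = None,
    leg_name: str = "",
) -> tuple[MREstimate, HarmonizedSet]:
    """Run the full IVW chain for one exposure→outcome leg.

    Raises :class:`PipelineError` naming the leg when no instruments
    survive selection, clumping or harmonization.
    """
    cfg = config or AnalysisConfig()
    name = leg_name or f"{exposure.trait_id}->{outcome.trait_id}"
    selected = select_instruments(exposure, cfg.p_threshold)
    if not selected:
        raise PipelineError(f"leg {name}: no instruments at p<{cfg.p_threshold:g}")
    kept = clump(exposure, selected, cfg.r2_threshold, cfg.window_kb)
    try:
        h = harmonize(exposure, outcome, kept, cfg.palindrome_eaf_window)
    except HarmonizationError as exc:
        raise PipelineError(f"leg {name}: {exc}") from exc
    if h.n_snps == 0:
        raise PipelineError(f"leg {name}: all instruments dropped in harmonization")
    return ivw(h, model=cfg.ivw_model), h
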