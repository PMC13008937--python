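"""Instrument selection, LD clumping and exposure/outcome harmonization.

Instruments are SNPs associated with the exposure below a p-value threshold
(default 1e-5).  Greedy clumping keeps, in p-ascending order, variants that
are not within a window of an already-retained variant on the same
chromosome with squared correlation above a threshold; without an LD
provider, any variant inside the window is removed (distance-only
clumping).  Harmonization aligns the outcome's effect to the exposure's
effect allele, flipping signs where the allele labels are swapped and
dropping strand-ambiguous palindromic variants whose allele frequency
cannot disambiguate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import HarmonizationError
from .gwas_data import SummaryStats

__all__ = [
    "HarmonizedSet",
    "select_instruments",
    "clump",
    "harmonize",
    "instrument_strength",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G single-base pairs; multi-base alleles are never palindromic."""
    return len(a1) == 1 and len(a2) == 1 and _complement(a1) == a2


@dataclass
class HarmonizedSet:
    """Per-instrument aligned exposure/outcome effects, ready for estimation.

    ``table`` columns: rsid, chrom, pos, beta_exp, se_exp, beta_out, se_out,
    eaf, flipped.  ``dropped`` lists (rsid, reason) for excluded variants.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, keep_mask_or_rsids) -> "HarmonizedSet":
        if isinstance(keep_mask_or_rsids, (list, set, tuple, pd.Index)):
            mask = self.table["rsid"].isin(set(keep_mask_or_rsids))
        else:
            mask = keep_mask_or_rsids
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.table.loc[mask].reset_index(drop=True),
            list(self.dropped),
        )

    def to_tsv(self, path, drop_log_path=None) -> None:
        cols = ["rsid", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "flipped"]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")
        if drop_log_path is not None:
            pd.DataFrame(self.dropped, columns=["rsid", "reason"]).to_csv(
                drop_log_path, sep="\t", index=False
            )


def select_instruments(stats: SummaryStats, p_threshold: float = 1e-5) -> list[str]:
    """rsids with ``pval < p_threshold``, sorted by p ascending (ties by rsid)."""
    t = stats.table
    hits = t.loc[t["pval"] < p_threshold, ["rsid", "pval"]]
    hits = hits.sort_values(["pval", "rsid"], kind="stable")
    return hits["rsid"].tolist()


def clump(
    stats: SummaryStats,
    selected: Sequence[str],
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    ld: Optional[Callable[[str, str], float]] = None,
) -> list[str]:
    """Greedy p-ascending clumping of ``selected`` instruments.

    A variant is removed when an already-retained variant on the same
    chromosome lies within ``window_kb`` and their squared correlation
    (from ``ld``) reaches ``r2_threshold``.  Without an ``ld`` provider the
    window alone decides (distance-only clumping).  Ties in p are broken by
    rsid so the result is order-stable.
    """
    t = stats.table.set_index("rsid")
    unknown = [r for r in selected if r not in t.index]
    if unknown:
        raise LookupError(f"rsid(s) not in summary statistics: {unknown[:5]}")
    rows = t.loc[list(selected), ["chrom", "pos", "pval"]]
    order = rows.sort_values(["pval", "rsid"], kind="stable").index
    window_bp = float(window_kb) * 1000.0
    kept: list[str] = []
    for rsid in order:
        chrom, pos = rows.at[rsid, "chrom"], rows.at[rsid, "pos"]
        removed = False
        for k in kept:
            if rows.at[k, "chrom"] != chrom:
                continue
            if abs(rows.at[k, "pos"] - pos) > window_bp:
                continue
            if ld is None or ld(rsid, k) >= r2_threshold:
                removed = True
                break
        if not removed:
            kept.append(rsid)
    return kept


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instruments: Sequence[str],
    palindrome_eaf_window: tuple[float, float] = (0.40, 0.60),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per instrument.

    Rules, per shared instrument:

    * alleles identical (directly or after strand complement) — keep as is;
    * alleles swapped (directly or after strand complement) — negate the
      outcome beta, mirror its frequency, flag ``flipped``;
    * palindromic (A/T, C/G) with either trait's frequency inside
      ``palindrome_eaf_window`` or missing — drop (``palindromic_ambiguous``);
      outside the window the orientation with concordant minor alleles wins;
    * otherwise — drop (``allele_mismatch``).

    Instruments absent from the outcome are dropped (``missing_in_outcome``).

    Raises
    ------
    HarmonizationError
        When exposure and outcome share no instrument at all.
    """
    lo, hi = palindrome_eaf_window
    exp = exposure.subset(instruments).set_index("rsid")
    exp = exp.loc[[r for r in instruments if r in exp.index]]
    out = outcome.table.set_index("rsid")

    dropped: list[tuple[str, str]] = []
    shared = [r for r in exp.index if r in out.index]
    for r in exp.index:
        if r not in out.index:
            dropped.append((r, "missing_in_outcome"))
    if not shared:
        raise HarmonizationError(
            f"no shared instruments between {exposure.trait_id!r} "
            f"and {outcome.trait_id!r}"
        )

    rows = []
    for rsid in shared:
        e = exp.loc[rsid]
        o = out.loc[rsid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        eaf_e = e["eaf"]
        eaf_o = o["eaf"]

        direct = (ea_o == ea_e) and (oa_o == oa_e)
        swapped = (ea_o == oa_e) and (oa_o == ea_e)
        c_ea_o, c_oa_o = _complement(ea_o), _complement(oa_o)
        strand_direct = (c_ea_o == ea_e) and (c_oa_o == oa_e)
        strand_swapped = (c_ea_o == oa_e) and (c_oa_o == ea_e)
        palindromic = _is_palindromic(ea_e, oa_e)

        if palindromic and (direct or swapped):
            ambiguous = (
                pd.isna(eaf_e)
                or pd.isna(eaf_o)
                or (lo < eaf_e < hi)
                or (lo < eaf_o < hi)
            )
            if ambiguous:
                dropped.append((rsid, "palindromic_ambiguous"))
                continue
            flip = (eaf_e < 0.5) != (eaf_o < 0.5)
        elif direct or strand_direct:
            flip = False
        elif swapped or strand_swapped:
            flip = True
        else:
            dropped.append((rsid, "allele_mismatch"))
            continue

        beta_out = -float(o["beta"]) if flip else float(o["beta"])
        rows.append(
            {
                "rsid": rsid,
                "chrom": e["chrom"],
                "pos": int(e["pos"]),
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf": float(eaf_e) if pd.notna(eaf_e) else np.nan,
                "flipped": bool(flip),
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "rsid", "chrom", "pos", "beta_exp", "se_exp",
            "beta_out", "se_out", "eaf", "flipped",
        ],
    )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, table, dropped)


def instrument_strength(h: HarmonizedSet) -> tuple[pd.Series, float]:
    """Per-instrument F-statistics ``(beta_exp/se_exp)**2`` and their mean.

    With a single instrumented predictor the first-stage F equals the
    squared Wald z of the SNP-exposure association; mean F near 10 or above
    is the conventional weak-instrument comfort zone.
    """
    f = (h.table["beta_exp"] / h.table["se_exp"]) ** 2
    f.index = h.table["rsid"]
    return f, float(f.mean())
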