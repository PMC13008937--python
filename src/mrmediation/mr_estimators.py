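"""Two-sample MR estimators: IVW, MR-Egger, weighted median, simple and
weighted mode, plus Cochran heterogeneity and odds-ratio reporting.

All estimators consume a :class:`~mrmediation.instruments.HarmonizedSet`
and operate on per-SNP Wald ratios (outcome effect divided by exposure
effect, with first-order delta SE ``se_out / |beta_exp|``).  Betas are on
the outcome scale — log-odds for binary outcomes — and are reported with
the exponentiated point estimate and 95% bounds ``exp(beta ∓ 1.96·se)``,
so the geometric mean of the CI bounds always equals the odds ratio.

The IVW default is a multiplicative random-effects model: the fixed-effect
SE is inflated by ``sqrt(Q/(n-1))`` when Cochran's Q exceeds its degrees of
freedom, never deflated.  P-values use the standard normal throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import EstimationError, InsufficientInstrumentsError
from .instruments import HarmonizedSet

__all__ = [
    "MREstimate",
    "FIVE_METHODS",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "all_methods",
    "cochran_q",
    "to_or",
    "format_or_ci",
    "estimates_table",
]

Z95 = 1.96

#: the five-method battery used for direction-consistency screening
FIVE_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass
class MREstimate:
    """One method's causal estimate with OR/CI and diagnostics."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    or_: float
    ci_low: float
    ci_high: float
    exposure_id: str = ""
    outcome_id: str = ""
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None


def to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, 95% CI low, high).

    By construction ``sqrt(ci_low * ci_high) == or_``, the structure of the
    conventional ``OR(95%CI)`` table column.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z95 * se)),
        float(np.exp(beta + Z95 * se)),
    )


def _two_sided_p(beta: float, se: float) -> float:
    return float(2.0 * sps.norm.sf(abs(beta) / se))


def _finish(
    method: str, beta: float, se: float, n: int, h: HarmonizedSet, **extra
) -> MREstimate:
    or_, lo, hi = to_or(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=_two_sided_p(beta, se),
        n_snps=int(n),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        **extra,
    )


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP causal ratios and first-order delta SEs, in rsid order.

    Instruments with a zero exposure effect carry an undefined ratio and
    are excluded with a warning.
    """
    t = h.table.sort_values("rsid", kind="stable")
    bx = t["beta_exp"].to_numpy(float)
    keep = bx != 0.0
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} instrument(s) with beta_exp == 0",
            stacklevel=2,
        )
    t = t.loc[keep]
    bx = bx[keep]
    ratios = t["beta_out"].to_numpy(float) / bx
    ses = t["se_out"].to_numpy(float) / np.abs(bx)
    return ratios, ses, t["rsid"].tolist()


def _require(h: HarmonizedSet, minimum: int, method: str) -> None:
    if h.n_snps < minimum:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {minimum} instruments, got {h.n_snps}"
        )


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Equivalent to weighted regression of outcome on exposure effects
    through the origin with weights ``se_out**-2``.  ``model`` is either
    ``"fixed"`` or ``"multiplicative_random"`` (SE inflated by
    ``max(1, sqrt(Q/(n-1)))`` when n >= 2).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    ratios, ses, _ = wald_ratios(h)
    n = ratios.size
    if n == 0:
        raise EstimationError("IVW: no usable instruments")
    w = ses**-2.0
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = q_df = q_p = None
    if n >= 2:
        q = float(np.sum(w * (ratios - beta) ** 2))
        q_df = n - 1
        q_p = float(sps.chi2.sf(q, q_df))
        if model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / q_df))
    return _finish("ivw", beta, se, n, h, q_stat=q, q_df=q_df, q_pval=q_p)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression with an intercept.

    Rows are orientated so every exposure effect is non-negative (the
    intercept is orientation-dependent).  The slope is the causal estimate;
    the intercept is the directional-pleiotropy diagnostic.  SEs use a
    multiplicative random-effects residual scale, never below 1.
    """
    _require(h, 3, "MR-Egger")
    t = h.table
    bx = t["beta_exp"].to_numpy(float)
    by = t["beta_out"].to_numpy(float)
    sy = t["se_out"].to_numpy(float)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = sy**-2.0

    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    denom = sw * swxx - swx**2
    if denom <= 0:
        raise EstimationError("MR-Egger: degenerate design (no spread in beta_exp)")
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swxx * swy - swx * swxy) / denom
    resid = y - intercept - slope * x
    n = len(x)
    sigma2 = float((w * resid**2).sum() / (n - 2))
    scale = max(1.0, sigma2)
    se_slope = float(np.sqrt(scale * sw / denom))
    se_int = float(np.sqrt(scale * swxx / denom))
    return _finish(
        "egger",
        slope,
        se_slope,
        n,
        h,
        egger_intercept=float(intercept),
        egger_intercept_se=se_int,
        egger_intercept_pval=_two_sided_p(intercept, se_int),
    )


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median with linear interpolation in cumulative weight.

    ``values``: (n_rows, n) array; ``weights``: (n,) shared across rows.
    Cumulative midpoints S_j = cumsum(w)_j - w_j/2 (normalized); the median
    is interpolated where S crosses 0.5.
    """
    values = np.atleast_2d(values)
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = weights[order]
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        si, vi = s[i], v[i]
        j = int(np.searchsorted(si, 0.5))
        if j == 0:
            out[i] = vi[0]
        elif j >= si.size:
            out[i] = vi[-1]
        else:
            frac = (0.5 - si[j - 1]) / (si[j] - si[j - 1])
            out[i] = vi[j - 1] + frac * (vi[j] - vi[j - 1])
    return out


def _bootstrap_se(
    estimator, ratios: np.ndarray, ses: np.ndarray, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ses, size=(n_boot, ratios.size))
    reps = estimator(draws)
    return float(np.std(reps, ddof=1))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator (consistent when >=50% of weight is valid).

    The SE is a parametric bootstrap: each ratio is resampled from
    ``Normal(ratio_j, se_j)`` ``n_boot`` times (instruments sorted by rsid
    before resampling so the draw is reproducible under permutation).
    """
    _require(h, 3, "weighted median")
    ratios, ses, _ = wald_ratios(h)
    w = ses**-2.0
    beta = float(_weighted_median_rows(ratios, w)[0])
    se = _bootstrap_se(lambda d: _weighted_median_rows(d, w), ratios, ses, n_boot, seed)
    return _finish("weighted_median", beta, se, ratios.size, h)


def _kde_mode(
    ratios: np.ndarray, weights: np.ndarray, phi: float, grid_points: int = 512
) -> float:
    """Argmax of a normal-kernel density over a fixed evaluation grid.

    Bandwidth is ``phi`` times a modified Silverman rule,
    ``0.9 * min(sd, 1.4826*mad) * n**(-1/5)`` (falling back to whichever
    dispersion measure is positive).  The grid spans the ratio range padded
    by three bandwidths; the first maximum wins.
    """
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    sd = float(np.std(ratios, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    disp = min(d for d in (sd, mad) if d > 0)
    bw = phi * 0.9 * disp * ratios.size ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, grid_points)
    z = (grid[:, None] - ratios[None, :]) / bw
    dens = (np.exp(-0.5 * z**2) * weights[None, :]).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator (simple or inverse-variance weighted kernel).

    Consistent when the largest group of instruments sharing a causal
    ratio is valid (ZEMPA).  SE by parametric bootstrap as for the
    weighted median.
    """
    _require(h, 3, "mode estimator")
    ratios, ses, _ = wald_ratios(h)
    w = ses**-2.0 if weighted else np.ones_like(ratios)
    w = w / w.sum()

    def est(draws: np.ndarray) -> np.ndarray:
        draws = np.atleast_2d(draws)
        return np.array([_kde_mode(row, w, phi) for row in draws])

    beta = float(est(ratios)[0])
    se = _bootstrap_se(est, ratios, ses, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, beta, se, ratios.size, h)


def all_methods(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0, phi: float = 1.0
) -> list[MREstimate]:
    """The five-method battery, in :data:`FIVE_METHODS` order."""
    return [
        ivw(h),
        egger(h),
        weighted_median(h, n_boot=n_boot, seed=seed),
        mode_estimate(h, weighted=False, phi=phi, n_boot=n_boot, seed=seed),
        mode_estimate(h, weighted=True, phi=phi, n_boot=n_boot, seed=seed),
    ]


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effect IVW estimate; (Q, df, p)."""
    _require(h, 2, "Cochran's Q")
    ratios, ses, _ = wald_ratios(h)
    w = ses**-2.0
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = ratios.size - 1
    return q, df, float(sps.chi2.sf(q, df))


def format_or_ci(or_: float, lo: float, hi: float) -> str:
    """``x.xxx(a.aaa-b.bbb)`` as in conventional MR result tables."""
    return f"{or_:.3f}({lo:.3f}-{hi:.3f})"


def estimates_table(estimates) -> "pd.DataFrame":
    """Tabulate estimates in the exposure/outcome/method/p/OR(CI) layout."""
    import pandas as pd

    rows = [
        {
            "exposure": e.exposure_id,
            "outcome": e.outcome_id,
            "method": e.method,
            "n_snps": e.n_snps,
            "beta": e.beta,
            "se": e.se,
            "p-value": e.pval,
            "OR(95%CI)": format_or_ci(e.or_, e.ci_low, e.ci_high),
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
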