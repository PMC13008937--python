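"""Synthetic GWAS summary statistics under a known causal DAG.

The generator emulates the three data layers of a protein → immune
phenotype → rare-disease two-step MR design: a well-powered quantitative
exposure GWAS (defaults anchored at n = 35,559), a much smaller
quantitative mediator GWAS (n = 3,757) and a binary outcome GWAS with
extreme case/control imbalance (126 cases / 412,055 controls).

Model
-----
Three disjoint SNP blocks, mutually independent (no LD), minor-allele
frequencies uniform on ``maf_range``:

* ``m_snps`` exposure SNPs with standardized effects ``b_x`` scaled so the
  block explains exactly ``h2_x`` of the exposure's unit variance;
* ``m_snps_mediator`` mediator-specific SNPs explaining ``h2_m`` of the
  mediator (the mediator also inherits ``theta_xm * b_x`` through the
  exposure);
* ``m_snps_outcome`` outcome-specific SNPs with log-odds effects of total
  squared scale ``outcome_snp_var`` (these give reverse-MR its
  instruments and are causally null for the exposure).

Traits: X standardized; M = theta_xm·X + own genetics + noise,
standardized; D binary with log-odds theta_xd·X + theta_md·M (+ optional
per-SNP horizontal pleiotropy on the exposure block).  Under the
rare-disease approximation the marginal per-SNP log-odds on D are linear:
``(theta_xd + theta_xm·theta_md)·b_x`` on the exposure block and
``theta_md·b_m`` on the mediator block.

Summary statistics are drawn from the asymptotic sampling distributions,
``beta_hat ~ Normal(beta_true, se^2)`` with ``se = 1/sqrt(2 n f (1-f))``
for standardized continuous traits and
``se = 1/sqrt(2 f (1-f) n_cases n_controls / n)`` for the binary trait.
:func:`simulate_individual_oracle` regenerates the same quantities from
individual-level genotypes and per-SNP regressions and serves as the
generator's independent cross-check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .gwas_data import SummaryStats

__all__ = [
    "SimConfig",
    "SimTruth",
    "ScreenRegistry",
    "simulate_triple",
    "simulate_with_truth",
    "simulate_individual_oracle",
    "null_registry",
    "simulate_screen_registry",
    "well_powered_config",
    "with_correlated_duplicates",
    "write_manifest",
]

_ALLELE_PAIRS = [
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T"),
]


@dataclass
class SimConfig:
    """Causal DAG and sampling parameters for the synthetic generator.

    ``theta_xm`` is the effect of the exposure X on the mediator M (per SD),
    ``theta_md`` the log-odds effect of M on the binary outcome D, and
    ``theta_xd`` the direct log-odds effect of X on D.  The implied true
    total effect is ``theta_xd + theta_xm * theta_md``.
    """

    m_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_x: float = 0.1
    theta_xm: float = 0.0
    theta_md: float = 0.0
    theta_xd: float = 0.0
    n_x: int = 35_559
    n_m: int = 3_757
    n_cases: int = 126
    n_controls: int = 412_055
    m_snps_mediator: int = 20
    h2_m: float = 0.2
    m_snps_outcome: int = 0
    outcome_snp_var: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.05
    pleiotropy_mean: float = 0.05  # mean direct SNP->D effect (directional)
    seed: int = 0

    @property
    def alpha_total_true(self) -> float:
        return self.theta_xd + self.theta_xm * self.theta_md

    @property
    def alpha_mediated_true(self) -> float:
        return self.theta_xm * self.theta_md

    @property
    def proportion_mediated_true(self) -> Optional[float]:
        total = self.alpha_total_true
        if total == 0:
            return None
        return 100.0 * self.alpha_mediated_true / total

    def validate(self) -> None:
        if self.m_snps < 1:
            raise ConfigError("m_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.h2_x < 1):
            raise ConfigError("h2_x must lie in [0, 1)")
        if self.m_snps_mediator < 0 or self.m_snps_outcome < 0:
            raise ConfigError("SNP-block sizes must be non-negative")
        if not (0 <= self.h2_m < 1):
            raise ConfigError("h2_m must lie in [0, 1)")
        if self.theta_xm**2 + self.h2_m >= 1:
            raise ConfigError(
                "infeasible mediator model: theta_xm**2 + h2_m must be < 1 "
                "for a unit-variance mediator"
            )
        for name in ("n_x", "n_m", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass
class SimTruth:
    """Ground-truth per-SNP effects behind one simulated triple."""

    config: SimConfig
    variants: pd.DataFrame  # rsid, chrom, pos, effect_allele, other_allele, eaf, block
    beta_x: np.ndarray  # true per-allele effect on X (standardized)
    beta_m: np.ndarray  # true per-allele effect on M (standardized)
    beta_d: np.ndarray  # true per-allele log-odds effect on D
    pleiotropy: np.ndarray  # direct SNP->D offsets (exposure block)

    @property
    def exposure_block(self) -> list[str]:
        v = self.variants
        return v.loc[v["block"] == "exposure", "rsid"].tolist()

    @property
    def mediator_block(self) -> list[str]:
        v = self.variants
        return v.loc[v["block"] == "mediator", "rsid"].tolist()

    @property
    def outcome_block(self) -> list[str]:
        v = self.variants
        return v.loc[v["block"] == "outcome", "rsid"].tolist()


def _variant_frame(
    rng: np.random.Generator,
    m: int,
    maf_range: tuple[float, float],
    prefix: str,
    start: int,
    block: str,
) -> pd.DataFrame:
    """Independent non-palindromic variants, spaced beyond clumping windows."""
    idx = np.arange(start, start + m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    eaf = rng.uniform(maf_range[0], maf_range[1], size=m)
    return pd.DataFrame(
        {
            "rsid": [f"{prefix}rs{i:06d}" for i in idx],
            "chrom": [str(int(i % 22) + 1) for i in idx],
            # 25 Mb spacing on a chromosome: outside default clump windows
            "pos": [10_000_000 + int(i // 22) * 25_000_000 for i in idx],
            "effect_allele": [_ALLELE_PAIRS[j][0] for j in pair_idx],
            "other_allele": [_ALLELE_PAIRS[j][1] for j in pair_idx],
            "eaf": eaf,
            "block": block,
        }
    )


def _scaled_effects(
    rng: np.random.Generator, eaf: np.ndarray, total_var: float
) -> np.ndarray:
    """Normal effects rescaled so sum(2 f (1-f) b^2) equals ``total_var``."""
    if total_var == 0 or eaf.size == 0:
        return np.zeros(eaf.size)
    raw = rng.standard_normal(eaf.size)
    var = 2.0 * eaf * (1.0 - eaf)
    return raw * np.sqrt(total_var / float(np.sum(var * raw**2)))


def _se_continuous(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _se_binary(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)


def _sample_stats(
    rng: np.random.Generator,
    variants: pd.DataFrame,
    true_beta: np.ndarray,
    se: np.ndarray,
    trait_id: str,
    trait_type: str,
    n: int,
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
    provenance: str = "synthetic",
) -> SummaryStats:
    beta_hat = true_beta + rng.standard_normal(true_beta.size) * se
    pval = 2.0 * sps.norm.sf(np.abs(beta_hat) / se)
    table = variants.drop(columns="block").copy()
    table["beta"] = beta_hat
    table["se"] = se
    table["pval"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    table["n"] = n
    if trait_type == "binary":
        table["n_cases"] = n_cases
        table["n_controls"] = n_controls
    return SummaryStats(trait_id, trait_type, table, provenance=provenance)


def _pleiotropy(
    rng: np.random.Generator, config: SimConfig, beta_x: np.ndarray
) -> np.ndarray:
    """Direct SNP→outcome log-odds offsets on the exposure block.

    Directional pleiotropy is defined in the exposure-increasing allele
    orientation (the convention under which the Egger intercept estimates
    the mean direct effect); with arbitrary allele coding the offset is
    therefore carried with the sign of the SNP's exposure effect.
    Balanced pleiotropy is zero-mean and orientation-free.
    """
    if config.pleiotropy_mode == "none":
        return np.zeros(beta_x.size)
    mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
    draws = rng.normal(mean, config.pleiotropy_sd, size=beta_x.size)
    return np.where(beta_x >= 0, 1.0, -1.0) * draws


def simulate_with_truth(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ids: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    rs_prefix: str = "",
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimTruth]:
    """Simulate an (exposure, mediator, outcome) triple plus its ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    blocks = [
        _variant_frame(rng, config.m_snps, config.maf_range, rs_prefix, 0, "exposure"),
        _variant_frame(
            rng, config.m_snps_mediator, config.maf_range, rs_prefix,
            config.m_snps, "mediator",
        ),
        _variant_frame(
            rng, config.m_snps_outcome, config.maf_range, rs_prefix,
            config.m_snps + config.m_snps_mediator, "outcome",
        ),
    ]
    variants = pd.concat(blocks, ignore_index=True)
    eaf = variants["eaf"].to_numpy()
    is_x = (variants["block"] == "exposure").to_numpy()
    is_m = (variants["block"] == "mediator").to_numpy()
    is_d = (variants["block"] == "outcome").to_numpy()

    b_x = np.zeros(len(variants))
    b_x[is_x] = _scaled_effects(rng, eaf[is_x], config.h2_x)
    b_m_own = np.zeros(len(variants))
    b_m_own[is_m] = _scaled_effects(rng, eaf[is_m], config.h2_m)
    b_d_own = np.zeros(len(variants))
    b_d_own[is_d] = _scaled_effects(rng, eaf[is_d], config.outcome_snp_var)
    pleio = np.zeros(len(variants))
    pleio[is_x] = _pleiotropy(rng, config, b_x[is_x])

    true_x = b_x
    true_m = config.theta_xm * b_x + b_m_own
    true_d = config.alpha_total_true * b_x + config.theta_md * b_m_own + b_d_own + pleio

    n_total = config.n_cases + config.n_controls
    x = _sample_stats(
        rng, variants, true_x, _se_continuous(eaf, config.n_x),
        ids[0], "continuous", config.n_x,
        provenance=f"synthetic seed={config.seed}",
    )
    m = _sample_stats(
        rng, variants, true_m, _se_continuous(eaf, config.n_m),
        ids[1], "continuous", config.n_m,
        provenance=f"synthetic seed={config.seed}",
    )
    d = _sample_stats(
        rng, variants, true_d,
        _se_binary(eaf, config.n_cases, config.n_controls),
        ids[2], "binary", n_total, config.n_cases, config.n_controls,
        provenance=f"synthetic seed={config.seed}",
    )
    truth = SimTruth(config, variants, true_x, true_m, true_d, pleio[is_x])
    return x, m, d, truth


def simulate_triple(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats]:
    """Simulate exposure, mediator and outcome summary statistics.

    Deterministic given ``config.seed``; two calls with the same config
    yield identical outputs.
    """
    x, m, d, _ = simulate_with_truth(config)
    return x, m, d


def simulate_individual_oracle(
    config: SimConfig,
    n_subsample: int,
    prevalence: Optional[float] = None,
) -> tuple[SummaryStats, SummaryStats, SummaryStats]:
    """Desk-scale individual-level oracle for :func:`simulate_triple`.

    Simulates ``n_subsample`` genotypes (binomial at the drawn allele
    frequencies), builds X and M as linear traits and D by a logistic
    model with the configured effects, then computes per-SNP summary
    statistics by actual regression (OLS for X and M, maximum-likelihood
    logistic for D).  The same variant panel and true effect draws are
    used as :func:`simulate_with_truth` at the same seed.
    """
    import statsmodels.api as sm

    config.validate()
    rng = np.random.default_rng(config.seed)
    # consume the same stream as simulate_with_truth up to the effect draws
    _, _, _, truth = simulate_with_truth(config, rng=None)
    variants = truth.variants
    eaf = variants["eaf"].to_numpy()
    m_total = len(variants)
    is_x = (variants["block"] == "exposure").to_numpy()

    rng = np.random.default_rng([config.seed, 0x0FACCE])
    g = rng.binomial(2, eaf[None, :], size=(n_subsample, m_total)).astype(float)

    b_x = truth.beta_x
    b_m_own = truth.beta_m - config.theta_xm * truth.beta_x
    pleio_full = np.zeros(m_total)
    pleio_full[is_x] = truth.pleiotropy
    b_d_own = truth.beta_d - (
        config.alpha_total_true * b_x + config.theta_md * b_m_own + pleio_full
    )

    x = g @ b_x + rng.normal(0, np.sqrt(1 - config.h2_x), n_subsample)
    resid_m = 1 - config.theta_xm**2 - config.h2_m
    m_trait = g @ b_m_own + config.theta_xm * x + rng.normal(
        0, np.sqrt(resid_m), n_subsample
    )
    if prevalence is None:
        prevalence = config.n_cases / (config.n_cases + config.n_controls)
    lp = (
        config.theta_xd * (x - x.mean())
        + config.theta_md * (m_trait - m_trait.mean())
        + (g - g.mean(axis=0)) @ (pleio_full + b_d_own)
    )
    beta0 = np.log(prevalence / (1 - prevalence))
    d = rng.binomial(1, 1.0 / (1.0 + np.exp(-(beta0 + lp))))

    def ols_stats(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        betas = np.empty(m_total)
        ses = np.empty(m_total)
        for j in range(m_total):
            gj = g[:, j]
            vg = gj.var()
            b = np.cov(gj, y, ddof=0)[0, 1] / vg
            resid = y - y.mean() - b * (gj - gj.mean())
            s2 = (resid**2).sum() / (n_subsample - 2)
            betas[j] = b
            ses[j] = np.sqrt(s2 / (vg * n_subsample))
        return betas, ses

    bx_hat, sx = ols_stats(x)
    bm_hat, sm_ = ols_stats(m_trait)

    bd_hat = np.empty(m_total)
    sd_ = np.empty(m_total)
    for j in range(m_total):
        design = sm.add_constant(g[:, j])
        fit = sm.Logit(d, design).fit(disp=0)
        bd_hat[j] = fit.params[1]
        sd_[j] = fit.bse[1]

    def pack(beta, se, trait_id, trait_type, n, **kw):
        pval = np.clip(
            2.0 * sps.norm.sf(np.abs(beta) / se), np.nextafter(0, 1), 1.0
        )
        table = variants.drop(columns="block").copy()
        table["beta"] = beta
        table["se"] = se
        table["pval"] = pval
        table["n"] = n
        for k, v in kw.items():
            table[k] = v
        return SummaryStats(
            trait_id, trait_type, table,
            provenance=f"individual-level oracle seed={config.seed}",
        )

    n_cases = int(d.sum())
    return (
        pack(bx_hat, sx, "exposure", "continuous", n_subsample),
        pack(bm_hat, sm_, "mediator", "continuous", n_subsample),
        pack(
            bd_hat, sd_, "outcome", "binary", n_subsample,
            n_cases=n_cases, n_controls=n_subsample - n_cases,
        ),
    )


def null_registry(
    config: SimConfig, k_exposures: int
) -> tuple[list[SummaryStats], SummaryStats]:
    """``k_exposures`` independent null-effect exposure GWAS + shared outcome.

    Every causal path is severed (all thetas zero); each exposure keeps its
    own instrument block and the outcome concatenates all blocks, so the
    registry estimates the screening pipeline's false-positive behavior.
    The first exposure reproduces :func:`simulate_triple`'s exposure layer
    at the same seed.
    """
    if k_exposures < 1:
        raise ConfigError("k_exposures must be >= 1")
    base = dataclasses.replace(config, theta_xm=0.0, theta_md=0.0, theta_xd=0.0)
    exposures: list[SummaryStats] = []
    outcome_tables = []
    n_total = config.n_cases + config.n_controls
    for k in range(k_exposures):
        if k == 0:
            rng = np.random.default_rng(base.seed)
            prefix = ""
        else:
            rng = np.random.default_rng(np.random.SeedSequence([base.seed, k]))
            prefix = f"e{k}_"
        x, _, d, _ = simulate_with_truth(
            base, rng=rng, ids=(f"exposure_{k:03d}", "mediator", "outcome"),
            rs_prefix=prefix,
        )
        exposures.append(x)
        outcome_tables.append(d.table)
    outcome = SummaryStats(
        "outcome",
        "binary",
        pd.concat(outcome_tables, ignore_index=True),
        provenance=f"null registry seed={config.seed}",
    )
    return exposures, outcome


@dataclass
class ScreenRegistry:
    """Synthetic screening registry with one true mediated path."""

    exposures: list[SummaryStats]
    mediators: list[SummaryStats]
    outcome: SummaryStats
    true_exposure_id: str
    true_mediator_id: str
    config: SimConfig = field(repr=False, default=None)


def well_powered_config(seed: int = 0) -> SimConfig:
    """The package's powered test regime for recovery and screening runs.

    Exposure and mediator GWAS keep the field-realistic sample sizes
    (35,559 and 3,757); the outcome GWAS uses 1,000 cases / 100,000
    controls so the causal legs are estimable at desk scale, with
    θ_xm = 0.4, θ_md = 0.5, θ_xd = 0.8 (true mediated proportion 20%).
    Twenty outcome-specific SNPs give reverse-MR its instruments.
    """
    return SimConfig(
        m_snps=50,
        h2_x=0.1,
        theta_xm=0.4,
        theta_md=0.5,
        theta_xd=0.8,
        n_cases=1_000,
        n_controls=100_000,
        m_snps_mediator=20,
        h2_m=0.2,
        m_snps_outcome=20,
        outcome_snp_var=1.0,
        seed=seed,
    )


def simulate_screen_registry(
    config: SimConfig,
    k_null_exposures: int = 50,
    k_null_mediators: int = 20,
    seed: Optional[int] = None,
) -> ScreenRegistry:
    """A registry of exposures and mediators with exactly one causal path.

    ``exposures[0]`` ("protein_causal") acts on the outcome directly and
    through ``mediators[0]`` ("phenotype_causal") per the config's thetas;
    all other traits have real instruments but no causal effect.  Null
    exposures carry the outcome-specific SNPs (null for them) so reverse
    MR is testable for every screened exposure; null mediators carry the
    causal exposure's SNPs (null for them) so the exposure→mediator leg is
    testable for every candidate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    provenance = f"screen registry seed={config.seed if seed is None else seed}"

    start = 0

    def block(m: int, name: str) -> pd.DataFrame:
        nonlocal start
        b = _variant_frame(rng, m, config.maf_range, "", start, name)
        start += m
        return b

    exp_blocks = [block(config.m_snps, f"exp{k}") for k in range(k_null_exposures + 1)]
    med_blocks = [
        block(config.m_snps_mediator, f"med{j}") for j in range(k_null_mediators + 1)
    ]
    out_block = block(config.m_snps_outcome, "out")

    exp_effects = [
        _scaled_effects(rng, b["eaf"].to_numpy(), config.h2_x) for b in exp_blocks
    ]
    med_effects = [
        _scaled_effects(rng, b["eaf"].to_numpy(), config.h2_m) for b in med_blocks
    ]
    out_effects = _scaled_effects(
        rng, out_block["eaf"].to_numpy(), config.outcome_snp_var
    )

    def trait_stats(panel_parts, true_parts, trait_id, continuous_n=None, binary=False):
        panel = pd.concat(panel_parts, ignore_index=True)
        true = np.concatenate(true_parts)
        eaf = panel["eaf"].to_numpy()
        if binary:
            se = _se_binary(eaf, config.n_cases, config.n_controls)
            return _sample_stats(
                rng, panel, true, se, trait_id, "binary",
                config.n_cases + config.n_controls,
                config.n_cases, config.n_controls, provenance=provenance,
            )
        se = _se_continuous(eaf, continuous_n)
        return _sample_stats(
            rng, panel, true, se, trait_id, "continuous", continuous_n,
            provenance=provenance,
        )

    exposures = []
    for k, (b, eff) in enumerate(zip(exp_blocks, exp_effects)):
        trait_id = "protein_causal" if k == 0 else f"protein_null_{k:03d}"
        exposures.append(
            trait_stats(
                [b, out_block],
                [eff, np.zeros(len(out_block))],
                trait_id,
                continuous_n=config.n_x,
            )
        )

    mediators = []
    for j, (b, eff) in enumerate(zip(med_blocks, med_effects)):
        trait_id = "phenotype_causal" if j == 0 else f"phenotype_null_{j:03d}"
        on_exp0 = config.theta_xm * exp_effects[0] if j == 0 else np.zeros(
            len(exp_blocks[0])
        )
        mediators.append(
            trait_stats(
                [b, exp_blocks[0], out_block],
                [eff, on_exp0, np.zeros(len(out_block))],
                trait_id,
                continuous_n=config.n_m,
            )
        )

    # outcome over the full panel
    panel_parts = exp_blocks + med_blocks + [out_block]
    true_parts = []
    for k, eff in enumerate(exp_effects):
        true_parts.append(config.alpha_total_true * eff if k == 0 else np.zeros_like(eff))
    for j, eff in enumerate(med_effects):
        true_parts.append(config.theta_md * eff if j == 0 else np.zeros_like(eff))
    true_parts.append(out_effects)
    outcome = trait_stats(panel_parts, true_parts, "endpoint", binary=True)

    return ScreenRegistry(
        exposures, mediators, outcome, "protein_causal", "phenotype_causal", config
    )


def with_correlated_duplicates(
    stats: SummaryStats,
    k_copies: int = 1,
    r2: float = 0.9,
    offset_bp: int = 1_000,
    seed: int = 0,
):
    """Add near-duplicate neighbours of every variant, plus an LD provider.

    Each variant gains ``k_copies`` companions ``<rsid>_dupN`` placed
    ``offset_bp`` apart with betas drawn around the original (correlation
    ``sqrt(r2)``), emulating an LD block so the clumping stage can be
    exercised without a reference panel.  Returns ``(stats, ld)`` where
    ``ld(a, b)`` reports ``r2`` for members of the same block and 0.0
    otherwise.
    """
    rng = np.random.default_rng(seed)
    base = stats.table
    parts = [base]
    rho = float(np.sqrt(r2))
    for i in range(1, k_copies + 1):
        dup = base.copy()
        dup["rsid"] = dup["rsid"] + f"_dup{i}"
        dup["pos"] = dup["pos"] + i * offset_bp
        noise = rng.standard_normal(len(dup)) * dup["se"]
        dup["beta"] = rho * dup["beta"] + np.sqrt(1 - r2) * noise
        dup["pval"] = np.clip(
            2.0 * sps.norm.sf(np.abs(dup["beta"] / dup["se"])),
            np.nextafter(0, 1), 1.0,
        )
        parts.append(dup)
    expanded = SummaryStats(
        stats.trait_id, stats.trait_type,
        pd.concat(parts, ignore_index=True),
        provenance=stats.provenance + " +correlated duplicates",
    )

    def block_of(rsid: str) -> str:
        return rsid.split("_dup")[0]

    def ld(a: str, b: str) -> float:
        if a == b:
            return 1.0
        return r2 if block_of(a) == block_of(b) else 0.0

    return expanded, ld


def write_manifest(config: SimConfig, path) -> None:
    """Record the true parameter values as key=value text for test harnesses."""
    lines = [f"{f.name}={getattr(config, f.name)}" for f in dataclasses.fields(config)]
    lines.append(f"alpha_total_true={config.alpha_total_true}")
    lines.append(f"alpha_mediated_true={config.alpha_mediated_true}")
    lines.append(f"proportion_mediated_true={config.proportion_mediated_true}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
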