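"""Summary-level GWAS simulation with a known structural model.

The generator draws exposure / mediator / outcome summary statistics from
the causal diagram

    SNPs (gamma) -> exposure --theta_em--> mediator --theta_mo--> outcome
                         \\________________theta_direct__________/

    mediator-specific SNPs (delta) -> mediator -> outcome

so the total exposure->outcome effect is
``theta_total = theta_direct + theta_em * theta_mo`` and the true proportion
mediated is ``theta_em * theta_mo / theta_total``. A configurable fraction of
exposure instruments additionally carries a horizontal-pleiotropy path to the
outcome (``alpha``), either balanced (zero-mean) or directional (drawn
relative to the exposure-increasing allele so that it biases IVW).

Simulation is at the summary level: for each SNP the "published" beta is the
true marginal effect plus Gaussian noise with standard error
``1 / sqrt(2 * n * maf * (1 - maf))``; case-control traits use the effective
sample size ``4 / (1/n_cases + 1/n_controls)``. Mediator-specific SNPs give
the mediator its own instruments, without which the mediator->outcome leg of
two-step mediation would be unidentifiable (every exposure instrument's Wald
ratio on that leg equals theta_total/theta_em, not theta_mo).

LD is block-diagonal: consecutive SNPs form blocks of ``ld_block_size`` with
pairwise r-squared ``within_block_r2``; estimates within a block share a
common noise factor and non-lead SNPs carry attenuated marginal effects
(scaled by r), so clumping to one SNP per block leaves consistent Wald
ratios. A fraction of SNPs receives palindromic (A/T or C/G) allele pairs so
the palindrome filter has work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import TraitTable

_CHROMOSOMES = 22
_BLOCK_SPACING_BP = 50_000_000  # keeps distinct blocks outside any clump window
_WITHIN_BLOCK_SPACING_BP = 1_000

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic exposure/mediator/outcome triplet.

    Defaults reproduce the cohort scales of the motivating study: an immune
    phenotype GWAS of 3,757 individuals, a metabolite GWAS of 8,299, and a
    rare-cancer case-control outcome of 224 cases / 314,193 controls. True
    effects default to theta_total=0.24, theta_em=0.1, theta_mo=0.6, i.e. a
    true proportion mediated of 0.25.
    """

    m_snps: int = 500                 # exposure-associated SNPs
    m_mediator_snps: int = 500        # mediator-specific SNPs
    n_exposure: int = 3_757
    n_mediator: int = 8_299
    n_cases: int = 224
    n_controls: int = 314_193
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_exposure_sd: float = 0.15    # SD of true instrument effects gamma_j
    beta_mediator_sd: float = 0.15    # SD of mediator-specific effects delta_k
    theta_total: float = 0.24         # exposure -> outcome total effect (log-odds)
    theta_em: float = 0.1             # exposure -> mediator
    theta_mo: float = 0.6             # mediator -> outcome (log-odds)
    pleiotropy_mode: str = "none"     # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0         # fraction of exposure SNPs given alpha != 0
    inside_violation: bool = False    # correlate alpha with gamma (breaks InSIDE)
    ld_block_size: int = 1
    within_block_r2: float = 0.0
    prop_palindromic: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 3:
            raise ConfigError("m_snps must be >= 3")
        if self.m_mediator_snps < 0:
            raise ConfigError("m_mediator_snps must be >= 0")
        for name in ("prop_invalid", "prop_palindromic", "within_block_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta_exposure_sd", "beta_mediator_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("n_exposure", "n_mediator", "n_cases", "n_controls"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")

    @property
    def theta_direct(self) -> float:
        """Direct effect, derived so total = direct + em*mo holds exactly."""
        return self.theta_total - self.theta_em * self.theta_mo

    @property
    def n_outcome_effective(self) -> float:
        """Effective sample size of the case-control outcome GWAS."""
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated triplet.

    ``effects`` has one row per SNP: snp_id, gamma (true marginal effect on
    the exposure), delta (true mediator-specific effect), alpha (pleiotropic
    outcome effect) and invalid flag.
    """

    effects: pd.DataFrame
    theta_total: float
    theta_direct: float
    theta_em: float
    theta_mo: float
    proportion_mediated: float

    @property
    def invalid_ids(self) -> list[str]:
        return list(self.effects.loc[self.effects.invalid, "snp_id"])


def _layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic SNP ids / positions / block structure for a config."""
    m = config.m_snps + config.m_mediator_snps
    idx = np.arange(m)
    block = idx // config.ld_block_size
    within = idx % config.ld_block_size
    chrom = (block % _CHROMOSOMES) + 1
    pos = 1_000_000 + (block // _CHROMOSOMES) * _BLOCK_SPACING_BP \
        + within * _WITHIN_BLOCK_SPACING_BP
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in idx],
            "chrom": chrom.astype(str),
            "pos": pos.astype(np.int64),
            "block": block,
            "is_lead": within == 0,
            "role": np.where(idx < config.m_snps, "exposure", "mediator"),
        }
    )


def _observed(truth: np.ndarray, se: np.ndarray, noise: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Published beta and two-sided normal p-value given truth, SE and z-noise."""
    beta = truth + se * noise
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    # keep p strictly inside (0, 1] so validation never rejects a simulated row
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, pval


def _block_noise(rng: np.random.Generator, block: np.ndarray, r: float) -> np.ndarray:
    """Z-scores with pairwise correlation r**2 inside each LD block."""
    m = len(block)
    own = rng.standard_normal(m)
    if r == 0.0:
        return own
    n_blocks = block.max() + 1
    common = rng.standard_normal(n_blocks)
    return r * common[block] + np.sqrt(1.0 - r * r) * own


def simulate_triplet(
    config: SimulationConfig,
) -> tuple[TraitTable, TraitTable, TraitTable, SimulationTruth]:
    """Draw one exposure / mediator / outcome summary-statistic triplet.

    Returns validated :class:`~mrmed.io.TraitTable` objects plus the ground
    truth. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    m = len(lay)
    is_exp = (lay.role == "exposure").to_numpy()
    block = lay.block.to_numpy()
    r = float(np.sqrt(config.within_block_r2))

    maf = rng.uniform(*config.maf_range, size=m)

    # allele pairs; a fixed fraction palindromic
    pal = rng.random(m) < config.prop_palindromic
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.where(
        pal,
        np.array([p[0] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[0] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )
    oa = np.where(
        pal,
        np.array([p[1] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[1] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )

    # true causal effects at block leads; non-lead marginals attenuated by r
    n_blocks = block.max() + 1
    lead_gamma = rng.normal(0.0, config.beta_exposure_sd, size=n_blocks)
    lead_delta = rng.normal(0.0, config.beta_mediator_sd, size=n_blocks)
    load = np.where(lay.is_lead.to_numpy(), 1.0, r)
    gamma = np.where(is_exp, lead_gamma[block] * load, 0.0)
    delta = np.where(~is_exp, lead_delta[block] * load, 0.0)

    # horizontal pleiotropy on the outcome path (exposure SNPs only)
    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    if config.pleiotropy_mode != "none" and config.prop_invalid > 0:
        cand = np.flatnonzero(is_exp)
        n_inv = int(round(config.prop_invalid * len(cand)))
        chosen = rng.choice(cand, size=n_inv, replace=False)
        invalid[chosen] = True
        draw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_inv)
        if config.pleiotropy_mode == "balanced":
            draw = rng.normal(0.0, config.pleiotropy_sd, size=n_inv)
        if config.inside_violation:
            # tie pleiotropy magnitude to instrument strength (breaks InSIDE)
            draw = draw + np.abs(gamma[chosen])
        if config.pleiotropy_mode == "directional":
            # directional relative to the exposure-increasing allele
            draw = draw * np.where(gamma[chosen] >= 0, 1.0, -1.0)
        alpha[chosen] = draw

    # true marginal effects per trait
    truth_exp = gamma
    truth_med = gamma * config.theta_em + delta
    truth_out = gamma * config.theta_total + delta * config.theta_mo + alpha

    den = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(config.n_exposure * den)
    se_med = 1.0 / np.sqrt(config.n_mediator * den)
    se_out = 1.0 / np.sqrt(config.n_outcome_effective * den)

    beta_exp, p_exp = _observed(truth_exp, se_exp, _block_noise(rng, block, r))
    beta_med, p_med = _observed(truth_med, se_med, _block_noise(rng, block, r))
    beta_out, p_out = _observed(truth_out, se_out, _block_noise(rng, block, r))

    eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)

    def table(trait_id, trait_type, beta, se, pval, n, **meta) -> TraitTable:
        frame = pd.DataFrame(
            {
                "snp_id": lay.snp_id,
                "chrom": lay.chrom,
                "pos": lay.pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": float(n),
            }
        )
        return TraitTable(trait_id=trait_id, trait_type=trait_type, records=frame, **meta)

    exposure = table("sim_exposure", "exposure", beta_exp, se_exp, p_exp, config.n_exposure)
    mediator = table("sim_mediator", "mediator", beta_med, se_med, p_med, config.n_mediator)
    outcome = table(
        "sim_outcome",
        "outcome",
        beta_out,
        se_out,
        p_out,
        config.n_outcome_effective,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )

    indirect = config.theta_em * config.theta_mo
    if config.theta_total != 0.0:
        prop = indirect / config.theta_total
    else:
        prop = 0.0 if indirect == 0.0 else float("nan")
    truth = SimulationTruth(
        effects=pd.DataFrame(
            {
                "snp_id": lay.snp_id,
                "gamma": gamma,
                "delta": delta,
                "alpha": alpha,
                "invalid": invalid,
            }
        ),
        theta_total=config.theta_total,
        theta_direct=config.theta_direct,
        theta_em=config.theta_em,
        theta_mo=config.theta_mo,
        proportion_mediated=prop,
    )
    return exposure, mediator, outcome, truth


def emit_ld_table(config: SimulationConfig) -> pd.DataFrame:
    """Pairwise LD (r-squared) table consistent with the block structure.

    Emits the diagonal (r2 = 1) and both orientations of every within-block
    pair (r2 = ``within_block_r2``); absent pairs are r2 = 0 by convention.
    """
    lay = _layout(config)
    rows_i, rows_j, r2 = [], [], []
    ids = lay.snp_id.to_numpy()
    for snp in ids:
        rows_i.append(snp)
        rows_j.append(snp)
        r2.append(1.0)
    if config.ld_block_size > 1 and config.within_block_r2 > 0:
        for _, grp in lay.groupby("block"):
            members = grp.snp_id.to_numpy()
            for a in range(len(members)):
                for b in range(len(members)):
                    if a != b:
                        rows_i.append(members[a])
                        rows_j.append(members[b])
                        r2.append(config.within_block_r2)
    return pd.DataFrame({"snp_i": rows_i, "snp_j": rows_j, "r2": r2})


def simulate_screen(
    n_exposures: int,
    thetas: Sequence[float],
    config: SimulationConfig,
) -> tuple[list[TraitTable], TraitTable, SimulationTruth]:
    """Simulate a batch of exposures against one shared outcome.

    Exposure ``k`` gets its own disjoint SNP panel (so instrument sets do not
    collide) and total effect ``thetas[k]``; the outcome table stacks all
    panels. Used for screening-scale validation; mediator tables are not
    produced.
    """
    if len(thetas) != n_exposures:
        raise ConfigError("need one theta per exposure")
    seeds = np.random.SeedSequence(config.seed).spawn(n_exposures)
    exposures: list[TraitTable] = []
    outcome_parts: list[pd.DataFrame] = []
    effect_parts: list[pd.DataFrame] = []
    for k, (theta, ss) in enumerate(zip(thetas, seeds)):
        sub = config.with_(
            theta_total=float(theta),
            theta_em=0.0,
            theta_mo=0.0,
            m_mediator_snps=0,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        exp_t, _med, out_t, truth = simulate_triplet(sub)
        prefix = f"e{k:03d}_"
        for t in (exp_t, out_t):
            t.records["snp_id"] = prefix + t.records["snp_id"]
        truth.effects["snp_id"] = prefix + truth.effects["snp_id"]
        # keep panels apart genomically as well
        exp_t.records["chrom"] = exp_t.records["chrom"].astype(str)
        exp_t.trait_id = f"exposure_{k:03d}"
        exposures.append(exp_t)
        outcome_parts.append(out_t.records)
        eff = truth.effects.copy()
        eff["exposure_id"] = exp_t.trait_id
        eff["theta_total"] = theta
        effect_parts.append(eff)
    outcome = TraitTable(
        trait_id="sim_outcome",
        trait_type="outcome",
        records=pd.concat(outcome_parts, ignore_index=True),
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    truth_all = SimulationTruth(
        effects=pd.concat(effect_parts, ignore_index=True),
        theta_total=float("nan"),
        theta_direct=float("nan"),
        theta_em=0.0,
        theta_mo=0.0,
        proportion_mediated=0.0,
    )
    return exposures, outcome, truth_all
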