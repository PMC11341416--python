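"""Two-step MR mediation: total effect split into direct and indirect parts.

The indirect effect is the product of coefficients
``beta_em * beta_mo`` (exposure -> mediator times mediator -> outcome), the
direct effect is ``beta_total - indirect`` and the proportion mediated is
``indirect / beta_total``. These identities hold exactly for every output.

The indirect-effect SE is the first-order delta method
``sqrt(beta_em^2 * se_mo^2 + beta_mo^2 * se_em^2)``; a seeded Monte-Carlo
alternative (resampling the two leg betas from their sampling
distributions) is provided as a cross-check. The proportion CI propagates
``indirect_se / |beta_total|``, a documented first-order approximation that
ignores the total-effect uncertainty.

``run_two_step`` fits the three legs with their own instrument selection.
Each leg defaults to IVW but falls back to the weighted median when the
Egger intercept test signals horizontal pleiotropy (p < 0.05), the rule the
motivating screening design applies to pleiotropic pairs. beta_mo comes
from univariable MR of the mediator on the outcome; no multivariable
adjustment for the exposure is performed (a known limitation of the
product-of-coefficients design, documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientInstrumentsError, MediationLegError
from .estimators import (
    MREstimate,
    SensitivityReport,
    Z95,
    ivw,
    mr_all,
    sensitivity_report,
    weighted_median,
    mode_estimate,
    egger,
)
from .instruments import SelectionParams, harmonize
from .io import TraitTable


@dataclass
class MediationResult:
    """Total / direct / indirect decomposition with uncertainty."""

    beta_total: float
    se_total: float
    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    indirect: float
    indirect_se: float
    direct: float
    proportion_mediated: float
    proportion_lci95: float
    proportion_uci95: float
    proportion_defined: bool


@dataclass
class MediationLeg:
    """One leg's estimate plus its diagnostics."""

    estimate: MREstimate
    report: SensitivityReport
    method_used: str
    fallback_fired: bool
    nsnp: int


@dataclass
class TwoStepResult:
    """Full two-step pipeline output: decomposition plus per-leg detail."""

    result: MediationResult
    total: MediationLeg
    exposure_mediator: MediationLeg
    mediator_outcome: MediationLeg


def decompose(total: MREstimate, em: MREstimate, mo: MREstimate) -> MediationResult:
    """Product-of-coefficients decomposition from three fitted legs.

    When the total effect is exactly zero the proportion mediated is
    undefined; indirect and direct are still returned and
    ``proportion_defined`` is False.
    """
    indirect = em.beta * mo.beta
    indirect_se = float(np.sqrt(em.beta**2 * mo.se**2 + mo.beta**2 * em.se**2))
    direct = total.beta - indirect
    if total.beta != 0.0:
        prop = indirect / total.beta
        prop_se = indirect_se / abs(total.beta)
        lo, hi = prop - Z95 * prop_se, prop + Z95 * prop_se
        defined = True
    else:
        prop, lo, hi = float("nan"), float("nan"), float("nan")
        defined = False
    return MediationResult(
        beta_total=total.beta,
        se_total=total.se,
        beta_em=em.beta,
        se_em=em.se,
        beta_mo=mo.beta,
        se_mo=mo.se,
        indirect=float(indirect),
        indirect_se=indirect_se,
        direct=float(direct),
        proportion_mediated=prop,
        proportion_lci95=lo,
        proportion_uci95=hi,
        proportion_defined=defined,
    )


def indirect_se_monte_carlo(
    em: MREstimate, mo: MREstimate, n_draws: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo SE of the product beta_em * beta_mo.

    Draws each leg beta from its normal sampling distribution and returns
    the SD of the products — the cross-check for the delta-method SE.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(em.beta, em.se, n_draws)
    b = rng.normal(mo.beta, mo.se, n_draws)
    return float(np.std(a * b, ddof=1))


def _fit_leg(
    exposure: TraitTable,
    outcome: TraitTable,
    params: SelectionParams,
    ld,
    method: str,
    n_boot: int,
    seed: int,
    egger_alpha: float,
    fallback: bool,
    leg_name: str,
) -> MediationLeg:
    try:
        h = harmonize(exposure, outcome, params=params, ld=ld)
        if h.nsnp < 2:
            raise InsufficientInstrumentsError(h.nsnp, 2, context=leg_name)
        report = sensitivity_report(h)
        fired = False
        use = method
        if (
            fallback
            and h.nsnp >= 3
            and np.isfinite(report.egger_intercept_pval)
            and report.egger_intercept_pval < egger_alpha
        ):
            use = "weighted_median"
            fired = use != method
        est = _single_method(h, use, n_boot, seed)
        return MediationLeg(
            estimate=est,
            report=report,
            method_used=use,
            fallback_fired=fired,
            nsnp=h.nsnp,
        )
    except InsufficientInstrumentsError as err:
        raise MediationLegError(leg_name, err) from err


def _single_method(h, method: str, n_boot: int, seed: int) -> MREstimate:
    if method == "ivw":
        return ivw(h)
    if method == "egger":
        return egger(h).slope
    if method == "weighted_median":
        return weighted_median(h, n_boot=n_boot, seed=seed)
    if method == "simple_mode":
        return mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed)
    if method == "weighted_mode":
        return mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed)
    raise ValueError(f"unknown estimator {method!r}")


def run_two_step(
    exposure: TraitTable,
    mediator: TraitTable,
    outcome: TraitTable,
    params: SelectionParams | None = None,
    ld=None,
    method: str = "ivw",
    n_boot: int = 1000,
    seed: int = 0,
    egger_alpha: float = 0.05,
    fallback: bool = True,
) -> TwoStepResult:
    """Three univariable MR fits plus the decomposition.

    Legs: exposure -> outcome (total), exposure -> mediator (beta_em),
    mediator -> outcome (beta_mo), each with its own instrument selection on
    the respective exposure-side trait. Raises
    :class:`~mrmed.errors.MediationLegError` naming the failing leg when one
    has too few instruments.
    """
    params = params or SelectionParams()
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(3)]
    total = _fit_leg(exposure, outcome, params, ld, method, n_boot, seeds[0],
                     egger_alpha, fallback, "total")
    em = _fit_leg(exposure, mediator, params, ld, method, n_boot, seeds[1],
                  egger_alpha, fallback, "exposure_mediator")
    mo = _fit_leg(mediator, outcome, params, ld, method, n_boot, seeds[2],
                  egger_alpha, fallback, "mediator_outcome")
    result = decompose(total.estimate, em.estimate, mo.estimate)
    return TwoStepResult(
        result=result,
        total=total,
        exposure_mediator=em,
        mediator_outcome=mo,
    )
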