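"""Two-sample MR estimators and sensitivity diagnostics.

All multi-SNP estimators consume a :class:`~mrmed.instruments.HarmonizedSet`
and return an :class:`MREstimate` whose odds-ratio columns are derived from
the log-odds beta and its SE by construction:

    or       = exp(beta)
    or_lci95 = exp(beta - 1.959964 * se)
    or_uci95 = exp(beta + 1.959964 * se)

P-values are two-sided normal for IVW, the weighted median and the mode
estimators, and Student t with nsnp - 2 degrees of freedom for MR-Egger.

Weights are first-order throughout: the Wald ratio for SNP j is
Gamma_j / gamma_j with weight w_j = gamma_j^2 / sigma_yj^2, i.e. the
uncertainty in the SNP-exposure association is ignored (the NO Measurement
Error approximation). IVW applies a multiplicative random-effects inflation
sqrt(Q/df) to its SE only when Cochran's Q exceeds its degrees of freedom,
mirroring the dual fixed/random behaviour of standard MR tooling; the
estimate reports which rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .instruments import HarmonizedSet

#: 97.5% normal quantile used for every 95% interval in the package.
Z95 = 1.959964

#: Display names used in result tables.
METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw": "Inverse variance weighted",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


@dataclass
class MREstimate:
    """One method's causal estimate — one row of a standard MR result table."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    or_: float
    or_lci95: float
    or_uci95: float
    random_effects: bool = False  # IVW only: whether sqrt(Q/df) inflation fired

    @classmethod
    def _build(cls, method, nsnp, beta, se, pval, **kw) -> "MREstimate":
        beta = float(beta)
        se = float(se)
        return cls(
            method=method,
            nsnp=int(nsnp),
            beta=beta,
            se=se,
            pval=float(pval),
            or_=float(np.exp(beta)),
            or_lci95=float(np.exp(beta - Z95 * se)),
            or_uci95=float(np.exp(beta + Z95 * se)),
            **kw,
        )

    @classmethod
    def from_normal(cls, method, nsnp, beta, se, **kw) -> "MREstimate":
        """Estimate with a two-sided normal p-value."""
        if se > 0 and np.isfinite(se):
            pval = 2.0 * stats.norm.sf(abs(beta / se))
        else:
            pval = float("nan")
        return cls._build(method, nsnp, beta, se, pval, **kw)

    @classmethod
    def from_t(cls, method, nsnp, beta, se, df, **kw) -> "MREstimate":
        """Estimate with a two-sided t p-value on ``df`` degrees of freedom."""
        if se > 0 and np.isfinite(se) and df > 0:
            pval = 2.0 * stats.t.sf(abs(beta / se), df)
        else:
            pval = float("nan")
        return cls._build(method, nsnp, beta, se, pval, **kw)


@dataclass
class EggerResult:
    """MR-Egger slope plus the intercept pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    q: float
    q_df: int


@dataclass
class SteigerResult:
    """Directionality check: does the instrument set explain more variance
    in the exposure than in the outcome?"""

    direction: bool  # True = exposure -> outcome orientation supported
    pval: float
    r2_exposure: float
    r2_outcome: float


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy, directionality and leave-one-out, bundled."""

    cochran_q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    steiger_direction: bool
    steiger_pval: float
    leave_one_out: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "beta", "se", "outlier"])
    )


def _arrays(h: HarmonizedSet):
    t = h.table
    return (
        t["beta_exp"].to_numpy(dtype=float),
        t["se_exp"].to_numpy(dtype=float),
        t["beta_out"].to_numpy(dtype=float),
        t["se_out"].to_numpy(dtype=float),
    )


def _require(h: HarmonizedSet, n_required: int, op: str) -> None:
    if h.nsnp < n_required:
        raise InsufficientInstrumentsError(h.nsnp, n_required, context=op)


def wald_ratio(beta_exp, se_exp, beta_out, se_out) -> MREstimate:
    """Single-SNP causal estimate: beta_out / beta_exp.

    The SE is the first-order delta approximation |se_out / beta_exp|, which
    ignores the exposure-side uncertainty (adequate for instruments passing
    an F >= 10 filter).
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    beta = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return MREstimate.from_normal("wald_ratio", 1, beta, se)


def _ivw_core(bx, by, sy):
    w = bx**2 / sy**2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q, w, ratios


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    Fixed-effect SE ``1/sqrt(sum w)``; inflated multiplicatively by
    ``sqrt(Q/df)`` when Cochran's Q exceeds its df (multiplicative
    random-effects model). ``random_effects`` records which rule fired.
    """
    _require(h, 2, "ivw")
    bx, _sx, by, sy = _arrays(h)
    beta, se_fixed, q, _w, _r = _ivw_core(bx, by, sy)
    df = len(bx) - 1
    inflate = q > df
    se = se_fixed * float(np.sqrt(q / df)) if inflate else se_fixed
    return MREstimate.from_normal("ivw", len(bx), beta, se, random_effects=bool(inflate))


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic about the fixed-effect IVW mean."""
    _require(h, 2, "cochran_q")
    bx, _sx, by, sy = _arrays(h)
    _beta, _se, q, _w, _r = _ivw_core(bx, by, sy)
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas with
    an intercept, after orienting every SNP to a non-negative exposure beta.

    A non-zero intercept estimates the average directional pleiotropy per
    instrument. Coefficient SEs are scaled by max(1, sqrt(Q_egger/(n-2)))
    and p-values use t(n-2).
    """
    _require(h, 3, "egger")
    bx, _sx, by, sy = _arrays(h)
    n = len(bx)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    try:
        cov_unscaled = np.linalg.inv(XtW @ X)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "MR-Egger needs variation in the exposure betas "
            "(constant |beta_exp| makes the regression singular)"
        ) from err
    coef = cov_unscaled @ (XtW @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (n - 2))
    se = np.sqrt(np.diag(cov_unscaled) * phi)
    slope = MREstimate.from_t("egger", n, coef[1], se[1], n - 2)
    icp_p = 2.0 * stats.t.sf(abs(coef[0] / se[0]), n - 2) if se[0] > 0 else float("nan")
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=float(icp_p),
        q=q,
        q_df=n - 2,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def _bootstrap_draws(rng, bx, sx, by, sy, n_boot):
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(bx)))
    return bxs, bys


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator: consistent when valid instruments carry
    at least half the total weight.

    The point estimate is the ratio at cumulative normalized weight 0.5
    (linear interpolation between bracketing order statistics), weights
    being the first-order inverse ratio variances. The SE comes from a
    seeded parametric bootstrap resampling the per-SNP betas from their
    sampling distributions; pass ``n_boot=0`` to skip it (SE and p become
    NaN).
    """
    _require(h, 3, "weighted_median")
    bx, sx, by, sy = _arrays(h)
    w = bx**2 / sy**2
    beta = _weighted_median_point(by / bx, w)
    se = float("nan")
    if n_boot:
        rng = np.random.default_rng(seed)
        bxs, bys = _bootstrap_draws(rng, bx, sx, by, sy, n_boot)
        rs = bys / bxs
        ws = bxs**2 / sy**2
        order = np.argsort(rs, axis=1)
        r_sorted = np.take_along_axis(rs, order, axis=1)
        w_sorted = np.take_along_axis(ws, order, axis=1)
        cum = (np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted) / np.sum(
            w_sorted, axis=1, keepdims=True
        )
        boots = np.array(
            [np.interp(0.5, cum[i], r_sorted[i]) for i in range(n_boot)]
        )
        se = float(boots.std(ddof=1))
    return MREstimate.from_normal("weighted_median", len(bx), beta, se)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    s = 0.9 * min(sd, mad) * n ** (-0.2)
    if s <= 0 or not np.isfinite(s):
        s = 0.9 * sd * n ** (-0.2)  # MAD degenerate (>=half the ratios tied)
    h_ = bandwidth_factor * s
    if h_ <= 0 or not np.isfinite(h_):
        return float(ratios[0])  # all ratios identical
    lo = ratios.min() - 3.0 * h_
    hi = ratios.max() + 3.0 * h_
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h_) ** 2) @ weights
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate: the argmax of a kernel-smoothed density of the
    per-SNP ratios (consistent when the largest group of instruments shares
    the true effect — the ZEMPA assumption).

    Normal kernel; bandwidth is ``bandwidth_factor`` times the modified
    Silverman scale 0.9 * min(sd, 1.4826*MAD) * n^(-1/5); the density is
    evaluated on a 512-point grid spanning the ratios +/- 3 bandwidths. The
    weighted variant weights each kernel by the first-order inverse ratio
    variance. SE by seeded parametric bootstrap (``n_boot=0`` skips it).
    """
    _require(h, 3, "mode_estimate")
    bx, sx, by, sy = _arrays(h)
    ratios = by / bx
    weights = bx**2 / sy**2 if weighted else np.ones(len(bx))
    beta = _mode_point(ratios, weights, bandwidth_factor)
    se = float("nan")
    if n_boot:
        rng = np.random.default_rng(seed)
        bxs, bys = _bootstrap_draws(rng, bx, sx, by, sy, n_boot)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            wi = bxs[i] ** 2 / sy**2 if weighted else weights
            boots[i] = _mode_point(bys[i] / bxs[i], wi, bandwidth_factor)
        se = float(boots.std(ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate.from_normal(method, len(bx), beta, se)


def steiger(h: HarmonizedSet, n_exp=None, n_out=None) -> SteigerResult:
    """Directionality test comparing instrument variance explained in the
    exposure versus the outcome.

    Per-SNP variance explained is recovered from the z-statistic as
    r^2 = z^2 / (z^2 + n - 2) and summed over instruments per trait. The
    correct orientation (exposure -> outcome) is supported when the
    instruments explain more of the exposure. The p-value is a Fisher-z test
    on the two multiple correlations, treating the two GWAS as independent
    samples (they are non-overlapping cohorts in the two-sample design).
    Sample sizes default to the per-SNP n columns of the harmonized table.
    """
    t = h.table
    n_exp_arr = np.full(h.nsnp, float(n_exp)) if n_exp is not None else t["n_exp"].to_numpy(float)
    n_out_arr = np.full(h.nsnp, float(n_out)) if n_out is not None else t["n_out"].to_numpy(float)
    if np.any(~np.isfinite(n_exp_arr)) or np.any(~np.isfinite(n_out_arr)):
        raise ValueError("sample sizes required for the Steiger test")
    bx, sx, by, sy = _arrays(h)
    zx = bx / sx
    zy = by / sy
    r2x = float(np.sum(zx**2 / (zx**2 + n_exp_arr - 2)))
    r2y = float(np.sum(zy**2 / (zy**2 + n_out_arr - 2)))
    rx = np.sqrt(min(r2x, 1.0 - 1e-12))
    ry = np.sqrt(min(r2y, 1.0 - 1e-12))
    fz_x = np.arctanh(rx)
    fz_y = np.arctanh(ry)
    se = np.sqrt(1.0 / (np.mean(n_exp_arr) - 3) + 1.0 / (np.mean(n_out_arr) - 3))
    z = (fz_x - fz_y) / se
    return SteigerResult(
        direction=bool(r2x > r2y),
        pval=float(2.0 * stats.norm.sf(abs(z))),
        r2_exposure=r2x,
        r2_outcome=r2y,
    )


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW re-estimated with each instrument dropped in turn.

    Returns one row per SNP: snp_id, beta, se, outlier. ``outlier`` flags
    drops whose beta falls outside the full-set IVW 95% CI — a crude
    influence screen matching the usual leave-one-out plot.
    """
    _require(h, 3, "leave_one_out")
    bx, _sx, by, sy = _arrays(h)
    beta_full, se_fixed_full, q_full, w, r = _ivw_core(bx, by, sy)
    n = len(bx)
    sw = np.sum(w)
    swr = np.sum(w * r)
    swr2 = np.sum(w * r**2)
    den = sw - w
    num = swr - w * r
    beta_i = num / den
    se_fixed_i = den**-0.5
    # Q with SNP i removed, about beta_i
    q_i = (swr2 - w * r**2) - 2.0 * beta_i * num + beta_i**2 * den
    q_i = np.maximum(q_i, 0.0)  # guard float cancellation at Q ~ 0
    df_i = n - 2
    inflate = q_i > df_i
    se_i = np.where(inflate, se_fixed_i * np.sqrt(q_i / df_i), se_fixed_i)

    full = ivw(h)
    lo, hi = full.beta - Z95 * full.se, full.beta + Z95 * full.se
    return pd.DataFrame(
        {
            "snp_id": h.table["snp_id"].to_numpy(),
            "beta": beta_i,
            "se": se_i,
            "outlier": (beta_i < lo) | (beta_i > hi),
        }
    )


def sensitivity_report(h: HarmonizedSet) -> SensitivityReport:
    """Bundle Q, the Egger intercept test, Steiger direction and
    leave-one-out into one report (requires >= 3 instruments for the Egger
    and leave-one-out parts, which are NaN/empty below that)."""
    q, q_df, q_p = cochran_q(h)
    st = steiger(h)
    if h.nsnp >= 3:
        try:
            eg = egger(h)
            icp, icp_se, icp_p = eg.intercept, eg.intercept_se, eg.intercept_pval
        except ValueError:  # degenerate exposure betas
            icp = icp_se = icp_p = float("nan")
        loo = leave_one_out(h)
    else:
        loo = pd.DataFrame(columns=["snp_id", "beta", "se", "outlier"])
        icp = icp_se = icp_p = float("nan")
    return SensitivityReport(
        cochran_q=q,
        q_df=q_df,
        q_pval=q_p,
        egger_intercept=icp,
        egger_intercept_se=icp_se,
        egger_intercept_pval=icp_p,
        steiger_direction=st.direction,
        steiger_pval=st.pval,
        leave_one_out=loo,
    )


def mr_all(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = 0,
    bandwidth_factor: float = 1.0,
) -> list[MREstimate]:
    """Fit the full method panel on one harmonized set.

    With a single instrument only the Wald ratio is estimable (IVW with one
    SNP reduces to it anyway); with two, IVW only; with three or more the
    full panel: IVW, MR-Egger, weighted median, simple mode, weighted mode.
    """
    if h.nsnp == 1:
        row = h.table.iloc[0]
        return [wald_ratio(row.beta_exp, row.se_exp, row.beta_out, row.se_out)]
    if h.nsnp == 2:
        return [ivw(h)]
    ss = np.random.SeedSequence(seed)
    s_med, s_smode, s_wmode = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    return [
        ivw(h),
        egger(h).slope,
        weighted_median(h, n_boot=n_boot, seed=s_med),
        mode_estimate(h, weighted=False, bandwidth_factor=bandwidth_factor,
                      n_boot=n_boot, seed=s_smode),
        mode_estimate(h, weighted=True, bandwidth_factor=bandwidth_factor,
                      n_boot=n_boot, seed=s_wmode),
    ]


def estimates_frame(estimates) -> pd.DataFrame:
    """Result table in the conventional layout:
    method, nsnp, pval, Beta, or, or_lci95, or_uci95."""
    rows = [
        {
            "method": METHOD_LABELS.get(e.method, e.method),
            "nsnp": e.nsnp,
            "pval": e.pval,
            "Beta": e.beta,
            "or": e.or_,
            "or_lci95": e.or_lci95,
            "or_uci95": e.or_uci95,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
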