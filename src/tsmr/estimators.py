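"""Estimator kernel: Wald ratios with Fieller limits, fixed-effect IVW,
MR-Egger regression and the weighted median estimator.

All estimators consume harmonized instruments and return :class:`MrEstimate`
records on the exposure's per-unit scale. First-order Wald standard errors
(se_outcome / |gamma|) supply the IVW weights; Fieller limits are attached
per SNP as diagnostics. Confidence intervals use z = 1.96 throughout
(normal theory, no small-sample correction).
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy import stats

from .errors import (
    InsufficientInstrumentsError,
    WeakInstrumentError,
    WeightShareError,
)
from .types import HarmonizedInstrument, MrEstimate, WaldRatio

Z95 = 1.96


def wald_ratio(inst: HarmonizedInstrument, alpha: float = 0.05) -> WaldRatio:
    """Single-SNP ratio estimate with Fieller-theorem confidence limits.

    The ratio is outcome-beta over exposure-beta; its first-order SE is
    ``se_big_gamma / |gamma_hat|``. Fieller limits are the roots in t of

        (g^2 - z^2 sg^2) t^2 - 2 g G t + (G^2 - z^2 sG^2) = 0

    with zero exposure-outcome covariance (two independent samples).
    ``fieller_case`` is ``bounded`` when the leading coefficient and
    discriminant are both positive, ``exclusive`` when the interval is the
    complement of a finite segment, and ``unbounded`` when it is the whole
    real line.
    """
    g, sg = inst.gamma_hat, inst.se_gamma
    G, sG = inst.big_gamma_hat, inst.se_big_gamma
    if g == 0:
        raise WeakInstrumentError(f"{inst.snp_id}: zero SNP-exposure association")
    z = stats.norm.ppf(1 - alpha / 2)

    a = g * g - z * z * sg * sg
    b = -2.0 * g * G
    c = G * G - z * z * sG * sG
    disc = b * b - 4.0 * a * c

    if a > 0 and disc > 0:
        root = math.sqrt(disc)
        low = (-b - root) / (2 * a)
        high = (-b + root) / (2 * a)
        case = "bounded"
    elif a < 0 and disc > 0:
        # CI is the complement of a finite segment:
        # (-inf, fieller_low] U [fieller_high, inf).
        root = math.sqrt(disc)
        low = (-b + root) / (2 * a)  # 2a < 0, so this is the smaller root
        high = (-b - root) / (2 * a)
        case = "exclusive"
    else:
        low, high, case = -math.inf, math.inf, "unbounded"

    return WaldRatio(
        snp_id=inst.snp_id,
        theta_hat=G / g,
        se_theta=sG / abs(g),
        fieller_low=low,
        fieller_high=high,
        fieller_case=case,
    )


def _weights(insts: list[HarmonizedInstrument]) -> np.ndarray:
    """First-order IVW weights 1/se_theta^2 = gamma^2 / se_outcome^2."""
    g = np.array([i.gamma_hat for i in insts], dtype=float)
    sG = np.array([i.se_big_gamma for i in insts], dtype=float)
    if np.any(g == 0):
        bad = insts[int(np.argmax(g == 0))].snp_id
        raise WeakInstrumentError(f"{bad}: zero SNP-exposure association")
    return g * g / (sG * sG)


def max_weight_share(insts: list[HarmonizedInstrument]) -> float:
    """Largest single-SNP share of the total first-order IVW weight."""
    w = _weights(insts)
    return float(np.max(w) / np.sum(w))


def ivw_fixed(insts: list[HarmonizedInstrument]) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    Equivalent to the zero-intercept weighted regression of the outcome
    betas on the exposure betas with weights 1/se_outcome^2 (asserted by
    the test suite's independent oracle).
    """
    if not insts:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    g = np.array([i.gamma_hat for i in insts], dtype=float)
    G = np.array([i.big_gamma_hat for i in insts], dtype=float)
    w = _weights(insts)
    theta = G / g
    total = float(np.sum(w))
    beta = float(np.sum(w * theta) / total)
    se = float(1.0 / math.sqrt(total))
    return MrEstimate(
        method="IVW",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        n_snps=len(insts),
        max_weight_share=float(np.max(w) / total),
    )


def mr_egger(
    insts: list[HarmonizedInstrument], residual_variance: str = "none"
) -> MrEstimate:
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with a free intercept estimating the average directional pleiotropic
    effect.

    Instruments are first oriented so every exposure beta is positive
    (both betas sign-flipped together). ``residual_variance`` selects the
    SE convention: ``"none"`` uses fixed-effect normal-theory SEs,
    ``"multiplicative"`` inflates by the residual standard deviation when
    it exceeds 1.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {len(insts)}"
        )
    if residual_variance not in {"none", "multiplicative"}:
        raise ValueError(f"unknown residual_variance mode {residual_variance!r}")
    g = np.array([i.gamma_hat for i in insts], dtype=float)
    G = np.array([i.big_gamma_hat for i in insts], dtype=float)
    sG = np.array([i.se_big_gamma for i in insts], dtype=float)
    if np.any(g == 0):
        raise WeakInstrumentError("zero SNP-exposure association in MR-Egger input")
    flip = np.sign(g)
    g, G = g * flip, G * flip

    w = 1.0 / (sG * sG)
    X = np.column_stack([np.ones_like(g), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)

    resid = G - X @ coef
    dof = len(insts) - 2
    scale = float(resid @ (w * resid) / dof)
    if residual_variance == "multiplicative":
        cov = cov * max(scale, 1.0)

    intercept, slope = float(coef[0]), float(coef[1])
    se_int = float(math.sqrt(cov[0, 0]))
    se_slope = float(math.sqrt(cov[1, 1]))
    p_int = float(2 * stats.norm.sf(abs(intercept) / se_int))
    w_ivw = _weights(insts)
    return MrEstimate(
        method="MR-Egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - Z95 * se_slope,
        ci_high=slope + Z95 * se_slope,
        n_snps=len(insts),
        max_weight_share=float(np.max(w_ivw) / np.sum(w_ivw)),
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def _interpolated_weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative-weight midpoints."""
    order = np.argsort(theta, kind="stable")
    theta = theta[order]
    w = w[order] / np.sum(w)
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, theta))


def weighted_median_point(insts: list[HarmonizedInstrument]) -> float:
    """Weighted-median point estimate without the bootstrap (no SE).

    Unlike :func:`weighted_median` this does not enforce the 50% weight-share
    precondition; it is intended for simulation summaries.
    """
    g = np.array([i.gamma_hat for i in insts], dtype=float)
    G = np.array([i.big_gamma_hat for i in insts], dtype=float)
    return _interpolated_weighted_median(G / g, _weights(insts))


def weighted_median(
    insts: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted median of the Wald ratios with a parametric-bootstrap SE.

    Consistent when instruments carrying less than half the weight are
    invalid. Sets where a single instrument carries more than half the
    weight are rejected (:class:`WeightShareError`) — the selection rule
    routes those to MR-Egger.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {len(insts)}"
        )
    w = _weights(insts)
    share = w / np.sum(w)
    if np.max(share) > 0.5:
        dominant = insts[int(np.argmax(share))]
        raise WeightShareError(dominant.snp_id, float(np.max(share)))

    g = np.array([i.gamma_hat for i in insts], dtype=float)
    sg = np.array([i.se_gamma for i in insts], dtype=float)
    G = np.array([i.big_gamma_hat for i in insts], dtype=float)
    sG = np.array([i.se_big_gamma for i in insts], dtype=float)
    beta = _interpolated_weighted_median(G / g, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        g_star = rng.normal(g, sg)
        G_star = rng.normal(G, sG)
        g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
        w_star = g_star * g_star / (sG * sG)
        boots[b] = _interpolated_weighted_median(G_star / g_star, w_star)
    se = float(np.std(boots, ddof=1))
    return MrEstimate(
        method="WeightedMedian",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        n_snps=len(insts),
        max_weight_share=float(np.max(share)),
    )


def to_odds_ratio(est: MrEstimate) -> MrEstimate:
    """Exponentiate a log-odds-scale estimate onto the OR scale.

    Only meaningful when the outcome betas are log-odds (binary outcome);
    beta-scale fields are left untouched.
    """
    return replace(
        est,
        or_point=math.exp(est.beta),
        or_low=math.exp(est.ci_low),
        or_high=math.exp(est.ci_high),
    )
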