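import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from tsmr import (
    InsufficientInstrumentsError,
    WeakInstrumentError,
    WeightShareError,
    ivw_fixed,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from tsmr.estimators import Z95

from .conftest import make_inst, random_instruments

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def fieller_limits_grid(g, sg, G, sG, alpha=0.05):
    """Grid+root-search oracle for the Fieller limits: solve the pivotal
    equation (G - t g)^2 / (sG^2 + t^2 sg^2) = z^2 for t."""
    z2 = stats.norm.ppf(1 - alpha / 2) ** 2

    def pivot(t):
        return (G - t * g) ** 2 / (sG**2 + t**2 * sg**2) - z2

    center = G / g
    width = 200 * (sG / abs(g) + abs(center) + 1)
    grid = np.linspace(center - width, center + width, 2_000_001)
    vals = pivot(grid)
    roots = []
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    for i in sign_change:
        roots.append(optimize.brentq(pivot, grid[i], grid[i + 1], xtol=1e-12))
    return sorted(roots)


def ivw_wls_oracle(insts):
    """Zero-intercept WLS of outcome betas on exposure betas, weights 1/sG^2."""
    g = np.array([i.gamma_hat for i in insts])
    G = np.array([i.big_gamma_hat for i in insts])
    sG = np.array([i.se_big_gamma for i in insts])
    w = 1.0 / sG**2
    sw = np.sqrt(w)
    slope, *_ = np.linalg.lstsq((sw * g)[:, None], sw * G, rcond=None)
    se = 1.0 / math.sqrt(float(np.sum(w * g * g)))
    return float(slope[0]), se


def egger_statsmodels_oracle(insts):
    """MR-Egger via statsmodels WLS (fixed-effect SEs: un-scale by sigma)."""
    g = np.array([i.gamma_hat for i in insts])
    G = np.array([i.big_gamma_hat for i in insts])
    sG = np.array([i.se_big_gamma for i in insts])
    flip = np.sign(g)
    g, G = g * flip, G * flip
    fit = sm.WLS(G, sm.add_constant(g), weights=1.0 / sG**2).fit()
    bse_fixed = fit.bse / math.sqrt(fit.scale)
    return {
        "intercept": fit.params[0],
        "slope": fit.params[1],
        "se_intercept": bse_fixed[0],
        "se_slope": bse_fixed[1],
    }


def weighted_median_scan_oracle(insts):
    """Walk cumulative weights in sorted-ratio order and interpolate at 1/2."""
    g = np.array([i.gamma_hat for i in insts])
    G = np.array([i.big_gamma_hat for i in insts])
    sG = np.array([i.se_big_gamma for i in insts])
    theta = G / g
    w = (g / sG) ** 2
    order = np.argsort(theta)
    theta, w = theta[order], w[order] / w.sum()
    cum = 0.0
    positions = []
    for wj in w:
        positions.append(cum + wj / 2.0)
        cum += wj
    positions = np.array(positions)
    if 0.5 <= positions[0]:
        return float(theta[0])
    if 0.5 >= positions[-1]:
        return float(theta[-1])
    j = int(np.searchsorted(positions, 0.5)) - 1
    frac = (0.5 - positions[j]) / (positions[j + 1] - positions[j])
    return float(theta[j] + frac * (theta[j + 1] - theta[j]))


# ---------------------------------------------------------------------------
# Wald ratio and Fieller limits
# ---------------------------------------------------------------------------


class TestWaldRatio:
    def test_unit_denominator(self):
        wr = wald_ratio(make_inst(gamma=1.0, se_gamma=0.1, big_gamma=0.5, se_big_gamma=0.1))
        assert wr.theta_hat == pytest.approx(0.5)
        assert wr.se_theta == pytest.approx(0.1)

    def test_fieller_limits_match_grid_search_oracle(self):
        g, sg, G, sG = 0.2, 0.05, 0.1, 0.02
        wr = wald_ratio(make_inst(gamma=g, se_gamma=sg, big_gamma=G, se_big_gamma=sG))
        roots = fieller_limits_grid(g, sg, G, sG)
        assert len(roots) == 2
        assert wr.fieller_case == "bounded"
        assert wr.fieller_low == pytest.approx(roots[0], abs=1e-6)
        assert wr.fieller_high == pytest.approx(roots[1], abs=1e-6)

    def test_degenerate_denominator_closed_form(self):
        g, G, sG = 0.25, 0.1, 0.02
        wr = wald_ratio(make_inst(gamma=g, se_gamma=1e-12, big_gamma=G, se_big_gamma=sG))
        z = stats.norm.ppf(0.975)
        assert wr.fieller_low == pytest.approx(G / g - z * sG / abs(g), rel=1e-6)
        assert wr.fieller_high == pytest.approx(G / g + z * sG / abs(g), rel=1e-6)

    def test_weak_instrument_exclusive_case(self):
        # |gamma| below noise, strong outcome signal: CI excludes a segment
        wr = wald_ratio(make_inst(gamma=0.01, se_gamma=0.05, big_gamma=0.5, se_big_gamma=0.02))
        assert wr.fieller_case == "exclusive"
        assert wr.fieller_low < wr.fieller_high
        # the point estimate lies in the accepted (outer) region
        assert wr.theta_hat <= wr.fieller_low or wr.theta_hat >= wr.fieller_high

    def test_weak_instrument_unbounded_case(self):
        wr = wald_ratio(make_inst(gamma=0.01, se_gamma=0.05, big_gamma=0.001, se_big_gamma=0.05))
        assert wr.fieller_case == "unbounded"
        assert wr.fieller_low == -math.inf and wr.fieller_high == math.inf

    def test_zero_gamma_raises(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(make_inst(gamma=0.0))

    @settings(max_examples=40, deadline=None)
    @given(
        g=st.floats(min_value=0.05, max_value=1.0),
        sg=st.floats(min_value=0.001, max_value=0.02),
        G=st.floats(min_value=-0.5, max_value=0.5),
        sG=st.floats(min_value=0.001, max_value=0.1),
    )
    def test_bounded_limits_bracket_estimate(self, g, sg, G, sG):
        wr = wald_ratio(make_inst(gamma=g, se_gamma=sg, big_gamma=G, se_big_gamma=sG))
        if wr.fieller_case == "bounded":
            assert wr.fieller_low <= wr.theta_hat <= wr.fieller_high


class TestFiellerCoverage:
    def test_95_interval_covers_truth(self):
        # strong instrument (gamma / se_gamma >= 10): empirical coverage 95% +/- 1%
        rng = np.random.default_rng(12345)
        n = 10_000
        gamma, se_g = 0.5, 0.05
        theta, se_G = 0.4, 0.08
        g_hat = rng.normal(gamma, se_g, n)
        G_hat = rng.normal(theta * gamma, se_G, n)
        covered = 0
        for g, G in zip(g_hat, G_hat):
            wr = wald_ratio(make_inst(gamma=g, se_gamma=se_g, big_gamma=G, se_big_gamma=se_G))
            if wr.fieller_case == "bounded":
                inside = wr.fieller_low <= theta <= wr.fieller_high
            elif wr.fieller_case == "exclusive":
                inside = theta <= wr.fieller_low or theta >= wr.fieller_high
            else:
                inside = True
            covered += inside
        assert covered / n == pytest.approx(0.95, abs=0.01)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


class TestIvwFixed:
    def test_single_instrument_reduction(self):
        inst = make_inst(gamma=0.2, se_gamma=0.05, big_gamma=0.1, se_big_gamma=0.02)
        est = ivw_fixed([inst])
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.02 / 0.2)
        assert est.max_weight_share == 1.0
        assert est.n_snps == 1

    def test_replication_symmetry(self):
        inst = make_inst(gamma=0.2, big_gamma=0.1, se_big_gamma=0.02)
        k = 4
        single = ivw_fixed([inst])
        clones = [make_inst(f"rs{i}", gamma=0.2, big_gamma=0.1, se_big_gamma=0.02) for i in range(k)]
        est = ivw_fixed(clones)
        assert est.beta == pytest.approx(single.beta)
        assert est.se == pytest.approx(single.se / math.sqrt(k))

    def test_agrees_with_zero_intercept_wls_oracle(self, rng):
        insts = random_instruments(rng, 12)
        est = ivw_fixed(insts)
        slope, se = ivw_wls_oracle(insts)
        assert est.beta == pytest.approx(slope, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed([])

    def test_zero_gamma_rejected(self):
        with pytest.raises(WeakInstrumentError, match="rs0"):
            ivw_fixed([make_inst("rs0", gamma=0.0), make_inst("rs1")])


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


class TestMrEgger:
    def _exact(self, slope, intercept):
        gs = [0.1, 0.2, 0.3, 0.4, 0.5]
        return [
            make_inst(f"rs{i}", gamma=g, big_gamma=intercept + slope * g, se_big_gamma=0.05)
            for i, g in enumerate(gs)
        ]

    def test_exact_fit_through_origin(self):
        est = mr_egger(self._exact(0.4, 0.0))
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        est = mr_egger(self._exact(0.4, 0.02))
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)

    def test_agrees_with_statsmodels_oracle(self, rng):
        insts = random_instruments(rng, 5)
        est = mr_egger(insts)
        ref = egger_statsmodels_oracle(insts)
        assert est.beta == pytest.approx(ref["slope"], rel=1e-9)
        assert est.egger_intercept == pytest.approx(ref["intercept"], rel=1e-9)
        assert est.se == pytest.approx(ref["se_slope"], rel=1e-9)
        assert est.egger_intercept_se == pytest.approx(ref["se_intercept"], rel=1e-9)

    def test_intercept_p_is_two_sided_normal(self, rng):
        insts = random_instruments(rng, 8)
        est = mr_egger(insts)
        expected = 2 * stats.norm.sf(abs(est.egger_intercept) / est.egger_intercept_se)
        assert est.egger_intercept_p == pytest.approx(expected, rel=1e-12)

    def test_multiplicative_mode_never_deflates(self, rng):
        insts = random_instruments(rng, 10)
        none = mr_egger(insts, residual_variance="none")
        mult = mr_egger(insts, residual_variance="multiplicative")
        assert mult.se >= none.se
        assert mult.beta == pytest.approx(none.beta)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([make_inst("rs1"), make_inst("rs2")])

    def test_negative_gamma_orientation(self):
        # flipping gamma and Gamma together is a no-op after re-orientation
        insts = self._exact(0.4, 0.02)
        flipped = [
            make_inst(i.snp_id, gamma=-i.gamma_hat, se_gamma=i.se_gamma,
                      big_gamma=-i.big_gamma_hat, se_big_gamma=i.se_big_gamma)
            for i in insts[:2]
        ] + insts[2:]
        est = mr_egger(flipped)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


class TestWeightedMedian:
    def test_equal_weights_odd_count(self):
        insts = [
            make_inst("rs1", gamma=1.0, big_gamma=0.1, se_big_gamma=1.0),
            make_inst("rs2", gamma=1.0, big_gamma=0.3, se_big_gamma=1.0),
            make_inst("rs3", gamma=1.0, big_gamma=0.9, se_big_gamma=1.0),
        ]
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_matches_cumulative_scan_oracle(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, int(rng.integers(3, 15)))
            try:
                est = weighted_median(insts, n_boot=10, seed=1)
            except WeightShareError:
                continue
            assert est.beta == pytest.approx(weighted_median_scan_oracle(insts), abs=1e-12)

    def test_dominant_snp_routed_away(self):
        insts = [
            make_inst("rs_big", gamma=2.0, big_gamma=1.0, se_big_gamma=0.1),
            make_inst("rs2", gamma=0.1, big_gamma=0.05, se_big_gamma=0.1),
            make_inst("rs3", gamma=0.1, big_gamma=0.05, se_big_gamma=0.1),
        ]
        with pytest.raises(WeightShareError, match="rs_big"):
            weighted_median(insts, n_boot=10, seed=0)

    def test_bootstrap_se_reproducible(self, rng):
        insts = random_instruments(rng, 8)
        a = weighted_median(insts, n_boot=200, seed=42)
        b = weighted_median(insts, n_boot=200, seed=42)
        assert a == b
        c = weighted_median(insts, n_boot=200, seed=43)
        assert c.se != a.se  # different seed perturbs the bootstrap

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([make_inst("rs1"), make_inst("rs2")], n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# Odds-ratio conversion
# ---------------------------------------------------------------------------


class TestToOddsRatio:
    def _est(self, beta, se):
        return ivw_fixed([make_inst(gamma=1.0, big_gamma=beta, se_big_gamma=se)])

    def test_null_effect(self):
        est = to_odds_ratio(self._est(0.0, 0.1))
        assert est.or_point == pytest.approx(1.0)

    def test_closed_form(self):
        est = self._est(math.log(2), math.log(2) / Z95)
        out = to_odds_ratio(est)
        assert out.or_point == pytest.approx(2.0)
        assert out.or_low == pytest.approx(1.0)
        assert out.or_high == pytest.approx(4.0)

    def test_back_solved_reference_interval(self):
        # exp(1.0952 -/+ 1.96 * 0.3127) rounds to 2.99 (1.62 to 5.52)
        out = to_odds_ratio(self._est(1.0952, 0.3127))
        assert round(out.or_point, 2) == 2.99
        assert round(out.or_low, 2) == 1.62
        assert round(out.or_high, 2) == 5.52

    def test_beta_scale_untouched(self, rng):
        est = ivw_fixed(random_instruments(rng, 5))
        out = to_odds_ratio(est)
        assert out.beta == est.beta and out.se == est.se


# ---------------------------------------------------------------------------
# Cross-estimator invariants
# ---------------------------------------------------------------------------


@st.composite
def instrument_lists(draw, min_size=3, max_size=12):
    seed = draw(st.integers(min_value=0, max_value=2**31))
    n = draw(st.integers(min_value=min_size, max_value=max_size))
    rng = np.random.default_rng(seed)
    return random_instruments(rng, n)


@settings(max_examples=30, deadline=None)
@given(insts=instrument_lists(), flips=st.integers(min_value=0, max_value=2**12 - 1))
def test_orientation_invariance(insts, flips):
    flipped = [
        make_inst(i.snp_id, gamma=-i.gamma_hat, se_gamma=i.se_gamma,
                  big_gamma=-i.big_gamma_hat, se_big_gamma=i.se_big_gamma)
        if (flips >> j) & 1 else i
        for j, i in enumerate(insts)
    ]
    assert ivw_fixed(flipped).beta == pytest.approx(ivw_fixed(insts).beta, rel=1e-12)
    assert mr_egger(flipped).beta == pytest.approx(mr_egger(insts).beta, rel=1e-9)
    assert weighted_median_point(flipped) == pytest.approx(
        weighted_median_point(insts), rel=1e-12
    )


@settings(max_examples=30, deadline=None)
@given(insts=instrument_lists(), c=st.floats(min_value=0.1, max_value=10.0))
def test_scale_equivariance(insts, c):
    scaled = [
        make_inst(i.snp_id, gamma=c * i.gamma_hat, se_gamma=c * i.se_gamma,
                  big_gamma=i.big_gamma_hat, se_big_gamma=i.se_big_gamma)
        for i in insts
    ]
    assert ivw_fixed(scaled).beta == pytest.approx(ivw_fixed(insts).beta / c, rel=1e-9)
    assert mr_egger(scaled).beta == pytest.approx(mr_egger(insts).beta / c, rel=1e-9)
    assert weighted_median_point(scaled) == pytest.approx(
        weighted_median_point(insts) / c, rel=1e-9
    )


@settings(max_examples=30, deadline=None)
@given(insts=instrument_lists())
def test_ordering_invariants(insts):
    theta = [i.big_gamma_hat / i.gamma_hat for i in insts]
    wm = weighted_median_point(insts)
    assert min(theta) <= wm <= max(theta)
    est = ivw_fixed(insts)
    min_se_theta = min(i.se_big_gamma / abs(i.gamma_hat) for i in insts)
    assert est.se <= min_se_theta + 1e-15
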