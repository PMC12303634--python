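import numpy as np
import pytest

from conftest import pairs_from_arrays
from mrpipe import estimators as est
from mrpipe.harmonize import harmonize
from mrpipe.synthetic_data import SimScenario, simulate_sumstats_pair


def test_wald_ratio_scale_and_sign():
    p = pairs_from_arrays([1.0], [0.01], [0.5], [0.05])
    e = est.wald_ratio(p)
    assert (e.beta, e.se) == (pytest.approx(0.5), pytest.approx(0.05))
    p2 = pairs_from_arrays([-2.0], [0.01], [1.0], [0.1])
    e2 = est.wald_ratio(p2)
    assert (e2.beta, e2.se) == (pytest.approx(-0.5), pytest.approx(0.05))


def test_wald_ratio_degenerate_gamma_errors():
    with pytest.raises(est.DegenerateInstrumentError):
        est.wald_ratio(pairs_from_arrays([0.0], [0.01], [0.5], [0.05]))


def test_wald_odds_ratio_transform():
    e = est.wald_ratio(pairs_from_arrays([1.0], [0.01], [0.191], [0.062]))
    assert round(e.or_value, 2) == 1.21


def test_ivw_equal_ratios_fixed_effects():
    p = pairs_from_arrays([1.0, 2.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.1])
    e = est.ivw(p, model="auto")
    assert e.method == "ivw_fe"
    assert e.beta == pytest.approx(0.5)
    # closed form: se = 1/sqrt(sum gamma^2/se_Gamma^2) = 1/sqrt(100+400)
    assert e.se == pytest.approx(1 / np.sqrt(500))


def test_ivw_matches_weighted_mean_oracle():
    rng = np.random.default_rng(3)
    g = rng.normal(0.1, 0.03, 6)
    sG = rng.uniform(0.02, 0.06, 6)
    G = rng.normal(0.05, 0.03, 6)
    e = est.ivw(pairs_from_arrays(g, np.full(6, 0.01), G, sG), model="fixed")
    w = (g / sG) ** 2
    oracle = np.sum(w * (G / g)) / np.sum(w)
    assert e.beta == pytest.approx(oracle)


def test_ivw_single_snp_falls_back_to_wald():
    p = pairs_from_arrays([1.0], [0.01], [0.5], [0.05])
    e = est.ivw(p)
    assert e.method == "wald" and e.beta == pytest.approx(0.5)


def test_ivw_random_effects_floor_at_fixed_se():
    # heterogeneous ratios force the random-effects branch
    p = pairs_from_arrays([1.0, 1.0, 1.0], [0.01] * 3, [0.0, 0.5, 1.0], [0.05] * 3)
    fe = est.ivw(p, model="fixed")
    re = est.ivw(p, model="random")
    assert re.se >= fe.se
    assert re.beta == pytest.approx(fe.beta)


def test_egger_exact_fit_recovers_intercept_and_slope():
    g = np.array([1.0, 2.0, 3.0])
    G = 0.1 + 0.4 * g
    e = est.egger(pairs_from_arrays(g, [0.01] * 3, G, [0.1] * 3))
    assert e.intercept == pytest.approx(0.1, abs=1e-8)
    assert e.beta == pytest.approx(0.4, abs=1e-8)


def test_egger_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    g = np.abs(rng.normal(0.1, 0.05, 10)) + 0.01
    sG = rng.uniform(0.02, 0.08, 10)
    G = 0.05 + 0.3 * g + rng.normal(0, 0.02, 10)
    e = est.egger(pairs_from_arrays(g, np.full(10, 0.005), G, sG))
    # direct 2x2 weighted normal equations
    w = 1 / sG**2
    X = np.column_stack([np.ones_like(g), g])
    beta_hat = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * G))
    assert e.intercept == pytest.approx(beta_hat[0])
    assert e.beta == pytest.approx(beta_hat[1])


def test_egger_orientation_negates_negative_gamma():
    g = np.array([0.05, -0.08, 0.1, -0.12])
    G = 0.02 + 0.4 * np.abs(g) * np.sign(g)  # consistent with slope on oriented data
    oriented = est.egger(pairs_from_arrays(np.abs(g), [0.01] * 4, 0.02 + 0.4 * np.abs(g), [0.05] * 4))
    mixed = est.egger(pairs_from_arrays(g, [0.01] * 4, np.sign(g) * (0.02 + 0.4 * np.abs(g)), [0.05] * 4))
    assert mixed.beta == pytest.approx(oriented.beta)
    assert mixed.intercept == pytest.approx(oriented.intercept)


def test_egger_needs_three_snps():
    with pytest.raises(est.InsufficientInstrumentsError):
        est.egger(pairs_from_arrays([1.0, 2.0], [0.01] * 2, [0.5, 1.0], [0.1] * 2))


def test_weighted_median_equal_weights_hits_middle_ratio():
    p = pairs_from_arrays([1.0, 1.0, 1.0], [0.01] * 3, [0.2, 0.4, 0.6], [0.1] * 3)
    e = est.weighted_median(p, n_boot=50, seed=1)
    assert e.beta == pytest.approx(0.4)


def test_weighted_median_interpolation_oracle():
    # ratios {0, 1}, weights {0.75, 0.25}: S = {0.375, 0.875};
    # interpolating at 0.5 gives 0 + (0.5-0.375)/(0.875-0.375) = 0.25
    assert est._weighted_median(np.array([0.0, 1.0]), np.array([0.75, 0.25])) == pytest.approx(0.25)
    assert est._weighted_median(np.array([0.0, 1.0]), np.array([0.75, 0.25])) < 0.5


def test_weighted_median_robust_to_30pct_invalid():
    rng = np.random.default_rng(5)
    reps_wm, reps_ivw = [], []
    for r in range(40):
        s = SimScenario(seed=int(rng.integers(2**31)), n_snps=30, true_beta=0.3,
                        invalid_fraction=0.3, pleiotropy_mean=0.05, pleiotropy_sd=0.02)
        e_t, o_t, _ = simulate_sumstats_pair(s)
        pairs = harmonize(e_t, o_t)
        reps_wm.append(est.weighted_median(pairs, n_boot=8, seed=1).beta)
        reps_ivw.append(est.ivw(pairs).beta)
    assert abs(np.mean(reps_wm) - 0.3) < abs(np.mean(reps_ivw) - 0.3)
    assert abs(np.mean(reps_wm) - 0.3) < 0.1


def test_mode_degenerate_identical_ratios():
    p = pairs_from_arrays([1.0, 2.0, 4.0], [0.01] * 3, [0.5, 1.0, 2.0], [0.1] * 3)
    e = est.mode_based(p, weighted=False, n_boot=10, seed=1)
    assert e.beta == pytest.approx(0.5)


def test_mode_finds_majority_cluster():
    ratios = np.array([0.1] * 7 + [0.9] * 3) + np.linspace(-0.005, 0.005, 10)
    p = pairs_from_arrays(np.ones(10), [0.01] * 10, ratios, [0.05] * 10)
    e = est.mode_based(p, weighted=False, n_boot=10, seed=1)
    assert abs(e.beta - 0.1) < 0.05
    # oracle: dense grid search of the same KDE
    w = np.full(10, 0.1)
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    h = 0.9 * min(sd, abs(iqr) / 1.34) * 10 ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20001)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(1)
    # the estimator uses a 512-point grid, so agreement is to its resolution
    coarse_step = (ratios.max() - ratios.min() + 6 * h) / 511
    assert e.beta == pytest.approx(grid[np.argmax(dens)], abs=1.1 * coarse_step)


def test_weighted_mode_dominant_weight_limit():
    g = np.array([10.0, 0.01, 0.01])
    sG = np.array([0.01, 1.0, 1.0])  # essentially all weight on SNP 1
    G = np.array([5.0, 0.009, 0.002])
    e = est.mode_based(pairs_from_arrays(g, [0.01] * 3, G, sG), weighted=True, n_boot=10, seed=1)
    assert e.beta == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"])
def test_sign_flip_properties(clean_pairs, method):
    """Joint (gamma, Gamma) negation is an allele re-coding and leaves the
    estimate unchanged; negating the outcome effects alone negates beta and
    keeps the SE."""
    def run(p):
        if method == "ivw":
            return est.ivw(p, model="fixed")
        if method == "egger":
            return est.egger(p)
        if method == "weighted_median":
            return est.weighted_median(p, n_boot=200, seed=9)
        return est.mode_based(p, weighted=(method == "weighted_mode"), n_boot=50, seed=9)

    a = run(clean_pairs)
    joint = run(pairs_from_arrays(
        -clean_pairs.gamma, clean_pairs.se_gamma, -clean_pairs.Gamma, clean_pairs.se_Gamma))
    assert joint.beta == pytest.approx(a.beta, abs=1e-8)
    assert joint.se == pytest.approx(a.se, rel=1e-6)

    out_flip = run(pairs_from_arrays(
        clean_pairs.gamma, clean_pairs.se_gamma, -clean_pairs.Gamma, clean_pairs.se_Gamma))
    assert out_flip.beta == pytest.approx(-a.beta, abs=1e-8)
    if method in ("ivw", "egger"):
        assert out_flip.se == pytest.approx(a.se)
    else:  # bootstrap SEs: independent draws on mirrored ratios
        assert out_flip.se == pytest.approx(a.se, rel=0.3)


def test_ci_contains_beta_and_or_is_exp_beta(clean_pairs):
    for e in (est.ivw(clean_pairs), est.egger(clean_pairs),
              est.weighted_median(clean_pairs, n_boot=50, seed=2)):
        assert e.ci_low < e.beta < e.ci_high
        assert e.or_value == pytest.approx(np.exp(e.beta))
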