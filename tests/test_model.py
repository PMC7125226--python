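import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import barfit
from barfit.model import (
    FitError,
    GeneModelFit,
    HitThresholds,
    bh_fdr,
    classify,
    fit_gene,
    lrt_pvalue,
    t_value,
)

from conftest import block_to_frame, random_gene_block
from oracle_mixed import bruteforce_fit, dense_loglik


def _fit_block(y, x, groups):
    ymat, sheet = block_to_frame(np.asarray(y, float), np.asarray(x, float), np.asarray(groups))
    return fit_gene(ymat, sheet, locus_tag="g")


def test_constant_data_no_signal():
    """Identical y everywhere: zero condition effect and equal log-likelihoods."""
    y = np.full(12, 1.5)
    x = np.tile([0.5, 0.5, -0.5, -0.5], 3)
    groups = np.repeat(np.arange(3), 4)
    fit = _fit_block(y, x, groups)
    assert fit.condition_effect == pytest.approx(0.0, abs=1e-9)
    assert fit.loglik_full == pytest.approx(fit.loglik_null, abs=1e-6)
    assert lrt_pvalue(fit) == pytest.approx(1.0)


def test_ols_limit_closed_form():
    """With barcodes that are exact permutations of each other the barcode
    variance estimate collapses to zero and the fit reduces to OLS: the
    condition effect is the difference of condition means and the Wald T
    equals the two-sample statistic computed with the ML pooled variance."""
    sel = np.array([1.0, 2.0, 3.0])
    ctl = np.array([-1.0, 0.0, 1.0])
    y = np.r_[sel, ctl, sel[::-1], ctl[::-1]]
    x = np.tile(np.r_[np.full(3, 0.5), np.full(3, -0.5)], 2)
    groups = np.repeat([0, 1], 6)
    fit = _fit_block(y, x, groups)
    assert fit.varsigma2 == pytest.approx(0.0, abs=1e-8)
    diff = sel.mean() - ctl.mean()
    assert fit.condition_effect == pytest.approx(diff, abs=1e-8)
    n = len(y)
    resid = y - y.mean() - diff * x
    s2_ml = resid @ resid / n
    t_closed = diff / math.sqrt(s2_ml * (1 / 6 + 1 / 6))
    assert t_value(fit) == pytest.approx(t_closed, rel=1e-6)
    # same statistic as scipy's two-sample t up to the ML/OLS dof factor
    t_classic = stats.ttest_ind(np.r_[sel, sel[::-1]], np.r_[ctl, ctl[::-1]]).statistic
    assert t_value(fit) == pytest.approx(t_classic * math.sqrt(n / (n - 2)), rel=1e-6)


@pytest.mark.parametrize("seed", range(8))
def test_ml_matches_bruteforce_oracle(seed):
    """The profiled 1-D ML search agrees with generic 4-parameter numerical
    maximization of the dense Gaussian likelihood."""
    rng = np.random.default_rng(100 + seed)
    y, x, groups = random_gene_block(rng)
    fit = _fit_block(y, x, groups)
    ll_oracle, mu_o, cond_o, *_ = bruteforce_fit(y, x, groups)
    assert fit.loglik_full == pytest.approx(ll_oracle, abs=1e-6)
    assert fit.condition_effect == pytest.approx(cond_o, abs=1e-4)
    ll_null_oracle, *_ = bruteforce_fit(y, x, groups, with_condition=False)
    assert fit.loglik_null == pytest.approx(ll_null_oracle, abs=1e-6)


def test_reported_loglik_is_exact_for_reported_parameters():
    """The stored log-likelihood equals the dense Gaussian log density
    evaluated at the stored parameter estimates."""
    rng = np.random.default_rng(5)
    y, x, groups = random_gene_block(rng)
    fit = _fit_block(y, x, groups)
    ll = dense_loglik(y, x, groups, fit.mu, fit.condition_effect, fit.varsigma2, fit.sigma2)
    assert fit.loglik_full == pytest.approx(ll, abs=1e-8)


def test_ml_matches_statsmodels_mixedlm():
    """Independent cross-check against statsmodels' MixedLM ML fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    y, x, groups = random_gene_block(rng)
    exog = np.column_stack([np.ones_like(y), x])
    res = sm.MixedLM(y, exog, groups=groups).fit(reml=False)
    fit = _fit_block(y, x, groups)
    assert fit.loglik_full >= res.llf - 1e-5
    assert fit.condition_effect == pytest.approx(res.params[1], abs=1e-3)


def test_label_swap_antisymmetry():
    """Exchanging selective and control labels negates fitness and T but
    leaves the likelihood-ratio p-value unchanged."""
    rng = np.random.default_rng(21)
    y, x, groups = random_gene_block(rng)
    fit = _fit_block(y, x, groups)
    fit_sw = _fit_block(y, -x, groups)
    assert fit_sw.condition_effect == pytest.approx(-fit.condition_effect, abs=1e-6)
    assert t_value(fit_sw) == pytest.approx(-t_value(fit), rel=1e-5)
    assert lrt_pvalue(fit_sw) == pytest.approx(lrt_pvalue(fit), abs=1e-8)


def test_nesting_invariant_on_random_genes():
    """2*(ll_full - ll_null) >= 0 for every fitted gene."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        y, x, groups = random_gene_block(rng)
        fit = _fit_block(y, x, groups)
        assert 2 * (fit.loglik_full - fit.loglik_null) >= -1e-8


def test_fit_preconditions():
    with pytest.raises(FitError, match=">=2 barcodes"):
        _fit_block(np.zeros(4), np.array([0.5, 0.5, -0.5, -0.5]), np.zeros(4, int))
    ymat, sheet = block_to_frame(np.zeros(4), np.array([0.5, 0.5, -0.5, -0.5]), np.repeat([0, 1], 2))
    only_sel = ymat[[c for c in ymat.columns if sheet.condition_of(c) == "selective"]]
    with pytest.raises(FitError, match="one condition"):
        fit_gene(only_sel, sheet, locus_tag="g")


@pytest.mark.parametrize(
    "stat,expected,decimals",
    [(3.841459, 0.05, 4), (10.8276, 0.001, 6), (0.0, 1.0, 12)],
)
def test_lrt_chi2_reference(stat, expected, decimals):
    """The p-value is the chi-square(1) upper tail at the -2 delta-loglik."""
    fit = GeneModelFit("g", 0, 0, 0, 1, loglik_full=stat / 2, loglik_null=0,
                       se_condition_effect=1, n_barcodes=2, n_obs=8)
    assert lrt_pvalue(fit) == pytest.approx(expected, abs=10 ** (-decimals) / 2)


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
        ([], []),
        ([0.5, 0.001], [0.5, 0.002]),  # order restored
    ],
)
def test_bh_fdr_hand_examples(pvals, expected):
    assert np.allclose(bh_fdr(pvals), expected)


def test_bh_fdr_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_t_value_degenerate_cases():
    base = dict(locus_tag="g", mu=0, varsigma2=0, sigma2=1, loglik_full=0,
                loglik_null=0, n_barcodes=2, n_obs=8)
    assert t_value(GeneModelFit(condition_effect=0.0, se_condition_effect=1.0, **base)) == 0.0
    assert t_value(GeneModelFit(condition_effect=-2.0, se_condition_effect=0.0, **base)) == -math.inf


@pytest.mark.parametrize(
    "fitness,t,q,expected",
    [
        (-1.5, -6.0, 1e-5, "negative"),
        (1.5, 6.0, 1e-5, "positive"),
        (0.0, 8.0, 1e-5, "none"),
        (1.2, 3.9, 1e-4, "none"),  # fails the T cut
        (-1.5, -6.0, 0.01, "none"),  # fails the FDR cut
        (-1.0, -6.0, 1e-5, "none"),  # threshold is strict
    ],
)
def test_classify_thresholds(fitness, t, q, expected):
    table = pd.DataFrame({"fitness": [fitness], "t_value": [t], "q": [q]})
    out = classify(table, HitThresholds())
    assert out["hit_class"].iloc[0] == expected


def test_high_depth_strong_fitness_gives_large_t():
    """A gene with true fitness -4 at megaread depth is detected with |T| > 4."""
    spec = {f"gene_{i:05d}": 0.0 for i in range(20)}
    spec["gene_00003"] = -4.0
    cfg = barfit.SimConfig(
        n_genes=20, barcodes_per_gene=5, depth_per_sample=1_000_000,
        fitness_spec=spec, seed=9,
    )
    cm, _ = barfit.simulate(cfg)
    cur, _ = barfit.curate(cm)
    table = barfit.fit_screen(barfit.normalize(cur), cur.pool)
    row = table.loc["gene_00003"]
    assert row["fitness"] < -2
    assert abs(row["t_value"]) > 4
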