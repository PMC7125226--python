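"""Per-gene fitness estimation by nested random-intercept Gaussian models.

For each gene *g*, the T0-adjusted log2 values y_{i,j,k} (barcode *i*,
condition *j*, sample *k*) are modelled as

    full:  y_{i,j,k} = mu_g + C_j + B_i + eps_{i,j,k}
    null:  y_{i,j,k} = mu_g       + B_i + eps_{i,j,k}

with B_i ~ iid N(0, varsigma_g^2) a per-insertion random intercept and
eps ~ iid N(0, sigma_g^2) residual noise. Both models are fitted by maximum
likelihood (ML, not REML — the log-likelihoods must be comparable across
fixed-effect structures). The condition contrast is coded sum-to-zero
(selective = +1/2, control = -1/2), so the coefficient on it *is* the gene's
fitness: the expected log2 abundance change under selection relative to
control. Its Wald statistic (estimate over the standard error from the
observed information at the ML variances) is the T-value. Gene-level
significance is a likelihood-ratio test of the condition term against the
upper tail of chi-square with one degree of freedom, followed by
Benjamini-Hochberg FDR adjustment across genes.

ML fitting is exact up to a 1-D numerical search: for a fixed variance ratio
lambda = varsigma^2 / sigma^2 the fixed effects and sigma^2 have closed-form
generalized-least-squares solutions, so the profiled log-likelihood is
maximized over lambda >= 0 alone (coarse log-spaced grid, then bounded
refinement, with the lambda = 0 boundary evaluated exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import BarcodePool, SampleSheet
from .normalize import NormalizedMatrix

_SIGMA2_FLOOR = 1e-12
_LAM_GRID = np.concatenate([[0.0], np.logspace(-6, 6, 49)])


class FitError(ValueError):
    """A gene's data cannot support the model fit."""


@dataclass
class GeneModelFit:
    """ML estimates for one gene under the full and null models."""

    locus_tag: str
    mu: float
    condition_effect: float  # selective minus control, log2 units
    varsigma2: float  # barcode random-intercept variance
    sigma2: float  # residual variance
    loglik_full: float
    loglik_null: float
    se_condition_effect: float
    n_barcodes: int
    n_obs: int
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling cutoffs: |fitness| above ``fitness_cut``, |T| above
    ``t_cut``, q below ``fdr_cut``."""

    fitness_cut: float = 1.0
    t_cut: float = 4.0
    fdr_cut: float = 0.001

    def __post_init__(self) -> None:
        if min(self.fitness_cut, self.t_cut, self.fdr_cut) <= 0:
            raise ValueError("all thresholds must be > 0")


# ---------------------------------------------------------------------------
# profiled ML machinery


def _group_stats(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Sort observations by group; return sorted arrays plus reduceat starts
    and per-group sizes."""
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    counts = np.diff(np.r_[starts, len(g)])
    return y[order], X[order], starts, counts


def _profile(y, X, starts, counts, lam):
    """GLS at fixed lambda = varsigma2/sigma2 under W_i = I + lam*J.

    Returns (loglik, beta, sigma2_hat, cov_beta). Uses the Woodbury form
    W_i^-1 = I - lam/(1 + n_i lam) * J per barcode block.
    """
    n = len(y)
    c = lam / (1.0 + counts * lam)
    gy = np.add.reduceat(y, starts)
    gX = np.add.reduceat(X, starts, axis=0)
    XtWX = X.T @ X - (gX * c[:, None]).T @ gX
    XtWy = X.T @ y - gX.T @ (c * gy)
    ytWy = y @ y - c @ (gy**2)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular design: {exc}") from exc
    rss = max(ytWy - beta @ XtWy, 0.0)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    logdet_w = np.sum(np.log1p(counts * lam))
    ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + rss / sigma2 + logdet_w)
    cov = sigma2 * np.linalg.inv(XtWX)
    return ll, beta, sigma2, cov


def _fit_ml(y, X, groups):
    """Maximize the random-intercept ML likelihood; returns
    (loglik, beta, varsigma2, sigma2, cov_beta)."""
    ys, Xs, starts, counts = _group_stats(y, X, groups)

    lls = np.array([_profile(ys, Xs, starts, counts, lam)[0] for lam in _LAM_GRID])
    k = int(np.argmax(lls))
    lam_best = _LAM_GRID[k]
    if 0 < k < len(_LAM_GRID) - 1:
        lo = _LAM_GRID[k - 1] if k > 1 else 1e-9
        hi = _LAM_GRID[k + 1]
        res = minimize_scalar(
            lambda u: -_profile(ys, Xs, starts, counts, math.exp(u))[0],
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam_ref = math.exp(res.x)
        if _profile(ys, Xs, starts, counts, lam_ref)[0] > lls[k]:
            lam_best = lam_ref

    ll, beta, sigma2, cov = _profile(ys, Xs, starts, counts, lam_best)
    return ll, beta, lam_best * sigma2, sigma2, cov


def _design(y_gene: pd.DataFrame, sheet: SampleSheet):
    """Long-form response, sum-to-zero condition codes and barcode groups for
    one gene's barcode x sample block."""
    cond = sheet.table.loc[list(y_gene.columns), "condition"]
    if (cond == "T0").any():
        raise FitError("T0 samples must be removed before model fitting")
    code = cond.map({"selective": 0.5, "control": -0.5}).to_numpy(float)
    n_bc, n_s = y_gene.shape
    y = y_gene.to_numpy(float).ravel()
    x = np.tile(code, n_bc)
    groups = np.repeat(np.arange(n_bc), n_s)
    return y, x, groups


def fit_gene(y_gene: pd.DataFrame, sheet: SampleSheet, locus_tag: str = "") -> GeneModelFit:
    """Fit the full and null models for one gene.

    ``y_gene`` is the normalized matrix restricted to the gene's barcodes
    (rows) over the non-T0 samples (columns). Requires >=2 barcodes and
    observations in both conditions.
    """
    if y_gene.shape[0] < 2:
        raise FitError(f"gene {locus_tag!r}: needs >=2 barcodes, has {y_gene.shape[0]}")
    y, x, groups = _design(y_gene, sheet)
    if len(y) < 3:
        raise FitError(f"gene {locus_tag!r}: too few observations ({len(y)})")
    if len(np.unique(x)) < 2:
        raise FitError(f"gene {locus_tag!r}: observations in only one condition")

    X_full = np.column_stack([np.ones_like(y), x])
    X_null = np.ones((len(y), 1))

    ll_full, beta, vs2, s2, cov = _fit_ml(y, X_full, groups)
    ll_null, *_ = _fit_ml(y, X_null, groups)

    se = math.sqrt(max(cov[1, 1], 0.0))
    return GeneModelFit(
        locus_tag=locus_tag,
        mu=float(beta[0]),
        condition_effect=float(beta[1]),
        varsigma2=float(vs2),
        sigma2=float(s2),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        se_condition_effect=se,
        n_barcodes=y_gene.shape[0],
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# inference


def lrt_pvalue(fit: GeneModelFit) -> float:
    """Likelihood-ratio p-value: 2*(ll_full - ll_null) against the chi2(1)
    upper tail; tiny negative statistics from round-off are clamped at 0."""
    stat = 2.0 * (fit.loglik_full - fit.loglik_null)
    if stat < -1e-6:
        raise FitError(
            f"gene {fit.locus_tag!r}: loglik_full < loglik_null ({stat=}), nesting violated"
        )
    return float(chi2.sf(max(stat, 0.0), df=1))


def t_value(fit: GeneModelFit) -> float:
    """Wald T-value for the condition effect (fitness / SE)."""
    if fit.se_condition_effect == 0.0:
        if fit.condition_effect == 0.0:
            return 0.0
        return math.copysign(math.inf, fit.condition_effect)
    return fit.condition_effect / fit.se_condition_effect


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(table: pd.DataFrame, thresholds: HitThresholds | None = None) -> pd.DataFrame:
    """Assign hit_class from fitness, T-value and q-value columns.

    negative: fitness < -cut, |T| > t_cut, q < fdr_cut (gene required under
    selection); positive: symmetric; otherwise none.
    """
    th = thresholds or HitThresholds()
    out = table.copy()
    sig = (out["t_value"].abs() > th.t_cut) & (out["q"] < th.fdr_cut)
    neg = sig & (out["fitness"] < -th.fitness_cut)
    pos = sig & (out["fitness"] > th.fitness_cut)
    out["hit_class"] = np.select([neg, pos], ["negative", "positive"], default="none")
    return out


def fit_screen(
    nm: NormalizedMatrix,
    pool: BarcodePool,
    thresholds: HitThresholds | None = None,
) -> pd.DataFrame:
    """Fit every gene in a normalized screen and assemble the fitness table.

    Returns a DataFrame indexed by locus_tag (sorted) with columns fitness,
    t_value, p, q, hit_class, n_barcodes, n_obs. Genes whose data cannot be
    fitted (fewer than two barcodes, one condition only) are excluded and
    listed with reasons in ``result.attrs["excluded"]``.
    """
    locus = pool.table.loc[nm.y.index, "locus_tag"]
    rows, excluded = [], {}
    for tag in sorted(locus.dropna().unique()):
        y_gene = nm.y.loc[locus.index[locus == tag]]
        try:
            fit = fit_gene(y_gene, nm.sheet, locus_tag=tag)
        except FitError as exc:
            excluded[tag] = str(exc)
            continue
        rows.append(
            {
                "locus_tag": tag,
                "fitness": fit.condition_effect,
                "t_value": t_value(fit),
                "p": lrt_pvalue(fit),
                "n_barcodes": fit.n_barcodes,
                "n_obs": fit.n_obs,
            }
        )
    if not rows:
        raise FitError("no genes could be fitted")
    table = pd.DataFrame(rows).set_index("locus_tag")
    table["q"] = bh_fdr(table["p"])
    table = classify(table, thresholds)
    table = table[["fitness", "t_value", "p", "q", "hit_class", "n_barcodes", "n_obs"]]
    table.attrs["excluded"] = excluded
    return table
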