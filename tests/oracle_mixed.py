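"""Independent brute-force ML oracle for the per-gene random-intercept model.

Builds the full n x n covariance matrix explicitly and maximizes the Gaussian
log-likelihood with a generic numerical optimizer over (mu, C, log varsigma2,
log sigma2) from several moment-based starts. Shares no code with the
package's profiled fitting path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal


def dense_loglik(y, x, groups, mu, cond, vs2, s2):
    """Exact multivariate-normal log density of the random-intercept model.

    ``x`` holds sum-to-zero condition codes (+0.5 selective, -0.5 control);
    ``cond`` is the selective-minus-control contrast.
    """
    z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    cov = s2 * np.eye(len(y)) + vs2 * (z @ z.T)
    mean = mu + cond * x
    return multivariate_normal.logpdf(y, mean=mean, cov=cov, allow_singular=True)


def bruteforce_fit(y, x, groups, with_condition=True):
    """Maximize the dense log-likelihood numerically.

    Returns (loglik, mu, cond, vs2, s2); ``cond`` is 0 when the condition
    term is excluded (the null model).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    groups = np.asarray(groups)

    def unpack(p):
        if with_condition:
            mu, cond, lv, ls = p
        else:
            (mu, lv, ls), cond = p, 0.0
        return mu, cond, np.exp(lv), np.exp(ls)

    def neg(p):
        return -dense_loglik(y, x, groups, *unpack(p))

    mu0 = float(np.mean(y))
    cond0 = float(np.mean(y[x > 0]) - np.mean(y[x < 0])) if with_condition else 0.0
    resid = y - mu0 - (cond0 * x if with_condition else 0.0)
    s2_0 = max(float(np.var(resid)), 1e-4)
    gmeans = np.array([resid[groups == g].mean() for g in np.unique(groups)])
    vs2_0 = max(float(np.var(gmeans)), 1e-4)

    starts = []
    for lv, ls in [
        (np.log(vs2_0), np.log(s2_0)),
        (np.log(1e-8), np.log(s2_0 + vs2_0)),
        (np.log(vs2_0 * 4 + 1e-3), np.log(max(s2_0 / 4, 1e-6))),
    ]:
        if with_condition:
            starts.append([mu0, cond0, lv, ls])
        else:
            starts.append([mu0, lv, ls])

    best = None
    for p0 in starts:
        res = minimize(neg, p0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        res2 = minimize(neg, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 20000})
        cand = res2 if res2.fun < res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    mu, cond, vs2, s2 = unpack(best.x)
    return -best.fun, mu, cond, vs2, s2
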