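"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates risk sets with plain Python loops and relies
on scipy's generic optimizer rather than the package's Newton solver, so
agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def naive_log_partial_likelihood(beta, time, event, X, offset=None, strata=None):
    """Breslow partial log-likelihood by direct risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    offset = np.zeros(len(time)) if offset is None else np.asarray(offset, dtype=float)
    strata = np.zeros(len(time)) if strata is None else np.asarray(strata)
    eta = X @ beta + offset
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = (time >= time[i]) & (strata == strata[i])
            ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


def naive_fit(time, event, X, offset=None, strata=None, x0=None):
    """Maximize the brute-force likelihood with scipy's BFGS."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    x0 = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float)

    def neg(beta):
        return -naive_log_partial_likelihood(beta, time, event, X, offset, strata)

    res = optimize.minimize(neg, x0, method="BFGS", options={"gtol": 1e-11, "maxiter": 500})
    # polish with Nelder-Mead if BFGS stalled
    if not res.success:
        res = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


def naive_schoenfeld(beta, time, event, X, offset=None):
    """Unscaled Schoenfeld residuals by direct risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    offset = np.zeros(len(time)) if offset is None else np.asarray(offset, dtype=float)
    eta = X @ beta + offset
    w = np.exp(eta)
    rows = []
    order = np.argsort(time, kind="stable")
    for i in order:
        if event[i] == 1:
            risk = time >= time[i]
            xbar = (w[risk][:, None] * X[risk]).sum(axis=0) / w[risk].sum()
            rows.append(X[i] - xbar)
    return np.array(rows)


def naive_kaplan_meier(time, event):
    """Product-limit estimate at each distinct event time, by hand."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def random_small_dataset(rng, n_max=30, p=2, with_offset=True, allow_ties=False):
    """A random survival dataset small enough for the brute-force oracles."""
    n = int(rng.integers(8, n_max + 1))
    X = rng.standard_normal((n, p))
    X[:, 0] = (rng.random(n) < 0.5).astype(float)
    beta_true = rng.normal(0, 0.5, p)
    T = rng.exponential(1.0 / np.exp(X @ beta_true))
    C = rng.exponential(1.5, n)
    time = np.minimum(T, C)
    if allow_ties:
        time = np.ceil(time * 4) / 4.0  # coarse grid forces ties
    event = (T <= C).astype(int)
    if event.sum() < 2:  # ensure some information
        event[rng.integers(0, n)] = 1
        event[rng.integers(0, n)] = 1
    offset = rng.normal(0, 0.4, n) if with_offset else np.zeros(n)
    return time, event, X, offset
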