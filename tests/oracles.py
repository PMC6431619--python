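"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (full rescans, brute-force pair
counting, generic numerical optimization) and shares no code with the
implementation under test.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm


# ---------------------------------------------------------------- features

def naive_counts(rec, t, initial_config=(0, 0, 0)):
    """Recompute N, S, I, R, RP at time t by replaying the raw event list."""
    applies = [(e.time, e.payload) for e in rec.events if e.etype == "apply" and e.time <= t]
    resets = [e.time for e in rec.events if e.etype == "reset" and e.time <= t]

    n = len(applies) + len(resets)
    r = len(resets)

    # repeats: brute force over ordered pairs of applies
    rp = 0
    for i, (_, cfg_i) in enumerate(applies):
        if any(cfg_j == cfg_i for _, cfg_j in applies[:i]):
            rp += 1

    # simple actions: replay the action sequence in original event order
    merged = [
        (e.time, e.etype, e.payload)
        for e in rec.events
        if e.etype in ("apply", "reset") and e.time <= t
    ]
    ref = tuple(initial_config)
    s = 0
    sliders_moved = set()
    for _, etype, cfg in merged:
        if etype == "reset":
            ref = tuple(initial_config)
        else:
            diffs = [k for k in range(3) if cfg[k] != ref[k]]
            if len(diffs) == 1:
                s += 1
                sliders_moved.add(diffs[0])
            ref = cfg
    i_votat = int(sliders_moved == {0, 1, 2})
    return {"N": n, "S": s, "I": i_votat, "R": r, "RP": rp}


# ---------------------------------------------------------------- metrics

def pairwise_auc(scores, outcomes):
    """AUC by explicit enumeration of all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        return None
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


# ---------------------------------------------------------------- likelihoods

def probit_loglik(b, X, y):
    eta = X @ np.asarray(b, dtype=float)
    return float(np.sum(np.where(y == 1, norm.logcdf(eta), norm.logcdf(-eta))))


def probit_grid_search(X, y, half_width=5.0, n_grid=21, n_rounds=8):
    """Maximize the probit log-likelihood by iteratively refined grid search.

    Supports p in {1, 2}; returns (b_hat, loglik)."""
    p = X.shape[1]
    assert p in (1, 2)
    center = np.zeros(p)
    width = half_width
    best_b, best_ll = center, probit_loglik(center, X, y)
    for _ in range(n_rounds):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        if p == 1:
            grid = axes[0][:, None]
        else:
            g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
            grid = np.column_stack([g0.ravel(), g1.ravel()])
        eta = X @ grid.T  # rows x grid points
        ll = np.sum(
            np.where(y[:, None] == 1, norm.logcdf(eta), norm.logcdf(-eta)), axis=0
        )
        k = int(np.argmax(ll))
        best_b, best_ll = grid[k], float(ll[k])
        center = grid[k]
        width = width * 2.0 / (n_grid - 1)  # keep the previous neighbourhood covered
    return best_b, best_ll


def probit_bfgs(X, y):
    """Generic numerical probit maximizer (for p where grids are infeasible)."""
    res = minimize(
        lambda b: -probit_loglik(b, X, y),
        x0=np.zeros(X.shape[1]),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x, -float(res.fun)


def lognormal_loglik(b, log_sigma, X, z):
    sigma2 = np.exp(2.0 * log_sigma)
    resid = z - X @ np.asarray(b, dtype=float)
    return float(
        -np.sum(z)
        - 0.5 * z.size * (np.log(2 * np.pi) + np.log(sigma2))
        - np.sum(resid**2) / (2 * sigma2)
    )


def duration_bfgs(X, z):
    """Maximize the pooled log-normal likelihood over (b2, log sigma) numerically."""
    p = X.shape[1]

    def neg(theta):
        return -lognormal_loglik(theta[:p], theta[p], X, z)

    res = minimize(
        neg,
        x0=np.concatenate([np.zeros(p), [0.0]]),
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 1000},
    )
    b = res.x[:p]
    sigma2 = float(np.exp(2.0 * res.x[p]))
    return b, sigma2, -float(res.fun)
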