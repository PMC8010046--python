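"""Maximum-likelihood random-intercept LMM core.

For the single-grouping random-intercept Gaussian model

    y = X beta + Z b + e,    b ~ N(0, s2*lam),  e ~ N(0, s2 I)

beta and s2 profile out in closed form for fixed variance ratio ``lam``
(Sherman-Morrison within participant blocks), leaving a smooth 1-D profiled
log-likelihood that is maximised by a coarse log-grid search plus golden
section refinement.  Everything is numba-compiled because the cluster
permutation test re-fits the full model at every timepoint of every
permutation (~10^6 fits per analysis).

Both nested models are fitted by ML (not REML): the likelihood-ratio test
compares fixed-effect structures, and REML likelihoods of models with
different fixed effects are not comparable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))

# log10(lam) search grid; lam = 0 (pure OLS) is always evaluated too
_GRID_LO = -6.0
_GRID_HI = 5.0
_GRID_STEP = 0.5
_GOLDEN_ITERS = 40


@njit(cache=True)
def _profiled_ll(lam, XtX, Xty, yty, S, ty, gsz, n):
    """Profiled ML log-likelihood at variance ratio lam.

    Uses the group-summed sufficient statistics only: XtX = X'X, Xty = X'y,
    yty = y'y, S[g] = column sums of X in group g, ty[g] = sum of y in group
    g, gsz[g] = group size.
    """
    p = XtX.shape[0]
    G = S.shape[0]
    A = XtX.copy()
    b = Xty.copy()
    c = yty
    logdet = 0.0
    for g in range(G):
        w = lam / (1.0 + lam * gsz[g])
        logdet += np.log(1.0 + lam * gsz[g])
        c -= w * ty[g] * ty[g]
        for i in range(p):
            bi = w * ty[g] * S[g, i]
            b[i] -= bi
            for j in range(p):
                A[i, j] -= w * S[g, i] * S[g, j]
    beta = np.linalg.solve(A, b)
    rss = c
    for i in range(p):
        rss -= b[i] * beta[i]
    if rss < 1e-300:
        rss = 1e-300
    return -0.5 * n * (LOG2PI + np.log(rss / n) + 1.0) - 0.5 * logdet


@njit(cache=True)
def _ml_max(XtX, Xty, yty, S, ty, gsz, n):
    """Maximise the profiled log-likelihood over lam >= 0.

    Returns (loglik, lam_hat).
    """
    best_ll = _profiled_ll(0.0, XtX, Xty, yty, S, ty, gsz, n)
    best_x = -np.inf  # log10(lam); -inf encodes lam = 0
    x = _GRID_LO
    while x <= _GRID_HI + 1e-9:
        ll = _profiled_ll(10.0**x, XtX, Xty, yty, S, ty, gsz, n)
        if ll > best_ll:
            best_ll = ll
            best_x = x
        x += _GRID_STEP
    if best_x == -np.inf:
        return best_ll, 0.0
    # golden-section refinement on log10(lam) around the grid optimum
    lo = best_x - _GRID_STEP
    hi = best_x + _GRID_STEP
    gr = 0.6180339887498949
    c1 = hi - gr * (hi - lo)
    c2 = lo + gr * (hi - lo)
    f1 = _profiled_ll(10.0**c1, XtX, Xty, yty, S, ty, gsz, n)
    f2 = _profiled_ll(10.0**c2, XtX, Xty, yty, S, ty, gsz, n)
    for _ in range(_GOLDEN_ITERS):
        if f1 < f2:
            lo = c1
            c1 = c2
            f1 = f2
            c2 = lo + gr * (hi - lo)
            f2 = _profiled_ll(10.0**c2, XtX, Xty, yty, S, ty, gsz, n)
        else:
            hi = c2
            c2 = c1
            f2 = f1
            c1 = hi - gr * (hi - lo)
            f1 = _profiled_ll(10.0**c1, XtX, Xty, yty, S, ty, gsz, n)
    xm = 0.5 * (lo + hi)
    fm = _profiled_ll(10.0**xm, XtX, Xty, yty, S, ty, gsz, n)
    if fm >= best_ll:
        return fm, 10.0**xm
    return best_ll, 10.0**best_x


@njit(cache=True)
def _suffstats_X(X, gidx, G):
    """X'X and per-group column sums of X."""
    n, p = X.shape
    XtX = X.T @ X
    S = np.zeros((G, p))
    for i in range(n):
        g = gidx[i]
        for j in range(p):
            S[g, j] += X[i, j]
    return XtX, S


@njit(cache=True)
def _suffstats_y(X, y, gidx, G):
    n, p = X.shape
    Xty = X.T @ y
    yty = float(y @ y)
    ty = np.zeros(G)
    for i in range(n):
        ty[gidx[i]] += y[i]
    return Xty, yty, ty


@njit(cache=True)
def _is_degenerate(yty, ty, n):
    """Response with (numerically) zero variance: both models saturate."""
    tot = 0.0
    for g in range(ty.shape[0]):
        tot += ty[g]
    sy = yty - tot * tot / n
    return sy <= 1e-12 * max(yty, 1e-300)


_SATURATED_LL = -0.5 * (np.log(2.0 * np.pi) + np.log(1e-300) + 1.0)


@njit(cache=True)
def _fit_pair(Xf, Xr, y, gidx, gsz):
    """Single-timepoint LRT: (chi2_raw, ll_full, ll_reduced)."""
    G = gsz.shape[0]
    n = y.shape[0]
    XtXf, Sf = _suffstats_X(Xf, gidx, G)
    XtXr, Sr = _suffstats_X(Xr, gidx, G)
    Xtyf, yty, ty = _suffstats_y(Xf, y, gidx, G)
    Xtyr = Xr.T @ y
    if _is_degenerate(yty, ty, n):
        ll = n * _SATURATED_LL
        return 0.0, ll, ll
    llf, _ = _ml_max(XtXf, Xtyf, yty, Sf, ty, gsz, n)
    llr, _ = _ml_max(XtXr, Xtyr, yty, Sr, ty, gsz, n)
    return 2.0 * (llf - llr), llf, llr


@njit(cache=True)
def _timecourse(Y, Xf, Xr, gidx, gsz):
    """LRT chi2 at every timepoint.  Y is (T, n)."""
    T, n = Y.shape
    G = gsz.shape[0]
    XtXf, Sf = _suffstats_X(Xf, gidx, G)
    XtXr, Sr = _suffstats_X(Xr, gidx, G)
    chi2 = np.empty(T)
    llf_arr = np.empty(T)
    llr_arr = np.empty(T)
    for t in range(T):
        y = Y[t]
        Xtyf, yty, ty = _suffstats_y(Xf, y, gidx, G)
        Xtyr = Xr.T @ y
        if _is_degenerate(yty, ty, n):
            chi2[t] = 0.0
            llf_arr[t] = n * _SATURATED_LL
            llr_arr[t] = n * _SATURATED_LL
            continue
        llf, _ = _ml_max(XtXf, Xtyf, yty, Sf, ty, gsz, n)
        llr, _ = _ml_max(XtXr, Xtyr, yty, Sr, ty, gsz, n)
        chi2[t] = 2.0 * (llf - llr)
        llf_arr[t] = llf
        llr_arr[t] = llr
    return chi2, llf_arr, llr_arr


@njit(cache=True)
def _biggest_cluster_mass(chi2, threshold):
    """Mass of the biggest run of strictly suprathreshold values (0 if none)."""
    best = 0.0
    cur = 0.0
    for t in range(chi2.shape[0]):
        if chi2[t] > threshold:
            cur += chi2[t]
            if cur > best:
                best = cur
        else:
            cur = 0.0
    return best


@njit(cache=True)
def _perm_null(Y, Xf, interest_cols, llr, gidx, gsz, group_rows, group_offsets,
               threshold, n_perm, seeds):
    """Null distribution of biggest-cluster masses under within-participant
    relabelling of the interest columns.

    The reduced model does not contain the interest terms, so its
    log-likelihoods (``llr``, precomputed) are invariant under the shuffle
    and only the full model is re-fitted.
    """
    T, n = Y.shape
    G = gsz.shape[0]
    null = np.empty(n_perm)
    Xp = Xf.copy()
    for b in range(n_perm):
        np.random.seed(seeds[b])
        # permute rows of the interest columns within each participant
        for g in range(G):
            rows = group_rows[group_offsets[g]:group_offsets[g + 1]]
            perm = np.random.permutation(rows.shape[0])
            for c in interest_cols:
                for k in range(rows.shape[0]):
                    Xp[rows[k], c] = Xf[rows[perm[k]], c]
        XtXp, Sp = _suffstats_X(Xp, gidx, G)
        chi2 = np.empty(T)
        for t in range(T):
            y = Y[t]
            Xty, yty, ty = _suffstats_y(Xp, y, gidx, G)
            if _is_degenerate(yty, ty, n):
                chi2[t] = 0.0
                continue
            llf, _ = _ml_max(XtXp, Xty, yty, Sp, ty, gsz, n)
            c2 = 2.0 * (llf - llr[t])
            chi2[t] = c2 if c2 > 0.0 else 0.0
        null[b] = _biggest_cluster_mass(chi2, threshold)
    return null


# ---------------------------------------------------------------------------
# plain-numpy single fits (used for EMMs and as a readable reference)


def ols_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian ML log-likelihood of an OLS fit (closed form)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return -0.5 * n * (LOG2PI + np.log(rss / n) + 1.0)


class RandomInterceptFit:
    """Result of a single random-intercept ML fit."""

    def __init__(self, loglik, lam, sigma2, beta, cov_beta, n, p):
        self.loglik = float(loglik)
        self.lam = float(lam)  # variance ratio sigma_b^2 / sigma_e^2
        self.sigma2 = float(sigma2)  # residual variance (ML)
        self.beta = beta
        self.cov_beta = cov_beta
        self.n = n
        self.p = p

    @property
    def intercept_variance(self) -> float:
        return self.lam * self.sigma2


def fit_random_intercept_ml(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> RandomInterceptFit:
    """Fit y = X beta + (1|group) + e by maximum likelihood.

    ``groups`` are integer codes.  Returns coefficient estimates with their
    GLS covariance evaluated at the ML variance ratio.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    gidx = np.ascontiguousarray(groups, dtype=np.int64)
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer observations ({n}) than columns ({p})")
    G = int(gidx.max()) + 1
    gsz = np.bincount(gidx, minlength=G).astype(np.float64)
    XtX, S = _suffstats_X(X, gidx, G)
    Xty, yty, ty = _suffstats_y(X, y, gidx, G)
    ll, lam = _ml_max(XtX, Xty, yty, S, ty, gsz, n)

    # GLS quantities at lam_hat
    w = lam / (1.0 + lam * gsz)
    A = XtX - (S * w[:, None]).T @ S
    b = Xty - S.T @ (w * ty)
    c = yty - float(w @ (ty * ty))
    beta = np.linalg.solve(A, b)
    rss = max(c - float(b @ beta), 1e-300)
    sigma2 = rss / n
    cov_beta = sigma2 * np.linalg.inv(A)
    return RandomInterceptFit(ll, lam, sigma2, beta, cov_beta, n, p)
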