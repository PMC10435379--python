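"""Vectorised logistic-regression scan: one binary outcome, fixed covariates,
and many candidate columns (genotype dosages) tested one at a time.

All variants are fitted simultaneously by batched Newton-Raphson; the
covariate-only null model is fitted once and reused for likelihood-ratio
tests.  Non-converged or separated fits fall back to a Jeffreys-penalised
(Firth) fit per variant.  This single engine backs the per-plate and
per-batch genotype-calling deviation tests and the association stand-in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 30
TOL = 1e-8
BETA_DIVERGED = 15.0


def _loglik(y, eta):
    # numerically safe Bernoulli log-likelihood with logit link
    return np.sum(y * eta - np.logaddexp(0.0, eta), axis=0)


def fit_null(y: np.ndarray, C: np.ndarray):
    """Newton fit of y ~ C. Returns (coef, loglik)."""
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    gamma = np.zeros(C.shape[1])
    for _ in range(MAX_ITER):
        eta = C @ gamma
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = C.T @ (y - mu)
        hess = (C * w[:, None]).T @ C
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        gamma = gamma + step
        if np.max(np.abs(step)) < TOL:
            break
    return gamma, float(_loglik(y, C @ gamma))


def logistic_scan(
    y: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    firth_fallback: bool = True,
    chunk_size: int = 4000,
) -> pd.DataFrame:
    """Per-column logistic regression of ``y`` on [C, G[:, v]].

    Parameters
    ----------
    y
        (n,) binary outcome.
    C
        (n, p) covariate matrix including the intercept column.
    G
        (n, m) tested columns; NaN entries are mean-imputed per column.
    chunk_size
        columns fitted per batched-Newton pass (bounds peak memory).

    Returns
    -------
    DataFrame with columns beta, se, p_wald, lrt, p_lrt, converged, flag.
    ``flag`` is '' | 'monomorphic' | 'firth' | 'not_converged'.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    G = np.asarray(G, dtype=float)
    m = G.shape[1]
    gamma0, ll0 = fit_null(y, C)
    if m > chunk_size:
        parts = [
            _scan_block(y, C, G[:, lo:lo + chunk_size], gamma0, ll0, firth_fallback)
            for lo in range(0, m, chunk_size)
        ]
        return pd.concat(parts, ignore_index=True)
    return _scan_block(y, C, G, gamma0, ll0, firth_fallback)


def _scan_block(y, C, G, gamma0, ll0, firth_fallback) -> pd.DataFrame:
    G = np.asarray(G, dtype=float).copy()
    n, p = C.shape
    m = G.shape[1]

    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    mono = np.nanstd(G, axis=0) == 0

    # parameter state: covariate coefs (p, m) + genotype coef (m,)
    Gam = np.tile(gamma0[:, None], (1, m))
    beta = np.zeros(m)
    active = ~mono
    # index pairs for the covariate-block Hessian via one GEMM
    iu = np.triu_indices(p)
    Cpairs = C[:, iu[0]] * C[:, iu[1]]          # (n, p*(p+1)/2)

    converged = np.zeros(m, dtype=bool)
    for _ in range(MAX_ITER):
        if not active.any():
            break
        eta = C @ Gam + G * beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        W = mu * (1 - mu)
        resid = y[:, None] - mu
        grad_c = C.T @ resid                     # (p, m)
        grad_g = np.sum(G * resid, axis=0)       # (m,)
        H_cc_flat = Cpairs.T @ W                 # (npairs, m)
        WG = W * G
        H_cg = C.T @ WG                          # (p, m)
        H_gg = np.sum(G * WG, axis=0)            # (m,)

        idx = np.flatnonzero(active)
        H = np.zeros((idx.size, p + 1, p + 1))
        H[:, iu[0], iu[1]] = H_cc_flat[:, idx].T
        H[:, iu[1], iu[0]] = H_cc_flat[:, idx].T
        H[:, :p, p] = H_cg[:, idx].T
        H[:, p, :p] = H_cg[:, idx].T
        H[:, p, p] = H_gg[idx]
        g_full = np.concatenate([grad_c[:, idx].T, grad_g[idx, None]], axis=1)
        # damped solve; singular systems are marked non-converged
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p + 1), g_full[:, :, None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.full((idx.size, p + 1), np.nan)
        bad = ~np.isfinite(step).all(axis=1)
        step[bad] = 0.0
        Gam[:, idx] += step[:, :p].T
        beta[idx] += step[:, p]
        done = np.max(np.abs(step), axis=1) < 1e-6
        converged[idx[done]] = True
        newly_bad = idx[bad]
        active[idx[done]] = False
        active[newly_bad] = False
        active[np.abs(beta) > BETA_DIVERGED] = False

    eta = C @ Gam + G * beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    W = mu * (1 - mu)
    ll_full = _loglik(y[:, None], eta)

    # Wald SE from the (p+1, p+1) observed information, variant by variant —
    # only the (p, p) corner varies through W so reuse the GEMM blocks
    H_cc_flat = Cpairs.T @ W
    WG = W * G
    H_cg = C.T @ WG
    H_gg = np.sum(G * WG, axis=0)
    se = np.full(m, np.nan)
    iu0, iu1 = iu
    ok = np.flatnonzero(~mono)
    if ok.size:
        Hall = np.zeros((ok.size, p + 1, p + 1))
        Hall[:, iu0, iu1] = H_cc_flat[:, ok].T
        Hall[:, iu1, iu0] = H_cc_flat[:, ok].T
        Hall[:, :p, p] = H_cg[:, ok].T
        Hall[:, p, :p] = H_cg[:, ok].T
        Hall[:, p, p] = H_gg[ok]
        ep = np.zeros(p + 1)
        ep[p] = 1.0
        try:
            rhs = np.broadcast_to(ep[:, None], (ok.size, p + 1, 1)).copy()
            last_col = np.linalg.solve(Hall, rhs)[..., 0]
            with np.errstate(invalid="ignore"):
                se[ok] = np.sqrt(last_col[:, p])
        except np.linalg.LinAlgError:
            for t, v in enumerate(ok):
                try:
                    se[v] = np.sqrt(np.linalg.inv(Hall[t])[p, p])
                except np.linalg.LinAlgError:
                    pass

    lrt = 2.0 * (ll_full - ll0)
    lrt = np.where(mono, np.nan, np.clip(lrt, 0, None))
    p_lrt = stats.chi2.sf(lrt, df=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = beta / se
    p_wald = 2.0 * stats.norm.sf(np.abs(zstat))

    flag = np.array([""] * m, dtype=object)
    flag[mono] = "monomorphic"
    needs_firth = (~mono) & (
        (~converged) | (np.abs(beta) > BETA_DIVERGED) | ~np.isfinite(se)
    )
    if firth_fallback:
        for v in np.flatnonzero(needs_firth):
            out = firth_fit(y, np.column_stack([C, G[:, v]]))
            if out is not None:
                b, s, ll = out
                beta[v], se[v] = b[p], s
                lrt[v] = np.nan  # penalised fit; LRT vs unpenalised null not comparable
                p_lrt[v] = np.nan
                p_wald[v] = 2.0 * stats.norm.sf(abs(b[p] / s)) if s > 0 else np.nan
                flag[v] = "firth"
            else:
                beta[v] = np.nan
                se[v] = np.nan
                p_wald[v] = np.nan
                p_lrt[v] = np.nan
                flag[v] = "not_converged"
    else:
        flag[needs_firth] = "not_converged"
        p_wald[needs_firth] = np.nan
        p_lrt[needs_firth] = np.nan

    # variants that converged cleanly keep LRT as the primary p-value
    pvalue = np.where(np.isfinite(p_lrt), p_lrt, p_wald)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p_wald": p_wald,
            "lrt": lrt,
            "p_lrt": p_lrt,
            "p": pvalue,
            "converged": converged | (flag == "firth"),
            "flag": flag,
        }
    )


def genotype_class_scan(
    y: np.ndarray,
    C: np.ndarray,
    calls: np.ndarray,
    chunk_size: int = 4000,
) -> pd.DataFrame:
    """Per-variant 2-df genotype-class logistic LRT of ``y`` on genotype.

    Adds heterozygote and minor-homozygote indicator columns to the covariate
    model and tests them jointly; sensitive to het->hom miscall artifacts
    that leave the dosage mean nearly unchanged.  Missing calls (<0) drop to
    the column means; the df shrinks when a genotype class is absent.

    Returns DataFrame with lrt, df, p, flag per variant.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    g = np.asarray(calls)
    _, ll0 = fit_null(y, C)
    rows = []
    for lo in range(0, g.shape[1], chunk_size):
        rows.append(_class_block(y, C, g[:, lo:lo + chunk_size], ll0))
    return pd.concat(rows, ignore_index=True)


def _class_block(y, C, g, ll0):
    n, p = C.shape
    m = g.shape[1]
    miss = g < 0
    H = [(g == 1).astype(float), (g == 2).astype(float)]
    for Hk in H:
        Hk[miss] = np.nan
        mu = np.nanmean(Hk, axis=0)
        bad = np.isnan(Hk)
        Hk[bad] = np.take(mu, np.nonzero(bad)[1])
    k = 2
    var_ok = np.stack([np.nanstd(Hk, axis=0) > 0 for Hk in H])  # (k, m)
    df = var_ok.sum(axis=0)
    gamma0, _ = fit_null(y, C)
    Gam = np.tile(gamma0[:, None], (1, m))
    beta = np.zeros((k, m))
    active = df > 0
    iu = np.triu_indices(p)
    Cpairs = C[:, iu[0]] * C[:, iu[1]]
    converged = np.zeros(m, dtype=bool)
    for _ in range(MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = C @ Gam + sum(H[j] * beta[j] for j in range(k))
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        W = mu * (1 - mu)
        resid = y[:, None] - mu
        grad_c = C.T @ resid
        grads_g = [np.sum(H[j] * resid, axis=0) for j in range(k)]
        Hcc = Cpairs.T @ W
        Hcg = [C.T @ (W * H[j]) for j in range(k)]
        Hgg = {}
        for a in range(k):
            for b in range(a, k):
                Hgg[(a, b)] = np.sum(H[a] * W * H[b], axis=0)
        d = p + k
        Hm = np.zeros((idx.size, d, d))
        Hm[:, iu[0], iu[1]] = Hcc[:, idx].T
        Hm[:, iu[1], iu[0]] = Hcc[:, idx].T
        for j in range(k):
            Hm[:, :p, p + j] = Hcg[j][:, idx].T
            Hm[:, p + j, :p] = Hcg[j][:, idx].T
        for a in range(k):
            for b in range(a, k):
                Hm[:, p + a, p + b] = Hgg[(a, b)][idx]
                Hm[:, p + b, p + a] = Hgg[(a, b)][idx]
        gvec = np.concatenate(
            [grad_c[:, idx].T] + [grads_g[j][idx, None] for j in range(k)], axis=1)
        # absent genotype classes: zero gradient, ridge keeps the solve stable
        step = np.linalg.solve(Hm + 1e-8 * np.eye(d), gvec[:, :, None])[..., 0]
        bad = ~np.isfinite(step).all(axis=1)
        step[bad] = 0.0
        Gam[:, idx] += step[:, :p].T
        for j in range(k):
            beta[j, idx] += step[:, p + j]
        done = np.max(np.abs(step), axis=1) < 1e-6
        converged[idx[done]] = True
        active[idx[done]] = False
        active[idx[bad]] = False
        active[np.max(np.abs(beta), axis=0) > BETA_DIVERGED] = False

    eta = C @ Gam + sum(H[j] * beta[j] for j in range(k))
    ll_full = _loglik(y[:, None], eta)
    lrt = np.clip(2.0 * (ll_full - ll0), 0, None)
    with np.errstate(invalid="ignore"):
        pval = np.where(df > 0, stats.chi2.sf(lrt, np.maximum(df, 1)), np.nan)
    flag = np.array([""] * m, dtype=object)
    flag[df == 0] = "monomorphic"
    flag[(df > 0) & ~converged] = "not_converged"
    pval[(df > 0) & ~converged] = np.nan
    return pd.DataFrame({"lrt": lrt, "df": df, "p": pval, "flag": flag})


def firth_fit(y: np.ndarray, X: np.ndarray, max_iter: int = 60):
    """Jeffreys-penalised logistic fit; returns (coef, se_last, penalised ll).

    Used as a fallback under (quasi-)separation, where the ordinary MLE
    diverges.  Returns None if the penalised fit itself fails.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    b = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ b, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XW = X * w[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        step = np.clip(step, -5, 5)
        b = b + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ b, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    try:
        se = float(np.sqrt(np.linalg.inv(info)[-1, -1]))
    except np.linalg.LinAlgError:
        return None
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return None
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * logdet)
    return b, se, ll


def region_design(region_ids) -> np.ndarray:
    """Intercept + region indicator columns (first level dropped)."""
    region_ids = pd.Series(region_ids).astype(str)
    levels = sorted(region_ids.unique())
    cols = [np.ones(len(region_ids))]
    for lev in levels[1:]:
        cols.append((region_ids == lev).to_numpy(dtype=float))
    return np.column_stack(cols)
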