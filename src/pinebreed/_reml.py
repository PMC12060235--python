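"""Restricted maximum likelihood (REML) solvers for Gaussian mixed models.

Two solvers cover every model fitted in this package.

``reml_spectral``
    y = Xb + g + e with g ~ N(0, sigma2_g * G) for a dense symmetric PSD
    kernel G (here: the genomic relationship matrix at clone level).
    G is eigendecomposed once, G = U D U', and the restricted log-likelihood
    is maximised over the single variance ratio lambda = sigma2_g / sigma2_e
    by bounded 1-D search on log(lambda).  In the rotated basis the
    covariance is diagonal, so each likelihood evaluation is O(n).

``reml_identity``
    y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k * I_{q_k}) for
    one-hot incidence matrices Z_k (year, ramet, clone factors).  Writing
    gamma_k = sigma2_k / sigma2_e and H = I + Z Gamma Z', the profiled
    restricted likelihood only needs q x q quantities via the Woodbury
    identity (q = total number of random levels):

        H^-1          = I - Z S M^-1 S Z',   M = I_q + S (Z'Z) S,
        log|H|        = log|M|,              S = diag(sqrt(gamma))

    so the cost per evaluation is O(q^3) regardless of the number of
    observations.  Z'Z, Z'X, Z'y etc. are precomputed once.

Both solvers profile out sigma2_e:

    -2 l_R(theta) = (n - p) log(sigma2_e_hat) + log|H| + log|X'H^-1 X| + C
    sigma2_e_hat  = y'P y / (n - p)

and return empirical BLUPs u_hat = Gamma Z' H^-1 (y - X b_hat) * 1 (the
ratio parameterisation makes sigma2_e cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize, minimize_scalar

_LOG2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# single dense kernel, spectral
# ----------------------------------------------------------------------
@dataclass
class SpectralFit:
    """Result of a single-kernel spectral REML fit."""

    sigma2_g: float
    sigma2_e: float
    ratio: float          # sigma2_g / sigma2_e
    beta: np.ndarray      # fixed effects (GLS at the optimum)
    blup: np.ndarray      # genetic values a_hat, one per observation/clone
    loglik: float         # restricted log-likelihood (up to an additive constant)
    eigvals: np.ndarray
    eigvecs: np.ndarray
    # U @ (w * U'(y - Xb)) at the optimum; gebv for new clones is
    # ratio * G_cross @ vinv_resid (= sigma2_g * G_cross V^-1 resid)
    vinv_resid: np.ndarray


def _profile_1d(loglam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """-2 restricted log-likelihood at variance ratio exp(loglam), rotated basis."""
    lam = np.exp(loglam)
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    ypy = float(r @ (w * r))
    n, p = Xt.shape
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or ypy <= 0:
        return np.inf
    return (n - p) * np.log(ypy / (n - p)) + float(np.sum(np.log(lam * d + 1.0))) + logdet_xwx


def reml_spectral(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    ratio_bounds: tuple[float, float] = (1e-9, 1e9),
    psd_tol: float = 1e-8,
) -> SpectralFit:
    """Fit y = Xb + g + e, g ~ N(0, sigma2_g G), e ~ N(0, sigma2_e I) by REML.

    Raises
    ------
    ValueError
        If G is asymmetric or indefinite beyond tolerance, X is rank
        deficient, or y has zero variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = np.asarray(G, dtype=float)
    n, p = X.shape
    if G.shape != (n, n):
        raise ValueError(f"G shape {G.shape} does not match n={n}")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G is not symmetric")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {n}")
    if np.var(y) == 0:
        raise ValueError("degenerate response: zero phenotypic variance")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is rank deficient")

    d, U = np.linalg.eigh((G + G.T) / 2.0)
    trace = float(np.sum(np.clip(d, 0, None)))
    if d.min() < -psd_tol * max(trace, 1.0):
        raise ValueError(f"G is not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)

    yt = U.T @ y
    Xt = U.T @ X
    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = minimize_scalar(
        _profile_1d,
        args=(d, yt, Xt),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))

    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    rt = yt - Xt @ beta
    sigma2_e = float(rt @ (w * rt)) / (n - p)
    sigma2_g = lam * sigma2_e
    vinv_resid = U @ (w * rt)          # = V^-1 (y - Xb) * sigma2_e
    blup = lam * (U @ (d * w * rt))    # = sigma2_g G V^-1 (y - Xb)
    loglik = -0.5 * (res.fun + (n - p) * (1.0 + _LOG2PI))
    return SpectralFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        ratio=lam,
        beta=beta,
        blup=blup,
        loglik=loglik,
        eigvals=d,
        eigvecs=U,
        vinv_resid=vinv_resid,
    )


# ----------------------------------------------------------------------
# multiple identity kernels, Woodbury
# ----------------------------------------------------------------------
@dataclass
class IdentityFit:
    """Result of a multi-kernel identity REML fit."""

    sigma2: list[float]       # one variance per random factor
    sigma2_e: float
    gammas: list[float]       # sigma2_k / sigma2_e
    beta: np.ndarray
    blups: list[np.ndarray]   # one BLUP vector per random factor
    loglik: float


def _factor_m(A, blocks, gammas):
    """Factor M = I + S A S and return (solve, logdetM), or (None, None).

    When every within-block Gram matrix is diagonal (one-hot factors), the
    largest block is eliminated by a Schur complement so the dense work is
    only on the remaining (small) blocks; otherwise a dense Cholesky of the
    full q x q matrix is used.
    """
    q = A.shape[0]
    s = np.sqrt(np.concatenate([np.full(m, g) for m, g in zip(blocks, gammas)]))
    offsets = np.cumsum([0] + list(blocks))
    diag_blocks = True
    for k, m in enumerate(blocks):
        sub = A[offsets[k] : offsets[k + 1], offsets[k] : offsets[k + 1]]
        if not np.array_equal(sub, np.diag(np.diag(sub))):
            diag_blocks = False
            break
    if diag_blocks:
        big = int(np.argmax(blocks))
        b0, b1 = offsets[big], offsets[big + 1]
        small = np.r_[np.arange(0, b0), np.arange(b1, q)]
        m_b = 1.0 + gammas[big] * np.diag(A)[b0:b1]
        if len(small) == 0:
            logdet = float(np.sum(np.log(m_b)))

            def solve(R):
                return (R.T / m_b).T

            return solve, logdet, s
        s_s = s[small]
        M_ss = np.eye(len(small)) + (s_s[:, None] * A[np.ix_(small, small)]) * s_s[None, :]
        M_sb = (s_s[:, None] * A[small][:, b0:b1]) * s[b0:b1][None, :]
        schur = M_ss - (M_sb / m_b[None, :]) @ M_sb.T
        sign, ld = np.linalg.slogdet(schur)
        if sign <= 0:
            return None, None, s
        logdet = float(np.sum(np.log(m_b))) + ld

        def solve(R):
            R = np.asarray(R, dtype=float)
            vec = R.ndim == 1
            Rm = R[:, None] if vec else R
            R_s, R_b = Rm[small], Rm[b0:b1]
            t = R_b / m_b[:, None]
            z_s = np.linalg.solve(schur, R_s - M_sb @ t)
            z_b = (R_b - M_sb.T @ z_s) / m_b[:, None]
            out = np.empty_like(Rm)
            out[small] = z_s
            out[b0:b1] = z_b
            return out[:, 0] if vec else out

        return solve, logdet, s
    M = np.eye(q) + (s[:, None] * A) * s[None, :]
    try:
        cf = sla.cho_factor(M, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return None, None, s
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

    def solve(R):
        return sla.cho_solve(cf, R, check_finite=False)

    return solve, logdet, s


def _identity_neg2lr(phi, blocks, precomp):
    A, B, c, XtX, Xty, yty, n, p = precomp
    gammas = np.exp(np.asarray(phi, dtype=float))
    solve, logdetM, s = _factor_m(A, blocks, gammas)
    if solve is None:
        return np.inf, None
    sB = s[:, None] * B
    sc = s * c
    WsB = solve(sB)
    Wsc = solve(sc)
    XtHX = XtX - sB.T @ WsB
    XtHy = Xty - sB.T @ Wsc
    ytHy = yty - float(sc @ Wsc)
    sign, logdet_xhx = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(XtHX, XtHy)
    ypy = ytHy - float(XtHy @ beta)
    if ypy <= 0:
        return np.inf, None
    val = (n - p) * np.log(ypy / (n - p)) + logdetM + logdet_xhx
    return val, (beta, ypy, solve, s)


def reml_identity(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list,
    start: np.ndarray | None = None,
    gamma_bounds: tuple[float, float] = (1e-12, 1e8),
) -> IdentityFit:
    """Fit y = Xb + sum_k Z_k u_k + e by REML over the variance ratios.

    ``Z_list`` holds one-hot (dense or scipy.sparse) incidence matrices.
    With a single random factor the ratio is found by bounded 1-D search;
    with several, Nelder-Mead on the log-ratios is followed by a
    coordinate-wise bounded refinement for a sharp optimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is rank deficient")
    Zs = [sp.csr_matrix(Z) for Z in Z_list]
    blocks = [Z.shape[1] for Z in Zs]
    Z = sp.hstack(Zs, format="csr")
    A = (Z.T @ Z).toarray()
    B = np.asarray(Z.T @ X)
    c = np.asarray(Z.T @ y).ravel()
    precomp = (A, B, c, X.T @ X, X.T @ y, float(y @ y), n, p)
    k = len(blocks)
    lo, hi = np.log(gamma_bounds[0]), np.log(gamma_bounds[1])

    if k == 1:
        res = minimize_scalar(
            lambda phi: _identity_neg2lr([phi], blocks, precomp)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        phi_opt = np.array([res.x])
    else:
        x0 = np.zeros(k) if start is None else np.log(np.asarray(start, dtype=float))
        res = minimize(
            lambda phi: _identity_neg2lr(np.clip(phi, lo, hi), blocks, precomp)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 600, "maxfev": 600},
        )
        phi_opt = np.clip(res.x, lo, hi)
        # coordinate-wise polish around the Nelder-Mead solution
        for _ in range(2):
            for j in range(k):
                def f1(v, j=j):
                    ph = phi_opt.copy()
                    ph[j] = v
                    return _identity_neg2lr(ph, blocks, precomp)[0]
                r1 = minimize_scalar(
                    f1, bounds=(max(lo, phi_opt[j] - 1.0), min(hi, phi_opt[j] + 1.0)),
                    method="bounded", options={"xatol": 1e-9},
                )
                phi_opt[j] = r1.x

    fun, aux = _identity_neg2lr(phi_opt, blocks, precomp)
    if aux is None:
        raise RuntimeError("REML optimisation failed (degenerate likelihood)")
    beta, ypy, solve, s = aux
    gammas = np.exp(phi_opt)
    sigma2_e = ypy / (n - p)
    # u = Gamma Z' H^-1 r ;  Z' H^-1 r = t - A S M^-1 S t  with  t = Z'r
    t = c - B @ beta
    zhr = t - A @ (s * solve(s * t))
    gamma_vec = np.concatenate([np.full(q, g) for q, g in zip(blocks, gammas)])
    u = gamma_vec * zhr
    blups, off = [], 0
    for q in blocks:
        blups.append(u[off : off + q])
        off += q
    loglik = -0.5 * (fun + (n - p) * (1.0 + _LOG2PI))
    return IdentityFit(
        sigma2=[float(g * sigma2_e) for g in gammas],
        sigma2_e=float(sigma2_e),
        gammas=[float(g) for g in gammas],
        beta=beta,
        blups=blups,
        loglik=loglik,
    )
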