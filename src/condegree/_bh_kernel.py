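"""Low-level product-partition change-point kernel.

Model: an ordered series x_1..x_n is partitioned into contiguous blocks by
change indicators U_1..U_{n-1}; within a block observations are
N(mu_block, sigma^2) with the block mean drawn N(mu0, sigma0^2 / block_len).
With w = sigma^2 / (sigma^2 + sigma0^2), flat priors on mu0 and log sigma^2,
p ~ U(0, p0) on the per-position change probability and w ~ U(0, w0),
integrating everything but the partition out gives

    f(X | U) ∝ [∫_0^{p0} p^{b-1} (1-p)^{n-b} dp]
               x [∫_0^{w0} w^{(b-1)/2} / (W + B w)^{(n-1)/2} dw]

where b is the number of blocks, W the within-block and B the between-block
sum of squares (W + B = total SS, so only B/T matters).  The w-integral has a
closed form through t = Bw/(W+Bw):

    ∫_0^{w0} w^{(b-1)/2} (W+Bw)^{-(n-1)/2} dw
        = W^{a-beta} B^{-a} Beta(a, b') I_{t0}(a, b'),
    a = (b+1)/2,  beta = (n-1)/2,  b' = (n-b-2)/2,  t0 = B w0 / (W + B w0),

valid for b <= n-3 and W, B > 0; the remaining cases are handled explicitly
(see ``_log_w_integral``).  The Gibbs sweep updates each U_i from its
conditional odds; log I_{t0}(a, b') is linearly interpolated on a dense
ln(t0) grid precomputed per (n, p0, w0) with scipy, which keeps one indicator
update at a handful of flops.

Everything in this module is private; the public surface is `changepoint`.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy import special

# --- shared numerical conventions (mirrored by the exact enumerator) -------
GRID = 4096
UMIN = float(np.log(1e-32))  # lower edge of the ln(t0) interpolation grid
VMIN = float(np.log(1e-16))  # lower edge of the ln(1-t0) near-one grid
VMAX = float(np.log(0.5))
BIG = 500.0  # -ln(delta): orders diverging perfect-fit (W=0) partitions
ZERO_TOL = 1e-13  # variance share below this is treated as exactly zero
CLAMP = 35.0  # |log-odds| beyond this is treated as deterministic
N_GL = 64  # Gauss-Legendre nodes for the rare b >= n-2 fallback


def log_p_integral(k, m, p0: float):
    """log ∫_0^{p0} p^k (1-p)^m dp (vectorised; small-p0 underflow safe)."""
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    lbeta = special.betaln(k + 1.0, m + 1.0)
    with np.errstate(divide="ignore"):
        out = lbeta + np.log(special.betainc(k + 1.0, m + 1.0, p0))
    # I_x(a,b) ~ x^a / (a B(a,b)) for x -> 0
    asym = (k + 1.0) * np.log(p0) - np.log(k + 1.0)
    return np.where(np.isfinite(out), out, asym)


class BHTables(NamedTuple):
    """Precomputed integral tables for a given (n, p0, w0)."""

    n: int
    p0: float
    w0: float
    a: np.ndarray  # a_b = (b+1)/2, indexed by block count b
    bp: np.ndarray  # b'_b = (n-b-2)/2
    lbeta: np.ndarray  # ln Beta(a_b, b'_b) where b' > 0, else 0
    log_i: np.ndarray  # (n+1, GRID) table of ln I_{t0}(a_b, b'_b)
    du: float  # grid spacing in ln(t0)
    log_i1: np.ndarray  # (n+1, GRID) table of ln I vs ln(1-t0) (t0 near 1)
    dv: float  # grid spacing in ln(1-t0)
    logpodds: np.ndarray  # prior odds term, indexed by b0 (blocks when U_i=0)
    logprior: np.ndarray  # ln ∫ p^{b-1}(1-p)^{n-b} dp, indexed by b
    glx: np.ndarray  # Gauss-Legendre nodes on (0, w0)
    lglw: np.ndarray  # ln of the matching weights


@lru_cache(maxsize=128)
def engine_tables(n: int, p0: float, w0: float) -> BHTables:
    b = np.arange(0, n + 1, dtype=float)
    a = (b + 1.0) / 2.0
    bp = (n - b - 2.0) / 2.0
    lbeta = np.zeros(n + 1)
    ok = bp > 0
    lbeta[ok] = special.betaln(a[ok], bp[ok])

    u = np.linspace(UMIN, 0.0, GRID)
    t0 = np.exp(u)
    v = np.linspace(VMIN, VMAX, GRID)
    omt0 = np.exp(v)
    log_i = np.zeros((n + 1, GRID))
    log_i1 = np.zeros((n + 1, GRID))
    for bi in range(1, n + 1):
        if bp[bi] <= 0:
            continue
        with np.errstate(divide="ignore"):
            li = np.log(special.betainc(a[bi], bp[bi], t0))
        asym = a[bi] * u - np.log(a[bi]) - lbeta[bi]
        log_i[bi] = np.where(np.isfinite(li), li, asym)
        # near t0 = 1 (fractional b' gives a cusp in t0): tabulate against
        # ln(1 - t0), where ln I is smooth
        small = special.betainc(bp[bi], a[bi], omt0)
        with np.errstate(divide="ignore"):
            log_i1[bi] = np.log1p(-np.clip(small, 0.0, 1 - 1e-16))

    b0 = np.arange(1, n, dtype=float)
    logpodds = np.zeros(n + 1)
    logpodds[1:n] = log_p_integral(b0, n - 1.0 - b0, p0) - log_p_integral(
        b0 - 1.0, n - b0, p0
    )
    bb = np.arange(1, n + 1, dtype=float)
    logprior = np.zeros(n + 1)
    logprior[1:] = log_p_integral(bb - 1.0, n - bb, p0)

    gx, gw = np.polynomial.legendre.leggauss(N_GL)
    glx = (gx + 1.0) / 2.0 * w0
    lglw = np.log(gw * w0 / 2.0)

    return BHTables(
        n=n,
        p0=p0,
        w0=w0,
        a=a,
        bp=bp,
        lbeta=lbeta,
        log_i=log_i,
        du=float(u[1] - u[0]),
        log_i1=log_i1,
        dv=float(v[1] - v[0]),
        logpodds=logpodds,
        logprior=logprior,
        glx=glx,
        lglw=lglw,
    )


@njit(cache=True)
def _log_w_integral(Q, T, b, n, w0, a, bp, lbeta, log_i, du, log_i1, dv, glx, lglw):
    """ln ∫_0^{w0} w^{(b-1)/2} (Wn + Bn w)^{-(n-1)/2} dw with Bn=Q/T, Wn=1-Bn.

    The common factor T^{-(n-1)/2} is dropped (it cancels in every ratio and
    normalisation this kernel is used for).
    """
    ab = a[b]
    if T <= 0.0:
        # globally constant series: the data term carries no information
        return ab * np.log(w0) - np.log(ab)
    beta = 0.5 * (n - 1.0)
    Bn = Q / T
    if Bn > 1.0:
        Bn = 1.0
    if Bn < ZERO_TOL:
        # no between-block variance (Wn = 1)
        return ab * np.log(w0) - np.log(ab)
    Wn = 1.0 - Bn
    if Wn < ZERO_TOL:
        # perfect within-block fit; integrable only for b >= n-1
        if b >= n - 1:
            g = 0.5 * (b - n + 2.0)
            return -beta * np.log(Bn) + g * np.log(w0) - np.log(g)
        # divergent: delta-truncated in log space so the coarsest perfect-fit
        # partition dominates (the correct sigma -> 0 limit)
        return 0.5 * (n - b - 2.0) * BIG - beta * np.log(Bn)
    bpb = bp[b]
    if bpb <= 0.0:
        # b in {n-2, n-1, n}: bounded integrand, Gauss-Legendre in log space
        hb = 0.5 * (b - 1.0)
        m = -1.0e308
        for j in range(glx.size):
            e = hb * np.log(glx[j]) - beta * np.log(Wn + Bn * glx[j]) + lglw[j]
            if e > m:
                m = e
        s = 0.0
        for j in range(glx.size):
            e = hb * np.log(glx[j]) - beta * np.log(Wn + Bn * glx[j]) + lglw[j]
            s += np.exp(e - m)
        return m + np.log(s)
    denom = Wn + Bn * w0
    t0 = Bn * w0 / denom
    omt0 = Wn / denom
    if omt0 <= 0.5:
        # near-one branch, interpolated against ln(1 - t0)
        vv = np.log(omt0)
        if vv <= VMIN:
            li = -np.exp(bpb * vv - np.log(bpb) - lbeta[b])
        else:
            pos = (vv - VMIN) / dv
            j = int(pos)
            if j >= GRID - 1:
                j = GRID - 2
            fr = pos - j
            li = log_i1[b, j] * (1.0 - fr) + log_i1[b, j + 1] * fr
    else:
        uu = np.log(t0)
        if uu <= UMIN:
            li = ab * uu - np.log(ab) - lbeta[b]
        else:
            pos = (uu - UMIN) / du
            j = int(pos)
            if j >= GRID - 1:
                j = GRID - 2
            fr = pos - j
            li = log_i[b, j] * (1.0 - fr) + log_i[b, j + 1] * fr
    return (ab - beta) * np.log(Wn) - ab * np.log(Bn) + lbeta[b] + li


@njit(cache=True)
def _gibbs_one(
    x, seed, w0, burnin, sweeps, logpodds, a, bp, lbeta, log_i, du,
    log_i1, dv, glx, lglw, cnt, msum,
):
    """One Gibbs chain; accumulates post-burnin U frequencies into ``cnt``
    and per-position block-mean sums into ``msum`` (both caller-zeroed)."""
    n = x.size
    np.random.seed(seed)
    mu = 0.0
    for i in range(n):
        mu += x[i]
    mu /= n
    S = np.zeros(n + 1)
    T = 0.0
    for i in range(n):
        xc = x[i] - mu
        S[i + 1] = S[i] + xc
        T += xc * xc
    U = np.zeros(n - 1, dtype=np.uint8)
    nblocks = 1
    Q = 0.0
    for it in range(burnin + sweeps):
        # refresh Q from the partition once per sweep (numerical hygiene)
        Q = 0.0
        start = 0
        for idx in range(n - 1):
            if U[idx] == 1:
                s = S[idx + 1] - S[start]
                Q += s * s / (idx + 1 - start)
                start = idx + 1
        s = S[n] - S[start]
        Q += s * s / (n - start)
        for j in range(n - 1):
            L = j
            while L > 0 and U[L - 1] == 0:
                L -= 1
            E = j + 1
            while E < n - 1 and U[E] == 0:
                E += 1
            s1 = S[j + 1] - S[L]
            n1 = j + 1 - L
            s2 = S[E + 1] - S[j + 1]
            n2 = E - j
            qs = s1 * s1 / n1 + s2 * s2 / n2
            sm = s1 + s2
            qm = sm * sm / (n1 + n2)
            if U[j] == 1:
                b0 = nblocks - 1
                Q1 = Q
                Q0 = Q - qs + qm
            else:
                b0 = nblocks
                Q0 = Q
                Q1 = Q - qm + qs
            lo = (
                logpodds[b0]
                + _log_w_integral(
                    Q1, T, b0 + 1, n, w0, a, bp, lbeta, log_i, du,
                    log_i1, dv, glx, lglw,
                )
                - _log_w_integral(
                    Q0, T, b0, n, w0, a, bp, lbeta, log_i, du,
                    log_i1, dv, glx, lglw,
                )
            )
            if lo > CLAMP:
                nu = 1
            elif lo < -CLAMP:
                nu = 0
            else:
                p = 1.0 / (1.0 + np.exp(-lo))
                nu = 1 if np.random.random() < p else 0
            if nu != U[j]:
                if nu == 1:
                    U[j] = 1
                    nblocks += 1
                    Q = Q1
                else:
                    U[j] = 0
                    nblocks -= 1
                    Q = Q0
        if it >= burnin:
            for j in range(n - 1):
                cnt[j] += U[j]
            start = 0
            for idx in range(n - 1):
                if U[idx] == 1:
                    bm = (S[idx + 1] - S[start]) / (idx + 1 - start)
                    for t in range(start, idx + 1):
                        msum[t] += bm
                    start = idx + 1
            bm = (S[n] - S[start]) / (n - start)
            for t in range(start, n):
                msum[t] += bm


@njit(cache=True)
def _gibbs_batch(
    X, seeds, w0, burnin, sweeps, bidx, logpodds, a, bp, lbeta, log_i, du,
    log_i1, dv, glx, lglw,
):
    """Run one chain per row of X; return the change frequency at ``bidx``."""
    R, n = X.shape
    out = np.empty(R)
    cnt = np.zeros(n - 1)
    msum = np.zeros(n)
    for r in range(R):
        for j in range(n - 1):
            cnt[j] = 0.0
        for t in range(n):
            msum[t] = 0.0
        _gibbs_one(
            X[r], seeds[r], w0, burnin, sweeps, logpodds, a, bp, lbeta, log_i, du,
            log_i1, dv, glx, lglw, cnt, msum,
        )
        out[r] = cnt[bidx] / sweeps
    return out


def gibbs_run(x: np.ndarray, seed: int, tab: BHTables, burnin: int, sweeps: int):
    """Python entry: one chain, full change-probability and mean vectors."""
    n = x.size
    cnt = np.zeros(n - 1)
    msum = np.zeros(n)
    _gibbs_one(
        np.ascontiguousarray(x, dtype=np.float64),
        np.int64(seed),
        tab.w0,
        np.int64(burnin),
        np.int64(sweeps),
        tab.logpodds,
        tab.a,
        tab.bp,
        tab.lbeta,
        tab.log_i,
        tab.du,
        tab.log_i1,
        tab.dv,
        tab.glx,
        tab.lglw,
        cnt,
        msum,
    )
    change_prob = cnt / sweeps
    posterior_mean = msum / sweeps + float(np.mean(x))
    return change_prob, posterior_mean


def gibbs_boundary_batch(
    X: np.ndarray, seeds: np.ndarray, boundary: int, tab: BHTables, burnin: int, sweeps: int
) -> np.ndarray:
    """Python entry: many chains, boundary change frequency per chain.

    ``boundary`` is the 1-based position count, i.e. the change between
    positions ``boundary`` and ``boundary + 1``.
    """
    return _gibbs_batch(
        np.ascontiguousarray(X, dtype=np.float64),
        np.asarray(seeds, dtype=np.int64),
        tab.w0,
        np.int64(burnin),
        np.int64(sweeps),
        np.int64(boundary - 1),
        tab.logpodds,
        tab.a,
        tab.bp,
        tab.lbeta,
        tab.log_i,
        tab.du,
        tab.log_i1,
        tab.dv,
        tab.glx,
        tab.lglw,
    )


# --- exact (non-interpolated) evaluation, shared by the enumerator ---------


def log_w_integral_exact(Q: float, T: float, b: int, n: int, w0: float) -> float:
    """Reference evaluation of the w-integral: identical case logic to the
    kernel but scipy's incomplete beta instead of the interpolation table,
    and adaptive quadrature for the b >= n-2 fallback."""
    a = (b + 1.0) / 2.0
    if T <= 0.0:
        return a * np.log(w0) - np.log(a)
    beta = 0.5 * (n - 1.0)
    Bn = min(Q / T, 1.0)
    if Bn < ZERO_TOL:
        return a * np.log(w0) - np.log(a)
    Wn = 1.0 - Bn
    if Wn < ZERO_TOL:
        if b >= n - 1:
            g = 0.5 * (b - n + 2.0)
            return -beta * np.log(Bn) + g * np.log(w0) - np.log(g)
        return 0.5 * (n - b - 2.0) * BIG - beta * np.log(Bn)
    bprime = (n - b - 2.0) / 2.0
    if bprime <= 0.0:
        from scipy.integrate import quad

        val, _ = quad(
            lambda w: w ** (0.5 * (b - 1.0)) * (Wn + Bn * w) ** (-beta),
            0.0,
            w0,
            epsabs=1e-300,
            epsrel=1e-12,
            limit=200,
        )
        return float(np.log(val))
    t0 = Bn * w0 / (Wn + Bn * w0)
    lbeta = special.betaln(a, bprime)
    with np.errstate(divide="ignore"):
        li = float(np.log(special.betainc(a, bprime, t0)))
    if not np.isfinite(li):
        li = a * np.log(t0) - np.log(a) - lbeta
    return (a - beta) * np.log(Wn) - a * np.log(Bn) + lbeta + li


def log_w_integral_quad(Q: float, T: float, b: int, n: int, w0: float) -> float:
    """Direct adaptive quadrature of the same integral (cross-check path).

    Only valid away from the degenerate W=0 regime.
    """
    from scipy.integrate import quad

    beta = 0.5 * (n - 1.0)
    Bn = min(Q / T, 1.0)
    Wn = 1.0 - Bn
    val, _ = quad(
        lambda w: w ** (0.5 * (b - 1.0)) * (Wn + Bn * w) ** (-beta),
        0.0,
        w0,
        epsabs=1e-300,
        epsrel=1e-12,
        limit=500,
    )
    return float(np.log(val))
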