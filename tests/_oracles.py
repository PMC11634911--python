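"""Independently coded brute-force oracles for the feature and regression
operations. Everything here is written with explicit loops and first
principles (no reuse of the package's vectorized implementations)."""

import math

import numpy as np


def setA_oracle(energies, centers):
    """Spectral flux/kurtosis/skewness/slope by explicit per-frame loops."""
    energies = np.asarray(energies, float)
    centers = np.asarray(centers, float)
    kurts, skews, slopes = [], [], []
    for s in energies:
        tot = s.sum()
        if tot <= 0:
            continue
        mu = sum(f * e for f, e in zip(centers, s)) / tot
        var = sum((f - mu) ** 2 * e for f, e in zip(centers, s)) / tot
        fbar = centers.mean()
        sbar = s.mean()
        num = sum((f - fbar) * (e - sbar) for f, e in zip(centers, s))
        den = sum((f - fbar) ** 2 for f in centers)
        slopes.append(num / den)
        if var <= 0:
            continue
        sd = math.sqrt(var)
        m3 = sum((f - mu) ** 3 * e for f, e in zip(centers, s)) / tot
        m4 = sum((f - mu) ** 4 * e for f, e in zip(centers, s)) / tot
        skews.append(m3 / sd ** 3)
        kurts.append(m4 / sd ** 4)
    fluxes = []
    for a, b in zip(energies[:-1], energies[1:]):
        if a.sum() <= 0 or b.sum() <= 0:
            continue
        na = a / a.sum()
        nb = b / b.sum()
        fluxes.append(math.sqrt(sum((x - y) ** 2 for x, y in zip(nb, na))))
    flux = float(np.mean(fluxes)) if fluxes else 0.0
    return (flux, float(np.mean(kurts)), float(np.mean(skews)),
            float(np.mean(slopes)))


def dct2_ortho_oracle(x):
    """Orthonormal DCT-II of one vector by the explicit cosine sum."""
    x = np.asarray(x, float)
    n = len(x)
    out = np.zeros(n)
    for k in range(n):
        s = sum(x[j] * math.cos(math.pi * k * (2 * j + 1) / (2 * n))
                for j in range(n))
        scale = math.sqrt(1.0 / n) if k == 0 else math.sqrt(2.0 / n)
        out[k] = scale * s
    return out


def delta_oracle(c, width=2):
    """Regression delta over frames with edge replication, explicit loops."""
    c = np.asarray(c, float)
    t_max = len(c)
    denom = 2 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    for t in range(t_max):
        acc = np.zeros(c.shape[1])
        for n in range(1, width + 1):
            hi = c[min(t + n, t_max - 1)]
            lo = c[max(t - n, 0)]
            acc += n * (hi - lo)
        out[t] = acc / denom
    return out


def mfcc_dd_oracle(energies, floor, first=0, n_keep=13, width=2):
    """Delta-delta MFCC vector via the explicit DCT and delta oracles."""
    energies = np.asarray(energies, float)
    logE = np.log(energies + floor)
    cep = np.array([dct2_ortho_oracle(row) for row in logE])
    cep = cep[:, first:first + n_keep]
    dd = delta_oracle(delta_oracle(cep, width), width)
    return dd.mean(axis=0)


def ols_oracle(X, y):
    """OLS with intercept via explicit normal equations.

    Returns (intercept, coefficients, r_squared, rmse_dof_corrected).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / (n - p - 1))
    return float(beta[0]), beta[1:], r2, rmse
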