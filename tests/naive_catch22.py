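"""Independent, deliberately naive re-implementation of the 22-feature set.

Used as the oracle for ``caflux.catch22``: every feature is recomputed
here from its written definition with plain loops, O(N²) transforms and
library fitting routines (``np.polyfit``, B-spline least squares)
instead of the package's vectorized/FFT paths.  Nothing here is shared
with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def zscore(y):
    return (y - np.mean(y)) / np.std(y)


def acf_naive(y, max_lag=None):
    """O(N·L) biased autocorrelation by direct summation."""
    n = len(y)
    if max_lag is None:
        max_lag = n - 1
    y = y - np.mean(y)
    denom = sum(v * v for v in y) / n
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        s = 0.0
        for i in range(n - lag):
            s += y[i] * y[i + lag]
        out[lag] = (s / n) / denom
    return out


def first_zero(acf):
    for i in range(1, len(acf)):
        if acf[i] <= 0:
            return i
    return len(acf)


def histogram_mode(y, nbins):
    edges = np.linspace(min(y), max(y), nbins + 1)
    counts, _ = np.histogram(y, bins=edges)
    centers = [(edges[i] + edges[i + 1]) / 2 for i in range(nbins)]
    mx = max(counts)
    winners = [c for c, k in zip(centers, counts) if k == mx]
    return sum(winners) / len(winners)


def f1ecac(acf):
    th = 1.0 / math.e
    for i in range(1, len(acf)):
        if acf[i] < th:
            return (i - 1) + (acf[i - 1] - th) / (acf[i - 1] - acf[i])
    return float(len(acf))


def first_min_ac(acf):
    for i in range(1, len(acf) - 1):
        if acf[i] < acf[i - 1] and acf[i] < acf[i + 1]:
            return float(i)
    return float(len(acf))


def longstretch(binary, target):
    best = cur = 0
    for b in binary:
        cur = cur + 1 if b == target else 0
        best = max(best, cur)
    return float(best)


def hist_ami_even_2_5(y):
    tau, nbins = 2, 5
    edges = np.linspace(min(y), max(y), nbins + 1)
    edges[-1] += 1e-12
    joint = np.zeros((nbins, nbins))
    for a, b in zip(y[:-tau], y[tau:]):
        i = min(np.searchsorted(edges, a, side="right") - 1, nbins - 1)
        j = min(np.searchsorted(edges, b, side="right") - 1, nbins - 1)
        joint[i, j] += 1
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ami = 0.0
    for i in range(nbins):
        for j in range(nbins):
            if p[i, j] > 0:
                ami += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return ami


def quantile_symbols(y, k=3):
    qs = np.quantile(y, [i / k for i in range(1, k)])
    return np.array([int(np.searchsorted(qs, v, side="left")) for v in y])


def transition_matrix_sumdiagcov(y, acf):
    tau = max(first_zero(acf), 1)
    ds = y[::tau]
    if len(ds) < 4:
        return 0.0
    sym = quantile_symbols(ds)
    T = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        T[a, b] += 1
    T /= len(sym) - 1
    # covariance between the three columns, ddof=1
    cols = [T[:, j] for j in range(3)]
    means = [c.mean() for c in cols]
    return sum(
        float(((cols[j] - means[j]) ** 2).sum()) / 2.0 for j in range(3)
    )


def periodicity_wang(y):
    from scipy.interpolate import BSpline

    n = len(y)
    x = np.arange(n, dtype=float)
    # least-squares cubic spline with one interior knot at the middle,
    # built explicitly from the B-spline design matrix
    k = 3
    t_int = [x[n // 2]]
    t = np.r_[[x[0]] * (k + 1), t_int, [x[-1]] * (k + 1)]
    nb = len(t) - k - 1
    B = np.empty((n, nb))
    for j in range(nb):
        cj = np.zeros(nb)
        cj[j] = 1.0
        B[:, j] = BSpline(t, cj, k)(x)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    resid = resid - resid.mean()
    max_lag = max(int(math.ceil(n / 3.0)), 3)
    ac = acf_naive(resid, max_lag)
    troughs = [i for i in range(1, len(ac) - 1) if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]]
    peaks = [i for i in range(1, len(ac) - 1) if ac[i] > ac[i - 1] and ac[i] > ac[i + 1]]
    for tr in troughs:
        after = [p for p in peaks if p > tr]
        if after and ac[after[0]] - ac[tr] >= 0.01 and ac[after[0]] > 0:
            return float(after[0])
    return 0.0


def embed2_dist_expfit_meandiff(y, acf):
    n = len(y)
    tau = first_zero(acf)
    if tau > n / 10:
        tau = max(n // 10, 1)
    m = n - tau - 1
    if m < 3:
        return 0.0
    d = [
        math.hypot(y[i + 1] - y[i], y[i + 1 + tau] - y[i + tau]) for i in range(m)
    ]
    lam = sum(d) / len(d)
    if lam <= 0:
        return 0.0
    nbins = int(math.ceil(math.sqrt(len(d))))
    counts, edges = np.histogram(d, bins=nbins)
    width = edges[1] - edges[0]
    if width <= 0:
        return 0.0
    diffs = []
    for i in range(nbins):
        center = (edges[i] + edges[i + 1]) / 2
        density = counts[i] / (len(d) * width)
        diffs.append(abs(density - math.exp(-center / lam) / lam))
    return sum(diffs) / len(diffs)


def ami_gaussian_fmmi(acf, n):
    tau_max = min(40, n // 2)
    ami = []
    for lag in range(1, tau_max + 1):
        rho = max(min(acf[lag], 0.999999), -0.999999)
        ami.append(-0.5 * math.log(1 - rho * rho))
    for k in range(1, len(ami) - 1):
        if ami[k] < ami[k - 1] and ami[k] < ami[k + 1]:
            return float(k + 1)
    return float(len(ami))


def local_mean_residuals(y, train):
    return np.array(
        [y[i] - np.mean(y[i - train : i]) for i in range(train, len(y))]
    )


def tauresrat(y, acf):
    res = local_mean_residuals(y, 1)
    if len(res) < 3:
        return 0.0
    denom = first_zero(acf)
    return first_zero(acf_naive(res)) / denom if denom > 0 else 0.0


def outlier_include_mdrmd(y):
    n = len(y)
    top = max(y)
    if top < 0.01:
        return 0.0
    stats = []
    th = 0.0
    while th < top:
        idx = [i for i in range(n) if y[i] >= th]
        if len(idx) / n * 100.0 < 2.0:
            break
        rel = [(i + 1) / n for i in idx]
        stats.append(2.0 * float(np.median(rel)) - 1.0)
        th += 0.01
    return float(np.median(stats)) if stats else 0.0


def welch_rect(y):
    """O(N²) direct DFT periodogram, rectangular window."""
    n = len(y)
    y = y - np.mean(y)
    nf = n // 2 + 1
    S = np.empty(nf)
    for k in range(nf):
        re = sum(y[j] * math.cos(2 * math.pi * k * j / n) for j in range(n))
        im = sum(-y[j] * math.sin(2 * math.pi * k * j / n) for j in range(n))
        S[k] = (re * re + im * im) / (2 * math.pi * n)
    w = np.array([2 * math.pi * k / n for k in range(nf)])
    return w, S


def spectral_area_5_1(w, S):
    dw = w[1] - w[0]
    return float(sum(S[: int(math.ceil(len(S) / 5.0))]) * dw)


def spectral_centroid(w, S):
    dw = w[1] - w[0]
    csum = np.cumsum(S) * dw
    if csum[-1] <= 0:
        return 0.0
    half = csum[-1] / 2
    for k in range(len(csum)):
        if csum[k] > half:
            return float(w[k])
    return float(w[-1])


def motif_three_hh(y):
    sym = quantile_symbols(y)
    counts = {}
    for a, b in zip(sym[:-1], sym[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def fluct_anal_prop_r1(y, how, lag):
    x = np.cumsum(y[::lag])
    n = len(x)
    lo, hi = 5, n // 2
    if hi < lo + 1:
        return 0.0
    taus = sorted(
        set(int(math.floor(v)) for v in np.logspace(math.log10(lo), math.log10(hi), 50))
    )
    taus = [t for t in taus if lo <= t <= hi]
    if len(taus) < 12:
        return 0.0
    F = []
    for tau in taus:
        nbuf = n // tau
        acc = []
        for b in range(nbuf):
            seg = x[b * tau : (b + 1) * tau]
            xi = np.arange(tau, dtype=float)
            fit = np.polyfit(xi, seg, 1)
            resid = seg - np.polyval(fit, xi)
            if how == "dfa":
                acc.append(float(np.mean(resid**2)))
            else:
                acc.append(float((resid.max() - resid.min()) ** 2))
        F.append(math.sqrt(sum(acc) / len(acc)))
    F = np.array(F)
    if np.any(F <= 0):
        return 0.0
    lt, lF = np.log(np.array(taus, dtype=float)), np.log(F)

    def sse(a, b):
        fit = np.polyfit(a, b, 1)
        return float(np.sum((b - np.polyval(fit, a)) ** 2))

    best, besti = math.inf, 6
    for i in range(6, len(taus) - 6 + 1):
        s = sse(lt[:i], lF[:i]) + sse(lt[i:], lF[i:])
        if s < best:
            best, besti = s, i
    return besti / len(taus)


def features_naive(y):
    """All 22 features in the package's canonical order."""
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        return np.zeros(22)
    z = zscore(y)
    acf = acf_naive(z)
    w, S = welch_rect(z)
    diffs = np.diff(z)
    out = np.array(
        [
            histogram_mode(z, 5),
            histogram_mode(z, 10),
            longstretch(list(diffs > 0), False),
            outlier_include_mdrmd(z),
            outlier_include_mdrmd(-z),
            f1ecac(acf),
            first_min_ac(acf),
            spectral_area_5_1(w, S),
            longstretch(list(z > 0), True),
            motif_three_hh(z),
            tauresrat(z, acf),
            hist_ami_even_2_5(z),
            float(np.mean(diffs**3)),
            float(np.mean(np.abs(diffs) > 0.04)),
            transition_matrix_sumdiagcov(z, acf),
            periodicity_wang(z),
            embed2_dist_expfit_meandiff(z, acf),
            ami_gaussian_fmmi(acf, len(z)),
            float(np.std(local_mean_residuals(z, 3), ddof=1)),
            fluct_anal_prop_r1(z, "dfa", 2),
            fluct_anal_prop_r1(z, "rsrangefit", 1),
            spectral_centroid(w, S),
        ]
    )
    out[~np.isfinite(out)] = 0.0
    return out
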